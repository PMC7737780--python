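"""Synthetic homolog families and MSAs with known ground truth.

The toy family emulates the situation the pipeline is built for: a set of
homologous single-domain structures sharing rigid, structurally conserved
anchor stretches (idealized helices at fixed torsions) connected by variable
loops. Loops belonging to the same planted conformational group share one base
torsion string; groups differ strongly (inter-group backbone rmsd above a
configurable floor), and per-homolog angular noise (Gaussian, clipped at the
stated bound) creates within-group variation. Loop base conformations are
geometrically closed onto the template's anchor frames at generation time, so
— as in a real family — every homolog presents the same framework geometry and
only the segment conformations differ.

Sequences follow the same logic: anchor stretches are conserved, loop
sequences vary freely. Toy MSAs plant exact pairwise identities by mutating a
controlled number of positions of a reference sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly import AssemblyRecipe, assemble
from .fragment_db import (
    FragmentDatabase,
    FragmentRecord,
    fragment_rmsd,
    graft_and_close,
)
from .pssm import ALPHABET, MSA
from .segmentation import Fragment, SegmentationScheme
from .structure_io import (
    BackboneModel,
    TorsionTriple,
    rebuild_backbone,
    write_pdb,
)

logger = logging.getLogger(__name__)

PHI_HELIX, PSI_HELIX = -57.0, -47.0
OMEGA_TRANS = 180.0

# (phi, psi) motifs sampled when planting loop conformations
LOOP_MOTIFS = (
    (-60.0, -45.0),
    (-120.0, 130.0),
    (-75.0, 145.0),
    (55.0, 45.0),
    (-90.0, -5.0),
    (-140.0, 160.0),
    (-70.0, 120.0),
    (75.0, 10.0),
)


@dataclass(frozen=True)
class ToyFamilySpec:
    n_structures: int = 10
    n_segments: int = 4
    loop_length_range: tuple = (6, 12)
    n_conformational_groups: int = 3
    torsion_noise: float = 2.0  # degrees; hard clip bound, Gaussian sigma = bound/2
    seed: int = 0
    anchor_block_len: int = 5
    intergroup_min_rmsd: float = 3.5  # Å between planted group base conformations

    def __post_init__(self):
        lo, hi = self.loop_length_range
        if lo > hi or lo < 3:
            raise ValueError("loop_length_range must satisfy 3 <= min <= max")
        if self.n_conformational_groups > self.n_structures:
            raise ValueError("more conformational groups than structures")
        if self.n_conformational_groups < 1 or self.n_segments < 1:
            raise ValueError("need at least one group and one segment")


@dataclass
class GroundTruth:
    template_id: str
    anchors: list
    segment_names: list
    group_labels: dict  # (structure_id, segment_name) -> group index
    loop_lengths: dict  # (segment_name, group index) -> loop length
    catalytic_positions: tuple
    identities: dict = field(default_factory=dict)


@dataclass
class ToyFamily:
    template: BackboneModel
    homologs: list
    scheme: SegmentationScheme
    ground_truth: GroundTruth

    def write(self, outdir) -> list:
        """Write template + homologs as PDB files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for model in [self.template, *self.homologs]:
            path = outdir / f"{model.source_id}.pdb"
            write_pdb(model, path)
            paths.append(path)
        return paths


def _random_seq(rng, length):
    return "".join(rng.choice(list(ALPHABET), size=length))


def _loop_torsions(rng, length):
    """Planted base torsions for one loop: motif per position plus jitter."""
    out = []
    for _ in range(length):
        phi, psi = LOOP_MOTIFS[int(rng.integers(len(LOOP_MOTIFS)))]
        out.append(
            (
                phi + float(rng.uniform(-10, 10)),
                psi + float(rng.uniform(-10, 10)),
            )
        )
    return out


def _clipped_noise(rng, bound):
    if bound <= 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, bound / 2.0), -bound, bound))


def _segment_fragment(
    template, scheme, name, loop_phi_psi, loop_seq, fl_left, fl_right, source_id
):
    """A Fragment spanning the segment's anchors: conserved helical flanks
    (``fl_left``/``fl_right`` residues, template sequence) around the given
    loop (phi, psi) list. The loop may differ in length from the template's."""
    seg = scheme.segment(name)
    helix = TorsionTriple(phi=PHI_HELIX, psi=PSI_HELIX, omega=OMEGA_TRANS)
    torsions = (
        [helix] * fl_left
        + [TorsionTriple(phi=p, psi=s, omega=OMEGA_TRANS) for p, s in loop_phi_psi]
        + [helix] * fl_right
    )
    seq = (
        template.seq[seg.start : seg.start + fl_left]
        + loop_seq
        + template.seq[seg.end - fl_right + 1 : seg.end + 1]
    )
    return Fragment(
        source_id=source_id,
        segment_name=name,
        seq=seq,
        torsions=torsions,
        end_frames=np.array(
            [template.backbone_frame(seg.start), template.backbone_frame(seg.end)]
        ),
        coords=None,
    )


def _close_fragment(template, frag, scheme, max_sweeps=500):
    """Close a planted fragment onto the template anchor frames; returns the
    closed torsion list or None if closure fails."""
    result = graft_and_close(template, frag, scheme, max_sweeps=max_sweeps)
    if not result.converged:
        return None
    return result.closed_torsions


def make_toy_family(spec: ToyFamilySpec, outdir=None):
    """Generate a template plus homolog family with planted conformational
    groups per segment.

    Returns ``(family, ground_truth)`` where family is a :class:`ToyFamily`;
    when ``outdir`` is given the structures are also written as PDB files and
    the family records their paths. Fixed seed gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_segments
    B = spec.anchor_block_len
    lo, hi = spec.loop_length_range

    # --- template: anchor blocks + group-0 loops ---------------------------
    block_seqs = [_random_seq(rng, B) for _ in range(k + 1)]
    loop_len0 = [int(rng.integers(lo, hi + 1)) for _ in range(k)]
    loops0 = [_loop_torsions(rng, L) for L in loop_len0]
    loop_seq0 = [_random_seq(rng, L) for L in loop_len0]

    torsions: list = []
    seq_parts: list = []
    anchors = []
    pos = 0
    for s in range(k + 1):
        anchors.append(pos + B // 2)
        for _ in range(B):
            torsions.append(
                TorsionTriple(phi=PHI_HELIX, psi=PSI_HELIX, omega=OMEGA_TRANS)
            )
        seq_parts.append(block_seqs[s])
        pos += B
        if s < k:
            for phi, psi in loops0[s]:
                torsions.append(TorsionTriple(phi=phi, psi=psi, omega=OMEGA_TRANS))
            seq_parts.append(loop_seq0[s])
            pos += loop_len0[s]
    torsions[0] = TorsionTriple(phi=None, psi=torsions[0].psi, omega=torsions[0].omega)
    torsions[-1] = TorsionTriple(phi=torsions[-1].phi, psi=None, omega=None)
    template = rebuild_backbone(torsions, "".join(seq_parts), source_id="template")

    names = [str(i + 1) for i in range(k)]
    scheme = SegmentationScheme.from_anchors("template", anchors, names=names)
    fl_left = B - B // 2  # anchor residue .. end of its block
    fl_right = B // 2 + 1  # start of next block .. its anchor residue

    # --- planted group base conformations per segment ----------------------
    base_torsions: dict = {}  # (segment, group) -> closed fragment torsion list
    base_loop_len: dict = {}
    for s, name in enumerate(names):
        own = _segment_fragment(
            template, scheme, name, loops0[s], loop_seq0[s], fl_left, fl_right, "base-g0"
        )
        closed0 = _close_fragment(template, own, scheme)
        if closed0 is None:  # grafting the template's own loop always closes
            raise RuntimeError(f"template loop failed self-closure in segment {name}")
        base_torsions[(name, 0)] = closed0
        base_loop_len[(name, 0)] = loop_len0[s]
        for g in range(1, spec.n_conformational_groups):
            placed = False
            for _ in range(80):
                Lg = int(rng.integers(loop_len0[s], max(loop_len0[s], hi) + 1))
                cand = _segment_fragment(
                    template,
                    scheme,
                    name,
                    _loop_torsions(rng, Lg),
                    _random_seq(rng, Lg),
                    fl_left,
                    fl_right,
                    f"base-g{g}",
                )
                closed = _close_fragment(template, cand, scheme)
                if closed is None:
                    continue
                frag_new = Fragment(
                    source_id="new", segment_name=name, seq=cand.seq, torsions=closed,
                    end_frames=cand.end_frames,
                )
                far_enough = True
                for g2 in range(g):
                    old = base_torsions[(name, g2)]
                    frag_old = Fragment(
                        source_id="old", segment_name=name,
                        seq="A" * len(old), torsions=old, end_frames=cand.end_frames,
                    )
                    if fragment_rmsd(frag_new, frag_old) < spec.intergroup_min_rmsd:
                        far_enough = False
                        break
                if far_enough:
                    base_torsions[(name, g)] = closed
                    base_loop_len[(name, g)] = Lg
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not plant group {g} for segment {name}: closure or"
                    " inter-group separation kept failing"
                )

    # --- homologs: per-segment group draw + clipped angular noise ----------
    group_labels: dict = {}
    homologs = []
    for h in range(spec.n_structures):
        hid = f"hom{h:03d}"
        records: dict = {}
        for s, name in enumerate(names):
            order = list(range(spec.n_conformational_groups))
            g = order[h % spec.n_conformational_groups]
            group_labels[(hid, name)] = g
            base = base_torsions[(name, g)]
            noisy = []
            for i, t in enumerate(base):
                if 0 < i < len(base) - 1:
                    noisy.append(
                        TorsionTriple(
                            phi=t.phi + _clipped_noise(rng, spec.torsion_noise),
                            psi=t.psi + _clipped_noise(rng, spec.torsion_noise),
                            omega=t.omega,
                        )
                    )
                else:
                    noisy.append(t)
            seg = scheme.segment(name)
            loop_len = len(base) - fl_left - fl_right
            frag = Fragment(
                source_id=hid,
                segment_name=name,
                seq=template.seq[seg.start : seg.start + fl_left]
                + _random_seq(rng, loop_len)
                + template.seq[seg.end - fl_right + 1 : seg.end + 1],
                torsions=noisy,
                end_frames=np.array(
                    [template.backbone_frame(seg.start), template.backbone_frame(seg.end)]
                ),
            )
            result = graft_and_close(template, frag, scheme, max_sweeps=500)
            records[name] = FragmentRecord(
                fragment=frag,
                closure_rmsd=result.closure_rmsd,
                converged=result.converged,
                closed_torsions=result.closed_torsions,
                accepted=True,
            )
        db = FragmentDatabase(
            segments={name: [records[name]] for name in names}, metadata={}
        )
        recipe = AssemblyRecipe(choices=tuple((name, 0) for name in names))
        cand = assemble(template, db, recipe, scheme)
        hom = BackboneModel(source_id=hid, residues=cand.model.residues, breaks=[])
        _random_rigid_motion(hom, rng)
        homologs.append(hom)

    catalytic = (anchors[1], anchors[min(2, len(anchors) - 1)])
    gt = GroundTruth(
        template_id="template",
        anchors=anchors,
        segment_names=names,
        group_labels=group_labels,
        loop_lengths=base_loop_len,
        catalytic_positions=catalytic,
    )
    family = ToyFamily(
        template=template, homologs=homologs, scheme=scheme, ground_truth=gt
    )
    if outdir is not None:
        family.write(outdir)
    return family, gt


def _random_rigid_motion(model: BackboneModel, rng) -> None:
    """Apply a random rotation + translation so structural alignment back to
    the template is non-trivial."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    for res in model.residues:
        for atom in res.atoms.values():
            object.__setattr__(atom, "coords", Q @ atom.coords + t)


def make_toy_msa(reference: str, identity_targets, seed: int = 0, names=None):
    """Mutate a reference sequence to hit each pairwise identity target within
    2 percentage points (substitutions only, so the alignment is trivial).

    Returns ``(msa, realized)`` where the MSA's row 0 is the reference and
    ``realized`` maps row name → exact planted identity.
    """
    L = len(reference)
    rng = np.random.default_rng(seed)
    rows = [reference]
    row_names = ["ref"]
    realized = {}
    for idx, target in enumerate(identity_targets):
        if not 0.0 <= target <= 1.0:
            raise ValueError("identity targets must be fractions in [0, 1]")
        k = int(round((1.0 - target) * L))
        achieved = (L - k) / L
        if abs(achieved - target) > 0.02:
            raise ValueError(
                f"target identity {target} unreachable within 2 points on a"
                f" reference of length {L}"
            )
        sites = rng.choice(L, size=k, replace=False)
        seq = list(reference)
        for site in sites:
            options = [a for a in ALPHABET if a != reference[site]]
            seq[site] = options[int(rng.integers(len(options)))]
        name = names[idx] if names else f"hom{idx:03d}"
        rows.append("".join(seq))
        row_names.append(name)
        realized[name] = achieved
    msa = MSA(names=row_names, rows=rows, reference_row=0)
    return msa, realized
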