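"""Combinatorial assembly of new backbones from database fragments.

An assembly recipe picks one accepted database fragment (or the template's own
conformation) for every segment of the scheme. Because every database record
stores torsions already closed onto the template's anchor frames, assembly is
a pure splice: segment torsions are concatenated N→C with the template's
framework torsions, each shared anchor taking its phi from the segment on its
left and its psi/omega from the segment on its right, and the full chain is
rebuilt once with idealized geometry — so every candidate backbone is
continuous by construction. The candidate carries a composed PSSM (one row per
designed position, sliced from each fragment's source profile), a
catalytic-residue fixation flag and a simple steric clash count standing in
for downstream all-atom design.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fragment_db import FragmentDatabase
from .geometry import kabsch_superpose
from .pssm import PSSMMatrix, compose_pssm
from .segmentation import SegmentationScheme
from .structure_io import (
    BackboneModel,
    TorsionTriple,
    extract_torsions,
    rebuild_backbone,
)

logger = logging.getLogger(__name__)

TEMPLATE_CHOICE = "template"
DEFAULT_CATALYTIC_TOL = 0.5  # Å
DEFAULT_CLASH_CUTOFF = 2.5  # Å
MIN_CLASH_SEPARATION = 3  # residues


@dataclass(frozen=True)
class AssemblyRecipe:
    choices: tuple  # ((segment_name, index-or-"template"), ...) in scheme order
    seed: int | None = None

    @classmethod
    def from_dict(cls, choices: dict, seed=None):
        return cls(choices=tuple(choices.items()), seed=seed)

    @property
    def as_dict(self):
        return dict(self.choices)

    def label(self) -> str:
        return "|".join(f"{name}={idx}" for name, idx in self.choices)

    def sort_key(self):
        out = []
        for name, idx in self.choices:
            if idx == TEMPLATE_CHOICE:
                out.append((name, -1, ""))
            elif isinstance(idx, (int, np.integer)):
                out.append((name, int(idx), ""))
            else:
                out.append((name, 2**31, str(idx)))
        return tuple(out)


@dataclass
class DesignCandidate:
    recipe: AssemblyRecipe
    model: BackboneModel
    pssm: PSSMMatrix | None = None
    catalytic_ok: bool | None = None
    steric_score: int | None = None
    feature_values: dict = field(default_factory=dict)
    template_map: dict = field(default_factory=dict)
    failed: bool = False
    failure_reason: str | None = None


@dataclass(frozen=True)
class CatalyticConstraint:
    positions: tuple  # template residue indices
    tolerance: float = DEFAULT_CATALYTIC_TOL

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(self.positions))


class AssemblyError(ValueError):
    pass


def _segment_payload(template, template_torsions, db, scheme, name, choice):
    """Torsions/sequence/source rows for one segment under one choice."""
    seg = scheme.segment(name)
    if choice == TEMPLATE_CHOICE:
        lo = seg.start if seg.start is not None else 0
        hi = seg.end if seg.end is not None else len(template) - 1
        return {
            "segment": seg,
            "torsions": template_torsions[lo : hi + 1],
            "seq": template.seq[lo : hi + 1],
            "source_id": template.source_id,
            "source_span": (lo, hi),
            "is_template": True,
        }
    records = db.accepted(name)
    idx = int(choice)
    if not 0 <= idx < len(records):
        raise AssemblyError(
            f"segment {name!r}: fragment index {idx} outside accepted range"
            f" 0..{len(records) - 1}"
        )
    rec = records[idx]
    return {
        "segment": seg,
        "torsions": rec.closed_torsions,
        "seq": rec.fragment.seq,
        "source_id": rec.fragment.source_id,
        "source_span": rec.fragment.source_span,
        "is_template": False,
    }


def assemble(
    template: BackboneModel,
    db: FragmentDatabase,
    recipe: AssemblyRecipe,
    scheme: SegmentationScheme,
    pssms: dict | None = None,
) -> DesignCandidate:
    """Splice the chosen closed fragments into a full-length backbone.

    ``pssms`` optionally maps source_id (template and homolog ids) to a
    full-length :class:`PSSMMatrix` over the source's ungapped positions; when
    given, a composed per-assembly PSSM is produced with exactly one row per
    designed position.
    """
    choices = recipe.as_dict
    missing = [s.name for s in scheme.segments if s.name not in choices]
    if missing:
        raise AssemblyError(f"recipe lacks choices for segments {missing}")

    template_torsions = extract_torsions(template)
    interior = [s for s in scheme.segments if not s.is_tail]
    payloads = {
        s.name: _segment_payload(
            template, template_torsions, db, scheme, s.name, choices[s.name]
        )
        for s in scheme.segments
    }

    a_first = interior[0].start
    a_last = interior[-1].end
    torsions: list = []
    seq: list = []
    template_map: dict = {}
    row_sources: list = []  # (source_id, source row index) per designed position

    def push(triple, aa, src, src_row, tmpl_idx=None):
        torsions.append(triple)
        seq.append(aa)
        row_sources.append((src, src_row))
        if tmpl_idx is not None:
            template_map[tmpl_idx] = len(seq) - 1

    def span_row(payload, k):
        span = payload["source_span"]
        return None if span is None else span[0] + k

    nterm = next((s for s in scheme.segments if s.start is None), None)
    if nterm is not None:
        p = payloads[nterm.name]
        m = len(p["seq"]) - 1
        for k in range(m):
            push(
                TorsionTriple(
                    phi=p["torsions"][k].phi if k > 0 else None,
                    psi=p["torsions"][k].psi,
                    omega=p["torsions"][k].omega,
                ),
                p["seq"][k],
                p["source_id"],
                span_row(p, k),
                tmpl_idx=k if p["is_template"] else None,
            )
    else:
        for i in range(a_first):
            push(
                template_torsions[i],
                template.residues[i].aa,
                template.source_id,
                i,
                tmpl_idx=i,
            )

    # first shared anchor: phi from upstream (template or nterm tail), psi/omega
    # from the first interior segment
    first_payload = payloads[interior[0].name]
    nterm_payload = payloads[nterm.name] if nterm is not None else None
    anchor_phi = (
        nterm_payload["torsions"][-1].phi
        if nterm_payload is not None
        else template_torsions[a_first].phi
    )
    push(
        TorsionTriple(
            phi=anchor_phi,
            psi=first_payload["torsions"][0].psi,
            omega=first_payload["torsions"][0].omega,
        ),
        template.residues[a_first].aa,
        template.source_id,
        a_first,
        tmpl_idx=a_first,
    )

    for k, seg in enumerate(interior):
        p = payloads[seg.name]
        m = len(p["seq"]) - 1
        for j in range(1, m):
            push(
                p["torsions"][j],
                p["seq"][j],
                p["source_id"],
                span_row(p, j),
                tmpl_idx=(seg.start + j) if p["is_template"] else None,
            )
        if k + 1 < len(interior):
            nxt = payloads[interior[k + 1].name]
            push(
                TorsionTriple(
                    phi=p["torsions"][m].phi,
                    psi=nxt["torsions"][0].psi,
                    omega=nxt["torsions"][0].omega,
                ),
                template.residues[seg.end].aa,
                template.source_id,
                seg.end,
                tmpl_idx=seg.end,
            )

    cterm = next((s for s in scheme.segments if s.end is None), None)
    last_payload = payloads[interior[-1].name]
    m_last = len(last_payload["seq"]) - 1
    if cterm is not None:
        pc = payloads[cterm.name]
        push(
            TorsionTriple(
                phi=last_payload["torsions"][m_last].phi,
                psi=pc["torsions"][0].psi,
                omega=pc["torsions"][0].omega,
            ),
            template.residues[a_last].aa,
            template.source_id,
            a_last,
            tmpl_idx=a_last,
        )
        mc = len(pc["seq"]) - 1
        for k in range(1, mc + 1):
            push(
                TorsionTriple(
                    phi=pc["torsions"][k].phi,
                    psi=pc["torsions"][k].psi if k < mc else None,
                    omega=pc["torsions"][k].omega if k < mc else None,
                ),
                pc["seq"][k],
                pc["source_id"],
                span_row(pc, k),
                tmpl_idx=(a_last + k) if pc["is_template"] else None,
            )
    else:
        push(
            TorsionTriple(
                phi=last_payload["torsions"][m_last].phi,
                psi=template_torsions[a_last].psi
                if a_last < len(template) - 1
                else None,
                omega=template_torsions[a_last].omega
                if a_last < len(template) - 1
                else None,
            ),
            template.residues[a_last].aa,
            template.source_id,
            a_last,
            tmpl_idx=a_last,
        )
        for i in range(a_last + 1, len(template)):
            push(
                template_torsions[i],
                template.residues[i].aa,
                template.source_id,
                i,
                tmpl_idx=i,
            )

    model = rebuild_backbone(
        torsions,
        "".join(seq),
        anchor_frame=None,
        source_id=f"design:{recipe.label()}",
    )
    _superpose_onto_template(model, template, scheme, template_map)

    composed = None
    if pssms is not None:
        if any(row is None for _, row in row_sources):
            raise AssemblyError(
                "PSSM composition needs fragments with recorded source spans"
            )
        try:
            composed = compose_pssm((pssms[src], row) for src, row in row_sources)
        except KeyError as exc:
            raise AssemblyError(f"no PSSM supplied for source {exc}") from exc

    return DesignCandidate(
        recipe=recipe, model=model, pssm=composed, template_map=template_map
    )


def _superpose_onto_template(model, template, scheme, template_map):
    """Rigid-body place the assembled model onto the template via the shared
    anchor N,CA,C frames (in-place)."""
    mob, fix = [], []
    for a in scheme.anchors:
        if a in template_map:
            mob.append(model.backbone_frame(template_map[a]))
            fix.append(template.backbone_frame(a))
    mob = np.concatenate(mob)
    fix = np.concatenate(fix)
    R, t, _ = kabsch_superpose(mob, fix)
    for res in model.residues:
        for atom in res.atoms.values():
            object.__setattr__(atom, "coords", R @ atom.coords + t)


def count_assemblies(db: FragmentDatabase, segment_names=None) -> int:
    """Product over segments of the accepted-fragment counts."""
    names = segment_names or db.segment_names
    total = 1
    for name in names:
        n = len(db.accepted(name))
        if n == 0:
            raise AssemblyError(f"segment {name!r} has no accepted fragments")
        total *= n
    return total


def enumerate_or_sample(
    db: FragmentDatabase, n: int, seed: int | None = None, segment_names=None
):
    """All recipes in lexicographic order if the combinatorial count is ≤ n;
    otherwise n distinct recipes sampled uniformly without replacement."""
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(segment_names or db.segment_names)
    radices = [len(db.accepted(name)) for name in names]
    total = count_assemblies(db, names)

    def decode(code):
        idxs = []
        for r in reversed(radices):
            idxs.append(code % r)
            code //= r
        return AssemblyRecipe(
            choices=tuple(zip(names, reversed(idxs))), seed=seed
        )

    if total <= n:
        return [decode(c) for c in range(total)]
    codes = random.Random(seed).sample(range(total), n)
    return [decode(c) for c in codes]


def check_catalytic(
    candidate: DesignCandidate,
    template: BackboneModel,
    constraint: CatalyticConstraint,
    scheme: SegmentationScheme,
) -> bool:
    """True iff, after anchor-frame superposition onto the template, every
    constrained residue's backbone atoms lie within the tolerance of the
    template's. The candidate's ``catalytic_ok`` flag is updated."""
    ok = True
    reason = None
    for pos in constraint.positions:
        if pos not in candidate.template_map:
            ok = False
            reason = f"constrained position {pos} absent from assembly"
            break
        ci = candidate.template_map[pos]
        for name in ("N", "CA", "C", "O"):
            t_res = template.residues[pos]
            c_res = candidate.model.residues[ci]
            if not (t_res.has(name) and c_res.has(name)):
                continue
            d = float(np.linalg.norm(t_res.coord(name) - c_res.coord(name)))
            if d > constraint.tolerance:
                ok = False
                reason = f"position {pos} atom {name} deviates {d:.2f} Å"
                break
        if not ok:
            break
    candidate.catalytic_ok = ok
    if not ok:
        candidate.failure_reason = reason
    return ok


def steric_screen(
    candidate: DesignCandidate, cutoff: float = DEFAULT_CLASH_CUTOFF
) -> int:
    """Count non-bonded backbone/CB atom pairs (residue separation ≥ 3) closer
    than the cutoff; recorded as the candidate's ``steric_score``."""
    coords, res_idx = [], []
    for i, res in enumerate(candidate.model.residues):
        for name in ("N", "CA", "C", "O", "CB"):
            if res.has(name):
                coords.append(res.coord(name))
                res_idx.append(i)
    coords = np.asarray(coords)
    res_idx = np.asarray(res_idx)
    tree = cKDTree(coords)
    clashes = 0
    for a, b in tree.query_pairs(cutoff):
        if abs(res_idx[a] - res_idx[b]) >= MIN_CLASH_SEPARATION:
            clashes += 1
    candidate.steric_score = clashes
    return clashes
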