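"""Segmentation of homologous structures at conserved anchors.

A segmentation scheme names contiguous segments of the template delimited by
user-chosen anchor residues — positions of maximal structural conservation
across the family (disulfide cysteines in antibodies, alignable β-strand
positions in TIM barrels). Homologs are aligned to the template by
sequence-seeded iterative superposition; each homolog then contributes one
torsion-space fragment per segment, spanning its residues between the mapped
anchors inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .geometry import kabsch_superpose
from .structure_io import BackboneModel, extract_torsions

logger = logging.getLogger(__name__)

ALIGN_DISTANCE_CUTOFF = 3.5  # Å; pairs farther than this are discarded per round


@dataclass(frozen=True)
class Segment:
    """One named segment; ``start``/``end`` are anchor residue indices on the
    template (0-based). ``None`` on one side marks a terminal tail anchored at
    a single position."""

    name: str
    start: int | None
    end: int | None

    @property
    def is_tail(self) -> bool:
        return self.start is None or self.end is None


@dataclass
class SegmentationScheme:
    template_id: str
    anchors: list
    segments: list

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.anchors, self.anchors[1:])):
            raise ValueError("anchors must be strictly increasing")
        anchor_set = set(self.anchors)
        for seg in self.segments:
            for a in (seg.start, seg.end):
                if a is not None and a not in anchor_set:
                    raise ValueError(f"segment {seg.name!r} uses unknown anchor {a}")
        # interior segments must chain contiguously
        interior = [s for s in self.segments if not s.is_tail]
        for left, right in zip(interior, interior[1:]):
            if left.end != right.start:
                raise ValueError(
                    f"segments {left.name!r} and {right.name!r} are not contiguous"
                )

    def segment(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(f"no segment named {name!r}")

    @property
    def segment_names(self):
        return [s.name for s in self.segments]

    @classmethod
    def from_anchors(cls, template_id: str, anchors, names=None, tails=False):
        """Build a scheme with one segment between each consecutive anchor
        pair, optionally adding N-/C-terminal tail segments."""
        anchors = list(anchors)
        if names is None:
            names = [str(i + 1) for i in range(len(anchors) - 1)]
        if len(names) != len(anchors) - 1:
            raise ValueError("need one name per consecutive anchor pair")
        segments = [
            Segment(name, a, b) for name, a, b in zip(names, anchors, anchors[1:])
        ]
        if tails:
            segments = (
                [Segment("nterm", None, anchors[0])]
                + segments
                + [Segment("cterm", anchors[-1], None)]
            )
        return cls(template_id=template_id, anchors=anchors, segments=segments)

    def to_yaml(self, path) -> None:
        data = {
            "template_id": self.template_id,
            "anchors": list(map(int, self.anchors)),
            "segments": [
                {"name": s.name, "start": s.start, "end": s.end} for s in self.segments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            template_id=data["template_id"],
            anchors=list(data["anchors"]),
            segments=[Segment(s["name"], s.get("start"), s.get("end")) for s in data["segments"]],
        )


@dataclass
class TemplateAlignment:
    homolog_id: str
    pairs: list  # (homolog residue index, template residue index), both increasing
    anchor_map: dict  # template anchor index -> homolog residue index


@dataclass
class Fragment:
    """One homolog's conformation for one segment.

    ``torsions`` cover every fragment residue; phi of the first residue and
    psi/omega of the last come from the homolog's surrounding context (they are
    owned by the neighbouring segments at assembly time). ``coords`` holds the
    homolog's backbone coordinates (residue × N,CA,C,O) for rmsd computations;
    ``end_frames`` the N,CA,C coordinates of the two anchor residues (one for
    tails).
    """

    source_id: str
    segment_name: str
    seq: str
    torsions: list
    end_frames: np.ndarray
    coords: np.ndarray | None = None
    source_span: tuple | None = None  # (start, end) residue indices in source

    def __post_init__(self):
        if len(self.seq) != len(self.torsions):
            raise ValueError("sequence and torsion list lengths differ")

    @property
    def n_res(self) -> int:
        return len(self.seq)


class AnchorMappingError(ValueError):
    """A template anchor could not be mapped onto the homolog."""


def _seed_pairs(homolog_seq: str, template_seq: str):
    """Residue-index pairs from a global sequence alignment (BLOSUM62)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(homolog_seq, template_seq)[0]
    pairs = []
    for (h0, h1), (t0, t1) in zip(*aln.aligned):
        pairs.extend(zip(range(h0, h1), range(t0, t1)))
    return pairs


def align_to_template(
    homolog: BackboneModel,
    template: BackboneModel,
    scheme: SegmentationScheme,
    distance_cutoff: float = ALIGN_DISTANCE_CUTOFF,
    max_rounds: int = 50,
) -> TemplateAlignment:
    """Sequence-guided iterative structural alignment of a homolog onto the
    template.

    A global sequence alignment seeds residue pairs; CA coordinates of the
    paired residues are superposed (Kabsch) and pairs farther apart than the
    cutoff are discarded, iterating until the pair set is stable. The homolog
    is rejected if any scheme anchor ends up unmapped.
    """
    seed_pairs = _seed_pairs(homolog.seq, template.seq)
    h_ca = homolog.ca_coords()
    t_ca = template.ca_coords()
    mob_all = np.array([h_ca[i] for i, _ in seed_pairs])
    fix_all = np.array([t_ca[j] for _, j in seed_pairs])
    pairs = list(seed_pairs)
    for _ in range(max_rounds):
        if len(pairs) < 3:
            raise AnchorMappingError(
                f"{homolog.source_id}: fewer than 3 residue pairs survive alignment"
            )
        mob = np.array([h_ca[i] for i, _ in pairs])
        fix = np.array([t_ca[j] for _, j in pairs])
        R, t, _ = kabsch_superpose(mob, fix)
        # re-evaluate every seeded pair under the refined transform so pairs
        # lost to a skewed early superposition can be recovered
        dist = np.linalg.norm(mob_all @ R.T + t - fix_all, axis=1)
        kept = [p for p, d in zip(seed_pairs, dist) if d <= distance_cutoff]
        if kept == pairs:
            break
        pairs = kept

    mapping = {j: i for i, j in pairs}
    anchor_map = {}
    for anchor in scheme.anchors:
        if anchor not in mapping:
            raise AnchorMappingError(
                f"{homolog.source_id}: anchor {anchor} is unmapped after alignment"
            )
        anchor_map[anchor] = mapping[anchor]
    return TemplateAlignment(
        homolog_id=homolog.source_id, pairs=pairs, anchor_map=anchor_map
    )


class FragmentExtractionError(ValueError):
    pass


def _backbone_coords(model: BackboneModel, start: int, end: int) -> np.ndarray:
    out = np.full((end - start + 1, 4, 3), np.nan)
    for k, res in enumerate(model.residues[start : end + 1]):
        for j, name in enumerate(("N", "CA", "C", "O")):
            if res.has(name):
                out[k, j] = res.coord(name)
    return out


def extract_fragment(
    homolog: BackboneModel,
    alignment: TemplateAlignment,
    segment: Segment | str,
    scheme: SegmentationScheme | None = None,
) -> Fragment:
    """Extract the homolog's fragment for one segment, anchors inclusive."""
    if isinstance(segment, str):
        if scheme is None:
            raise ValueError("need the scheme to resolve a segment name")
        segment = scheme.segment(segment)
    if segment.start is None:
        start, end = 0, alignment.anchor_map[segment.end]
    elif segment.end is None:
        start, end = alignment.anchor_map[segment.start], len(homolog) - 1
    else:
        start = alignment.anchor_map[segment.start]
        end = alignment.anchor_map[segment.end]
    if end <= start and not (segment.is_tail and end == start):
        raise FragmentExtractionError(
            f"{alignment.homolog_id}/{segment.name}: empty span {start}..{end}"
        )
    inside = [b for b in homolog.breaks if start < b <= end]
    if inside:
        raise FragmentExtractionError(
            f"{alignment.homolog_id}/{segment.name}: chain break inside span"
        )
    torsions = extract_torsions(homolog)[start : end + 1]
    if segment.is_tail:
        frame_indices = [end] if segment.start is None else [start]
    else:
        frame_indices = [start, end]
    end_frames = np.array(
        [homolog.backbone_frame(i) for i in frame_indices]
    )  # (n_ends, 3 atoms, 3)
    return Fragment(
        source_id=alignment.homolog_id,
        segment_name=segment.name,
        seq=homolog.seq[start : end + 1],
        torsions=torsions,
        end_frames=end_frames,
        coords=_backbone_coords(homolog, start, end),
        source_span=(start, end),
    )


def align_fragment_ends(fragments, reference: Fragment):
    """Rigid-body align each fragment's anchor atoms onto the reference's.

    Uses the N, CA, C atoms of both end residues (one end for tails). Returns
    the transformed fragments along with the residual anchor-atom rmsd of each.
    """
    ref_pts = reference.end_frames.reshape(-1, 3)
    out = []
    rmsds = []
    for frag in fragments:
        if frag.segment_name != reference.segment_name:
            raise ValueError("fragments must share the reference's segment")
        pts = frag.end_frames.reshape(-1, 3)
        R, t, rmsd = kabsch_superpose(pts, ref_pts)
        new_frames = frag.end_frames @ R.T + t
        new_coords = None
        if frag.coords is not None:
            new_coords = frag.coords @ R.T + t
        out.append(replace(frag, end_frames=new_frames, coords=new_coords))
        rmsds.append(rmsd)
    return out, rmsds


def anchor_deviation_report(
    homologs, template: BackboneModel, alignments
) -> dict:
    """Per-template-position mean CA–CA deviation across aligned homologs.

    A helper for choosing anchors: low-deviation positions are candidates for
    segmentation points. Returns {template index: mean deviation in Å} over
    positions mapped in at least one homolog.
    """
    t_ca = template.ca_coords()
    sums, counts = {}, {}
    for hom, aln in zip(homologs, alignments):
        h_ca = hom.ca_coords()
        mob = np.array([h_ca[i] for i, _ in aln.pairs])
        fix = np.array([t_ca[j] for _, j in aln.pairs])
        R, t, _ = kabsch_superpose(mob, fix)
        moved = mob @ R.T + t
        for (hi, tj), pos in zip(aln.pairs, moved):
            d = float(np.linalg.norm(pos - t_ca[tj]))
            sums[tj] = sums.get(tj, 0.0) + d
            counts[tj] = counts.get(tj, 0) + 1
    return {j: sums[j] / counts[j] for j in sorted(sums)}
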