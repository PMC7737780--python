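"""Evolutionary sequence constraints: homolog filtering and PSSM construction.

Design avoids mutations rarely observed among homologs. Homolog sequences are
filtered by pairwise global-alignment identity and coverage against the query
(defaults 35% identity, ≥75% coverage, top 3,000 by identity), assembled into
an MSA, and converted into a position-specific scoring matrix: per-column
weighted residue frequencies (Henikoff position-based weights), BLOSUM62
marginal background, pseudocounts, and half-bit rounded integer log-odds
scores. The matrix serializes to the PSI-BLAST ASCII dialect so externally
generated PSSMs can be swapped in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

# BLOSUM62 marginal (background) amino-acid frequencies.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}
_BG = np.array([BLOSUM62_BACKGROUND[a] for a in ALPHABET])
_BG = _BG / _BG.sum()

SCORE_CAP = 16  # integer half-bit scores clipped to ±SCORE_CAP
DEFAULT_PSEUDOCOUNT = 50.0  # effective background counts


@dataclass(frozen=True)
class SequenceFilter:
    min_identity: float = 0.35
    min_coverage: float = 0.75
    max_sequences: int = 3000

    def __post_init__(self):
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_coverage <= 1):
            raise ValueError("identity/coverage thresholds must be fractions in [0, 1]")
        if self.max_sequences < 1:
            raise ValueError("max_sequences must be >= 1")


@dataclass
class MSA:
    names: list
    rows: list
    reference_row: int = 0

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all MSA rows must have equal length")
        ref = self.rows[self.reference_row]
        bad = set(ref) - set(ALPHABET) - {"-"}
        if bad:
            raise ValueError(f"reference row contains ambiguous characters: {bad}")

    @property
    def n_cols(self):
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path, reference_row: int = 0):
        names, rows, seq = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if seq:
                        rows.append("".join(seq))
                        seq = []
                    names.append(line[1:].split()[0])
                elif line:
                    seq.append(line.upper())
        if seq:
            rows.append("".join(seq))
        return cls(names=names, rows=rows, reference_row=reference_row)

    def to_fasta(self, path):
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.rows):
                fh.write(f">{name}\n{row}\n")


@dataclass
class PSSMMatrix:
    """positions × 20 integer log-odds scores (half-bit units), with the
    reference residue at each position. Column order A R N D C Q E G H I L K
    M F P S T W Y V."""

    positions: list
    ref_seq: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if self.scores.shape != (len(self.positions), 20):
            raise ValueError("scores must be (n_positions, 20)")
        if len(self.ref_seq) != len(self.positions):
            raise ValueError("ref_seq length must match positions")

    def __len__(self):
        return len(self.positions)

    def row(self, position):
        return self.scores[self.positions.index(position)]


def _global_alignment(query: str, candidate: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner.align(query, candidate)[0]


def identity_and_coverage(query: str, candidate: str):
    """Pairwise identity (matches / aligned columns, terminal gaps excluded)
    and coverage (aligned query residues / query length) from a global
    alignment."""
    aln = _global_alignment(query, candidate)
    blocks_q, blocks_c = aln.aligned
    if len(blocks_q) == 0:
        return 0.0, 0.0
    matches = 0
    aligned_query = 0
    for (q0, q1), (c0, c1) in zip(blocks_q, blocks_c):
        aligned_query += q1 - q0
        for qi, ci in zip(range(q0, q1), range(c0, c1)):
            if query[qi] == candidate[ci]:
                matches += 1
    # columns between the first and last aligned pair, internal gaps included
    q_span = blocks_q[-1][1] - blocks_q[0][0]
    c_span = blocks_c[-1][1] - blocks_c[0][0]
    aligned_cols = aligned_query + (q_span - aligned_query) + (c_span - aligned_query)
    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = aligned_query / len(query)
    return identity, coverage


def filter_homologs(query: str, candidates, seq_filter: SequenceFilter | None = None):
    """Retain candidates meeting the identity and coverage thresholds, sorted
    by identity descending and truncated to ``max_sequences``."""
    if not query:
        raise ValueError("query sequence must be non-empty")
    seq_filter = seq_filter or SequenceFilter()
    if not candidates:
        logger.warning("no candidate sequences supplied")
        return []
    kept = []
    for cand in candidates:
        ident, cov = identity_and_coverage(query, cand)
        if ident >= seq_filter.min_identity and cov >= seq_filter.min_coverage:
            kept.append((ident, cand))
    kept.sort(key=lambda ic: (-ic[0], ic[1]))
    return [cand for _, cand in kept[: seq_filter.max_sequences]]


def _position_based_weights(rows):
    """Henikoff position-based sequence weights (gap treated as a 21st
    symbol), normalized to sum to 1."""
    n_seq = len(rows)
    weights = np.zeros(n_seq)
    for col in zip(*rows):
        symbols = {}
        for ch in col:
            symbols[ch] = symbols.get(ch, 0) + 1
        r = len(symbols)
        if r == 1:
            continue
        for s, ch in enumerate(col):
            weights[s] += 1.0 / (r * symbols[ch])
    if weights.sum() == 0:
        weights[:] = 1.0
    return weights / weights.sum()


def build_pssm(
    msa: MSA, pseudocount_weight: float = DEFAULT_PSEUDOCOUNT
) -> PSSMMatrix:
    """Position-specific scoring matrix over the reference row's ungapped
    positions.

    Per column: weighted observed frequencies f are blended with the BLOSUM62
    background b as f' = (N·f + w·b)/(N + w) where N is the weighted non-gap
    count scaled to the number of contributing sequences and w the pseudocount
    weight; scores are 2·log2(f'/b) rounded to integers and clipped to
    ±SCORE_CAP.
    """
    if len(msa.rows) < 1:
        raise ValueError("MSA must contain at least one row")
    ref = msa.rows[msa.reference_row]
    if set(ref) == {"-"}:
        raise ValueError("reference row is all gaps")
    weights = _position_based_weights(msa.rows)
    positions, ref_seq, score_rows = [], [], []
    ref_pos = -1
    for col_idx in range(msa.n_cols):
        ref_char = ref[col_idx]
        if ref_char == "-":
            continue
        ref_pos += 1
        col = [row[col_idx] for row in msa.rows]
        freqs = np.zeros(20)
        total_w = 0.0
        n_contrib = 0
        for w, ch in zip(weights, col):
            if ch in AA_INDEX:
                freqs[AA_INDEX[ch]] += w
                total_w += w
                n_contrib += 1
        if total_w > 0:
            freqs /= total_w
        n_eff = float(n_contrib)
        blended = (n_eff * freqs + pseudocount_weight * _BG) / (
            n_eff + pseudocount_weight
        )
        with np.errstate(divide="ignore"):
            raw = 2.0 * np.log2(blended / _BG)
        raw = np.where(np.isfinite(raw), raw, -np.inf)
        scores = np.clip(np.round(raw), -SCORE_CAP, SCORE_CAP).astype(int)
        positions.append(ref_pos)
        ref_seq.append(ref_char)
        score_rows.append(scores)
    return PSSMMatrix(
        positions=positions, ref_seq="".join(ref_seq), scores=np.array(score_rows)
    )


def slice_pssm(pssm: PSSMMatrix, fragment, offset: int) -> PSSMMatrix:
    """Rows ``offset .. offset+len−1`` of the matrix, renumbered from 0.
    ``fragment`` may be a Fragment or a plain length."""
    length = fragment if isinstance(fragment, int) else fragment.n_res
    if offset < 0 or offset + length > len(pssm):
        raise IndexError(
            f"slice [{offset}, {offset + length}) outside matrix of {len(pssm)} rows"
        )
    return PSSMMatrix(
        positions=list(range(length)),
        ref_seq=pssm.ref_seq[offset : offset + length],
        scores=pssm.scores[offset : offset + length].copy(),
    )


def concat_pssms(parts) -> PSSMMatrix:
    """Concatenate matrices, renumbering positions consecutively from 0."""
    parts = list(parts)
    if not parts:
        raise ValueError("nothing to concatenate")
    scores = np.concatenate([p.scores for p in parts])
    ref_seq = "".join(p.ref_seq for p in parts)
    return PSSMMatrix(positions=list(range(len(ref_seq))), ref_seq=ref_seq, scores=scores)


def compose_pssm(row_sources) -> PSSMMatrix:
    """Build a per-assembly matrix from (pssm, row index) pairs, one per
    designed position."""
    rows, chars = [], []
    for pssm, idx in row_sources:
        rows.append(pssm.scores[idx])
        chars.append(pssm.ref_seq[idx])
    return PSSMMatrix(
        positions=list(range(len(rows))), ref_seq="".join(chars), scores=np.array(rows)
    )


def allowed_residues(pssm: PSSMMatrix, position: int, threshold: float = 0.0):
    """Residues scoring ≥ threshold at the position; never empty — falls back
    to the single best-scoring residue with a warning."""
    row = pssm.row(position)
    allowed = {ALPHABET[i] for i in range(20) if row[i] >= threshold}
    if not allowed:
        best = ALPHABET[int(np.argmax(row))]
        logger.warning(
            "no residue reaches threshold %s at position %s; falling back to %s",
            threshold, position, best,
        )
        allowed = {best}
    return allowed


def write_psiblast_ascii(pssm: PSSMMatrix, path) -> None:
    """Serialize in the PSI-BLAST ASCII dialect (header with the 20-letter
    alphabet; one row per position: 1-based index, reference residue, 20
    integer scores)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed"
            " percentages rounded down, information per position, and relative"
            " weight of gapless real matches to pseudocounts\n"
        )
        fh.write("           " + "  ".join(ALPHABET) + "\n")
        for pos, ch, row in zip(pssm.positions, pssm.ref_seq, pssm.scores):
            cells = "".join(f"{int(v):4d}" for v in row)
            fh.write(f"{pos + 1:5d} {ch}  {cells}\n")


def read_psiblast_ascii(path) -> PSSMMatrix:
    positions, ref_seq, rows = [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
                positions.append(int(parts[0]) - 1)
                ref_seq.append(parts[1])
                rows.append([int(v) for v in parts[2:22]])
    if not rows:
        raise ValueError(f"no PSSM rows found in {path}")
    return PSSMMatrix(
        positions=positions, ref_seq="".join(ref_seq), scores=np.array(rows)
    )
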