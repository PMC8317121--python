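"""Pairwise global sequence alignment with affine gap penalties.

Paralogous domain pairs are aligned at the amino-acid level (BLOSUM62,
gap open -10 / extend -0.5) before their occupancy profiles are projected
into shared coordinates, and at the DNA level (match +1 / mismatch -1,
open -5 / extend -2) to compute the percent identity used by the
30-80% relatedness band.  A gap run of length L costs
``open + (L - 1) * extend``; terminal gaps are scored like internal ones.

Externally computed alignments (e.g. from MUSCLE or MAFFT) can be imported
from two-record aligned FASTA files so that published alignments can be
reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO
from Bio.Align import PairwiseAligner, substitution_matrices

GAP = "-"
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_DNA_ALPHABET = set("ACGT")

#: (substitution scoring, gap open, gap extend) per sequence kind.
DEFAULT_SCORING = {
    "protein": {"matrix": "BLOSUM62", "open": -10.0, "extend": -0.5},
    "dna": {"match": 1.0, "mismatch": -1.0, "open": -5.0, "extend": -2.0},
}


@dataclass(frozen=True)
class PairAlignment:
    """A global pairwise alignment: two equal-length gapped strings.

    No column may be a gap in both rows, and stripping gaps must recover
    the original sequences.
    """

    aligned_a: str
    aligned_b: str
    kind: str
    score: float

    def __post_init__(self) -> None:
        if self.kind not in ("dna", "protein"):
            raise ValueError(f"kind must be 'dna' or 'protein', got {self.kind!r}")
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows have unequal lengths")
        if len(self.aligned_a) == 0:
            raise ValueError("empty alignment")
        for i, (x, y) in enumerate(zip(self.aligned_a, self.aligned_b)):
            if x == GAP and y == GAP:
                raise ValueError(f"column {i} is a gap in both rows")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace(GAP, "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.aligned_a)


def _check_alphabet(seq: str, kind: str) -> None:
    alphabet = _DNA_ALPHABET if kind == "dna" else _PROTEIN_ALPHABET
    bad = sorted(set(seq) - alphabet)
    if bad:
        raise ValueError(f"characters outside {kind} alphabet: {bad}")


def _make_aligner(kind: str, scoring: dict | None) -> PairwiseAligner:
    params = dict(DEFAULT_SCORING[kind])
    if scoring:
        params.update(scoring)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if kind == "protein":
        aligner.substitution_matrix = substitution_matrices.load(params["matrix"])
    else:
        aligner.match_score = params["match"]
        aligner.mismatch_score = params["mismatch"]
    aligner.open_gap_score = params["open"]
    aligner.extend_gap_score = params["extend"]
    return aligner


def align_global(
    seq_a: str, seq_b: str, kind: str = "protein", scoring: dict | None = None
) -> PairAlignment:
    """Optimal global alignment of two sequences under affine gap scoring.

    When several alignments are co-optimal the first one enumerated by the
    aligner is returned, which is deterministic for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if kind not in DEFAULT_SCORING:
        raise ValueError(f"kind must be 'dna' or 'protein', got {kind!r}")
    _check_alphabet(seq_a, kind)
    _check_alphabet(seq_b, kind)
    alignments = _make_aligner(kind, scoring).align(seq_a, seq_b)
    best = alignments[0]
    return PairAlignment(
        aligned_a=best[0], aligned_b=best[1], kind=kind, score=float(best.score)
    )


def score_alignment(
    aligned_a: str, aligned_b: str, kind: str = "protein", scoring: dict | None = None
) -> float:
    """Score an explicit alignment under the same affine convention."""
    params = dict(DEFAULT_SCORING[kind])
    if scoring:
        params.update(scoring)
    if kind == "protein":
        matrix = substitution_matrices.load(params["matrix"])

        def sub(x: str, y: str) -> float:
            return float(matrix[x, y])

    else:

        def sub(x: str, y: str) -> float:
            return params["match"] if x == y else params["mismatch"]

    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP:
            score += params["extend"] if in_gap_a else params["open"]
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            score += params["extend"] if in_gap_b else params["open"]
            in_gap_a, in_gap_b = False, True
        else:
            score += sub(x, y)
            in_gap_a = in_gap_b = False
    return score


def _core_span(alignment: PairAlignment) -> tuple[int, int]:
    """Column span [start, end) excluding gap runs that touch either end.

    A terminal run is a maximal gap run in one row that includes the first
    or last alignment column; the same definition governs gap_stats.
    """
    n = len(alignment)
    start, end = 0, n
    for row in (alignment.aligned_a, alignment.aligned_b):
        if row[0] == GAP:
            i = 0
            while i < n and row[i] == GAP:
                i += 1
            start = max(start, i)
        if row[-1] == GAP:
            j = n
            while j > 0 and row[j - 1] == GAP:
                j -= 1
            end = min(end, j)
    return start, end


def percent_identity(alignment: PairAlignment) -> float:
    """Fraction of identical columns, excluding terminal gap runs.

    The denominator is the number of alignment columns in the core span
    (internal gap columns count as mismatches).
    """
    start, end = _core_span(alignment)
    if end <= start:
        raise ValueError("no columns remain after terminal-gap exclusion")
    a = alignment.aligned_a[start:end]
    b = alignment.aligned_b[start:end]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    return matches / (end - start)


def gap_stats(alignment: PairAlignment) -> tuple[int, int]:
    """Number of gap runs and longest run, pooled over both rows.

    A gap is a maximal run of gap symbols within one row.  Runs touching
    either end of the alignment are not counted.  Returns ``(0, 0)`` for a
    gapless core.
    """
    n = len(alignment)
    runs: list[int] = []
    for row in (alignment.aligned_a, alignment.aligned_b):
        i = 0
        while i < n:
            if row[i] == GAP:
                j = i
                while j < n and row[j] == GAP:
                    j += 1
                if i > 0 and j < n:  # terminal runs excluded
                    runs.append(j - i)
                i = j
            else:
                i += 1
    if not runs:
        return 0, 0
    return len(runs), max(runs)


def import_alignment(path: str | Path, kind: str = "protein") -> PairAlignment:
    """Read a two-record aligned FASTA (e.g. MUSCLE output) as a PairAlignment."""
    msa = AlignIO.read(str(path), "fasta")
    if len(msa) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(msa)}")
    a, b = (str(rec.seq).upper() for rec in msa)
    if len(a) != len(b):
        raise ValueError(f"{path}: aligned records have unequal lengths")
    return PairAlignment(
        aligned_a=a, aligned_b=b, kind=kind, score=score_alignment(a, b, kind)
    )


def export_alignment(
    alignment: PairAlignment, path: str | Path, id_a: str = "a", id_b: str = "b"
) -> None:
    with open(path, "w") as fh:
        fh.write(f">{id_a}\n{alignment.aligned_a}\n>{id_b}\n{alignment.aligned_b}\n")
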