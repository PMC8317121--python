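"""From raw per-codon A-site counts to normalized occupancy profiles.

A domain's raw profile is the slice of its gene's per-codon A-site counts
covering the annotated residue range.  For a pair of domains the processing
chain is:

1. reject pairs whose amino-acid alignment is gappy (more than ten internal
   gap runs, or any run of five or more positions; terminal runs ignored);
2. remove positions falling in the first 40 or last 20 codons of the
   full-length gene, which are inflated by initiation/termination biases;
3. project both count vectors onto the columns of the pair's amino-acid
   alignment and drop columns whose position was trimmed in either domain;
4. fill alignment-gap slots and zero-count positions by a cubic
   interpolating spline through the positive observed positions (anchors),
   holding anchor values fixed; negative interpolants are clamped to zero;
5. smooth with a 15-codon centered moving average (the window truncates at
   the profile edges);
6. normalize to unit area (sum, with unit codon spacing).

Pairs whose final shared profile is shorter than 50 positions are discarded.
Single-domain profiles (used for the non-paralogous comparison pool) follow
the same chain without an alignment step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline

from .alignment import GAP, PairAlignment, _core_span, gap_stats
from .io_formats import DomainAnnotation, GeneRecord

#: provenance codes for processed profile positions
OBSERVED, INTERPOLATED, GAP_FILLED = "observed", "interpolated", "gap-filled"


class ProfileRejection(Exception):
    """A domain or pair failed a quality-control rule; ``rule`` names it."""

    def __init__(self, rule: str, detail: str = ""):
        self.rule = rule
        self.detail = detail
        super().__init__(f"{rule}{': ' + detail if detail else ''}")


@dataclass(frozen=True)
class ProcessingParams:
    """Quality-control thresholds and processing constants.

    Defaults are the study's published values: domains of at least 100
    residues with at least 70% of codon positions covered by reads; pair
    alignments with at most 10 internal gap runs, none of length 5 or more;
    40 codons trimmed at the 5' gene end and 20 at the 3' end; a 15-codon
    smoothing window; processed profiles of at least 50 positions.
    """

    min_len: int = 100
    min_coverage: float = 0.70
    max_gap_runs: int = 10
    max_gap_len: int = 4  # longest run still allowed
    trim_start: int = 40
    trim_end: int = 20
    smooth_window: int = 15
    min_profile_len: int = 50


DEFAULT_PARAMS = ProcessingParams()


@dataclass(frozen=True)
class RawDomainProfile:
    """Per-codon counts for one domain, in full-gene coordinates.

    ``gene_codon_indices`` are the 0-based positions of each count within
    the gene; they are strictly increasing and contiguous.  ``domain_start``
    and ``domain_len`` record the untrimmed extent so that trimmed profiles
    can still be mapped onto an alignment of the full domain sequence.
    """

    domain_id: str
    counts: np.ndarray
    gene_codon_indices: np.ndarray
    gene_len: int
    domain_start: int = None  # type: ignore[assignment]
    domain_len: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        idx = np.asarray(self.gene_codon_indices, dtype=np.int64)
        if counts.ndim != 1 or idx.shape != counts.shape:
            raise ValueError(f"{self.domain_id}: counts/indices shape mismatch")
        if len(idx) == 0:
            raise ValueError(f"{self.domain_id}: empty profile")
        if np.any(np.diff(idx) != 1):
            raise ValueError(f"{self.domain_id}: indices not contiguous increasing")
        if idx[0] < 0 or idx[-1] >= self.gene_len:
            raise ValueError(f"{self.domain_id}: indices outside gene of "
                             f"{self.gene_len} codons")
        if np.any(counts < 0):
            raise ValueError(f"{self.domain_id}: negative counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_codon_indices", idx)
        if self.domain_start is None:
            object.__setattr__(self, "domain_start", int(idx[0]))
        if self.domain_len is None:
            object.__setattr__(self, "domain_len", len(idx))

    @classmethod
    def from_domain(
        cls,
        domain: DomainAnnotation,
        gene: GeneRecord,
        counts: np.ndarray | None = None,
    ) -> "RawDomainProfile":
        """Slice a gene's count vector to the domain's residue range."""
        vec = np.asarray(gene.counts if counts is None else counts)
        if domain.end_res > len(vec):
            raise ValueError(
                f"{domain.domain_id}: range ends at residue {domain.end_res} "
                f"but gene has {len(vec)} codons"
            )
        sl = slice(domain.start_res - 1, domain.end_res)
        return cls(
            domain_id=domain.domain_id,
            counts=vec[sl],
            gene_codon_indices=np.arange(domain.start_res - 1, domain.end_res),
            gene_len=len(vec),
        )


@dataclass(frozen=True)
class ProcessedProfile:
    """A normalized, smoothed occupancy profile in alignment coordinates.

    ``values`` sum to one; ``alignment_columns`` index the pair-alignment
    columns each value occupies (or 0..L-1 for single-domain profiles);
    ``provenance`` flags each position as observed, interpolated (zero read
    density or trimmed interior) or gap-filled (alignment gap).
    """

    domain_id: str
    values: np.ndarray
    alignment_columns: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        cols = np.asarray(self.alignment_columns, dtype=np.int64)
        prov = np.asarray(self.provenance)
        if not (len(values) == len(cols) == len(prov)):
            raise ValueError("values/columns/provenance length mismatch")
        if np.any(values < 0):
            raise ValueError("negative profile values")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile sums to {values.sum()!r}, not 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "alignment_columns", cols)
        object.__setattr__(self, "provenance", prov)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Domain-level quality control


def coverage(raw: RawDomainProfile) -> float:
    """Fraction of domain codon positions with at least one read."""
    return float(np.mean(raw.counts > 0))


def filter_domains(
    domains: Sequence[DomainAnnotation],
    genes: Mapping[str, GeneRecord],
    counts: Mapping[str, np.ndarray] | None = None,
    params: ProcessingParams = DEFAULT_PARAMS,
) -> tuple[list[DomainAnnotation], list[tuple[str, str]]]:
    """Apply the domain-level filters; return retained domains and a rejection log.

    Rules: (i) non-contiguous definitions (a domain_id spanning several
    rows), (ii) fewer than ``min_len`` residues, (iii) read coverage below
    ``min_coverage``.  The log records ``(domain_id, rule)`` per rejection.
    """
    seen: dict[str, int] = {}
    for d in domains:
        seen[d.domain_id] = seen.get(d.domain_id, 0) + 1
    retained: list[DomainAnnotation] = []
    rejections: list[tuple[str, str]] = []
    for d in domains:
        if seen[d.domain_id] > 1:
            rejections.append((d.domain_id, "non-contiguous"))
            continue
        if d.n_residues < params.min_len:
            rejections.append((d.domain_id, "min_length"))
            continue
        gene = genes[d.gene_id]
        vec = None if counts is None else counts[d.gene_id]
        raw = RawDomainProfile.from_domain(d, gene, vec)
        if coverage(raw) < params.min_coverage:
            rejections.append((d.domain_id, "coverage"))
            continue
        retained.append(d)
    return retained, rejections


# ---------------------------------------------------------------------------
# Processing steps


def trim_gene_ends(
    raw: RawDomainProfile, trim_start: int = 40, trim_end: int = 20
) -> RawDomainProfile:
    """Drop positions in the first ``trim_start`` / last ``trim_end`` gene codons.

    Raises ProfileRejection("fully_trimmed") if nothing remains.
    """
    idx = raw.gene_codon_indices
    keep = (idx >= trim_start) & (idx < raw.gene_len - trim_end)
    if not keep.any():
        raise ProfileRejection("fully_trimmed", raw.domain_id)
    return replace(
        raw,
        counts=raw.counts[keep],
        gene_codon_indices=idx[keep],
        domain_start=raw.domain_start,
        domain_len=raw.domain_len,
    )


@dataclass(frozen=True)
class ProjectedPair:
    """Two count vectors laid on shared alignment columns.

    ``status_*`` per column is ``observed`` (count available), ``trimmed``
    (position removed by the gene-end trim) or ``gap`` (alignment gap in
    that row).  Values at non-observed columns are NaN.
    """

    values_a: np.ndarray
    values_b: np.ndarray
    status_a: np.ndarray
    status_b: np.ndarray


def _project_row(raw: RawDomainProfile, aligned: str) -> tuple[np.ndarray, np.ndarray]:
    n_res = len(aligned) - aligned.count(GAP)
    if n_res != raw.domain_len:
        raise ValueError(
            f"{raw.domain_id}: alignment row has {n_res} residues but the "
            f"domain spans {raw.domain_len}"
        )
    n_cols = len(aligned)
    values = np.full(n_cols, np.nan)
    status = np.full(n_cols, "gap", dtype=object)
    first_kept = int(raw.gene_codon_indices[0])
    last_kept = int(raw.gene_codon_indices[-1])
    residue = 0
    for col, ch in enumerate(aligned):
        if ch == GAP:
            continue
        gene_idx = raw.domain_start + residue
        if first_kept <= gene_idx <= last_kept:
            values[col] = raw.counts[gene_idx - first_kept]
            status[col] = "observed"
        else:
            status[col] = "trimmed"
        residue += 1
    return values, status


def project_to_alignment(
    raw_a: RawDomainProfile, raw_b: RawDomainProfile, aln: PairAlignment
) -> ProjectedPair:
    """Lay two (possibly trimmed) raw profiles onto the pair alignment's columns."""
    values_a, status_a = _project_row(raw_a, aln.aligned_a)
    values_b, status_b = _project_row(raw_b, aln.aligned_b)
    return ProjectedPair(values_a, values_b, status_a, status_b)


def interpolate_profile(
    values: Sequence[float], missing: Sequence[bool] | None = None
) -> np.ndarray:
    """Fill missing and zero positions by spline interpolation through anchors.

    Anchors are positions with an observed positive count; their values are
    held exactly fixed.  With four or more anchors a cubic interpolating
    spline is used (negative interpolants clamped to zero); with two or
    three, linear interpolation.  Positions before the first or after the
    last anchor take the nearest anchor's value rather than extrapolating.

    Raises ProfileRejection("uninterpolatable") with fewer than two anchors.
    """
    v = np.asarray(values, dtype=float)
    miss = (
        np.zeros(len(v), dtype=bool)
        if missing is None
        else np.asarray(missing, dtype=bool)
    )
    v = np.where(miss, np.nan, v)
    anchors = ~miss & (np.nan_to_num(v) > 0)
    n_anchors = int(anchors.sum())
    if n_anchors < 2:
        raise ProfileRejection("uninterpolatable", f"{n_anchors} anchor(s)")
    x = np.arange(len(v), dtype=float)
    xa, ya = x[anchors], v[anchors]
    if n_anchors <= 3:
        out = np.interp(x, xa, ya)  # linear; ends clamp to nearest anchor
    else:
        spline = InterpolatedUnivariateSpline(xa, ya, k=3)
        out = spline(x)
        out[x < xa[0]] = ya[0]
        out[x > xa[-1]] = ya[-1]
        np.clip(out, 0.0, None, out=out)
    out[anchors] = ya  # exact anchor preservation
    return out


def smooth(values: Sequence[float], window: int = 15) -> np.ndarray:
    """Centered moving average; the window truncates at the profile edges.

    Each position is averaged over the part of its ``window``-wide centered
    neighbourhood that lies inside the profile, so a position at the very
    edge with window 15 averages over 8 values.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty vector")
    kernel = np.ones(window)
    sums = np.convolve(v, kernel, mode="same")
    norms = np.convolve(np.ones(len(v)), kernel, mode="same")
    return sums / norms


def normalize_auc(values: Sequence[float]) -> np.ndarray:
    """Scale a profile to unit area under the curve (sum, unit codon spacing)."""
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError(f"cannot normalize profile with sum {total}")
    return v / total


# ---------------------------------------------------------------------------
# Full chains


def _finish(values: np.ndarray, window: int) -> np.ndarray:
    return normalize_auc(smooth(values, window))


def process_pair(
    raw_a: RawDomainProfile,
    raw_b: RawDomainProfile,
    protein_aln: PairAlignment,
    params: ProcessingParams = DEFAULT_PARAMS,
) -> tuple[ProcessedProfile, ProcessedProfile]:
    """Run the full pair chain: gap filter, trim, project, interpolate, smooth, normalize.

    Both returned profiles share their alignment columns (positions trimmed
    in either domain are dropped from both).  Raises ProfileRejection with
    the failing rule: ``gappy_alignment``, ``fully_trimmed``,
    ``short_profile`` or ``uninterpolatable``.
    """
    n_runs, max_run = gap_stats(protein_aln)
    if n_runs > params.max_gap_runs or max_run > params.max_gap_len:
        raise ProfileRejection(
            "gappy_alignment", f"{n_runs} gap runs, longest {max_run}"
        )
    trimmed_a = trim_gene_ends(raw_a, params.trim_start, params.trim_end)
    trimmed_b = trim_gene_ends(raw_b, params.trim_start, params.trim_end)
    proj = project_to_alignment(trimmed_a, trimmed_b, protein_aln)
    keep = (proj.status_a != "trimmed") & (proj.status_b != "trimmed")
    # terminal-gap columns carry no observation at all for one domain
    # (there is nothing beyond the sequence end to interpolate between),
    # so they are dropped like trimmed columns rather than fabricated
    core_start, core_end = _core_span(protein_aln)
    keep[:core_start] = False
    keep[core_end:] = False
    columns = np.flatnonzero(keep)
    if len(columns) < params.min_profile_len:
        raise ProfileRejection(
            "short_profile", f"{len(columns)} positions after trimming"
        )
    profiles = []
    for raw, values, status in (
        (raw_a, proj.values_a[keep], proj.status_a[keep]),
        (raw_b, proj.values_b[keep], proj.status_b[keep]),
    ):
        missing = status == "gap"
        filled = interpolate_profile(np.nan_to_num(values), missing)
        provenance = np.where(
            missing,
            GAP_FILLED,
            np.where(np.nan_to_num(values) > 0, OBSERVED, INTERPOLATED),
        )
        profiles.append(
            ProcessedProfile(
                domain_id=raw.domain_id,
                values=_finish(filled, params.smooth_window),
                alignment_columns=columns,
                provenance=provenance,
            )
        )
    return profiles[0], profiles[1]


def process_single(
    raw: RawDomainProfile, params: ProcessingParams = DEFAULT_PARAMS
) -> ProcessedProfile:
    """Process one domain's profile without an alignment (trim, interpolate,
    smooth, normalize); used for the non-paralogous comparison pool."""
    trimmed = trim_gene_ends(raw, params.trim_start, params.trim_end)
    if len(trimmed.counts) < params.min_profile_len:
        raise ProfileRejection(
            "short_profile", f"{len(trimmed.counts)} positions after trimming"
        )
    filled = interpolate_profile(trimmed.counts)
    provenance = np.where(trimmed.counts > 0, OBSERVED, INTERPOLATED)
    return ProcessedProfile(
        domain_id=raw.domain_id,
        values=_finish(filled, params.smooth_window),
        alignment_columns=np.arange(len(filled)),
        provenance=provenance,
    )


def export_profiles(profiles: Sequence[ProcessedProfile], path) -> None:
    """Write processed profiles as TSV (domain_id, alignment_column, value, provenance)."""
    with open(path, "w") as fh:
        fh.write("domain_id\talignment_column\tvalue\tprovenance\n")
        for p in profiles:
            for col, val, prov in zip(p.alignment_columns, p.values, p.provenance):
                fh.write(f"{p.domain_id}\t{col}\t{val:.10g}\t{prov}\n")
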