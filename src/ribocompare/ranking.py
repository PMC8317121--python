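"""Rank-based comparison of paralogous pairs against non-paralogous domains.

Each paralogous domain pair is scored by the fsmf of its two processed
profiles and ranked against the fsmf of the first pair member versus 19
randomly selected, size-matched non-paralogous domains (different SCOP
class, superfamily and family; length within 25 residues).  Non-paralogous
profiles are laid alongside the pair profile from the first shared 5'
position and truncated at the 3' end to the pair profile's length.  Rank 1
means the paralogous pair is the most similar of the 20 comparisons; under
the null the rank is uniform on 1..20, so the expected count per rank is
``n_pairs / 20``.

Twenty independent trials redraw the non-paralog sets; a random-pair
control replaces paralogous pairs with random domain pairs (no family or
identity requirement) run through identical machinery; per-rank differences
between two rank tables are assessed by a permutation test that relabels
trial rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import align_global, percent_identity
from .fsmf import fsmf
from .io_formats import AMINO_ACIDS, DomainAnnotation, GeneRecord
from .profile_processing import (
    DEFAULT_PARAMS,
    ProcessedProfile,
    ProcessingParams,
    ProfileRejection,
    RawDomainProfile,
    coverage,
    interpolate_profile,
    normalize_auc,
    process_pair,
    process_single,
    smooth,
    trim_gene_ends,
)

N_RANKS_DEFAULT = 20


def _as_seedseq(
    seed: int | np.random.SeedSequence | None,
) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class PoolEntry:
    """A quality-controlled domain with its raw, trimmed and processed profiles."""

    domain: DomainAnnotation
    raw: RawDomainProfile
    protein: str
    cds: str
    profile: ProcessedProfile | None
    coverage: float
    trimmed: RawDomainProfile | None = None

    @property
    def domain_id(self) -> str:
        return self.domain.domain_id


@dataclass
class PairComparison:
    """Two aligned processed profiles and their fsmf value."""

    entry_a: PoolEntry
    entry_b: PoolEntry
    profile_a: ProcessedProfile
    profile_b: ProcessedProfile
    fsmf_value: float
    dna_identity: float | None = None

    @property
    def pair_id(self) -> str:
        return f"{self.entry_a.domain_id}|{self.entry_b.domain_id}"

    @property
    def profile_len(self) -> int:
        return len(self.profile_a)


def build_pool(
    domains: Sequence[DomainAnnotation],
    genes: Mapping[str, GeneRecord],
    counts: Mapping[str, np.ndarray] | None = None,
    params: ProcessingParams = DEFAULT_PARAMS,
) -> tuple[list[PoolEntry], list[tuple[str, str]]]:
    """Build pool entries with single-domain processed profiles.

    Domains whose standalone profile fails processing keep ``profile=None``
    (they can still serve as paralog pair members) and are logged.
    """
    entries: list[PoolEntry] = []
    failures: list[tuple[str, str]] = []
    for dom in domains:
        gene = genes[dom.gene_id]
        vec = None if counts is None else counts[dom.gene_id]
        raw = RawDomainProfile.from_domain(dom, gene, vec)
        entries.append(_make_entry(
            dom,
            raw,
            protein=gene.protein[dom.start_res - 1 : dom.end_res],
            cds=gene.cds[(dom.start_res - 1) * 3 : dom.end_res * 3],
            params=params,
            failures=failures,
        ))
    return entries, failures


def _make_entry(
    dom: DomainAnnotation,
    raw: RawDomainProfile,
    protein: str,
    cds: str,
    params: ProcessingParams,
    failures: list[tuple[str, str]] | None = None,
    cov: float | None = None,
) -> PoolEntry:
    try:
        profile = process_single(raw, params)
    except ProfileRejection as exc:
        profile = None
        if failures is not None:
            failures.append((dom.domain_id, exc.rule))
    try:
        trimmed = trim_gene_ends(raw, params.trim_start, params.trim_end)
    except ProfileRejection:
        trimmed = None
    return PoolEntry(
        domain=dom,
        raw=raw,
        protein=protein,
        cds=cds,
        profile=profile,
        coverage=cov if cov is not None else coverage(raw),
        trimmed=trimmed,
    )


def compare_pair(
    entry_a: PoolEntry,
    entry_b: PoolEntry,
    params: ProcessingParams = DEFAULT_PARAMS,
    compute_identity: bool = True,
) -> PairComparison:
    """Align a domain pair's proteins, process both profiles, compute fsmf.

    Raises ProfileRejection when the pair fails any processing rule.
    """
    aln = align_global(entry_a.protein, entry_b.protein, kind="protein")
    prof_a, prof_b = process_pair(entry_a.raw, entry_b.raw, aln, params)
    identity = None
    if compute_identity:
        identity = percent_identity(align_global(entry_a.cds, entry_b.cds, kind="dna"))
    return PairComparison(
        entry_a=entry_a,
        entry_b=entry_b,
        profile_a=prof_a,
        profile_b=prof_b,
        fsmf_value=fsmf(prof_a, prof_b),
        dna_identity=identity,
    )


# ---------------------------------------------------------------------------
# Non-paralog selection and ranking


def eligible_nonparalogs(
    pair: PairComparison,
    pool: Sequence[PoolEntry],
    length_tolerance: int = 25,
    params: ProcessingParams = DEFAULT_PARAMS,
) -> list[PoolEntry]:
    """Candidates satisfying every deterministic criterion for this pair.

    A candidate must survive gene-end trimming, must not lie on either pair
    gene, must meet the length and coverage floors, must differ from both
    pair members in SCOP class, superfamily and family, and must be within
    ``length_tolerance`` residues of the reference (first) member's length.
    """
    da, db = pair.entry_a.domain, pair.entry_b.domain
    pair_genes = {da.gene_id, db.gene_id}
    ref_len = da.n_residues
    out = []
    for e in pool:
        d = e.domain
        if e.trimmed is None or d.gene_id in pair_genes:
            continue
        if d.n_residues < params.min_len or e.coverage < params.min_coverage:
            continue
        if abs(d.n_residues - ref_len) > length_tolerance:
            continue
        if any(
            d.scop_class == p.scop_class
            or d.superfamily == p.superfamily
            or d.family == p.family
            for p in (da, db)
        ):
            continue
        out.append(e)
    return out


def align_nonparalog(
    entry: PoolEntry, ref_len: int, params: ProcessingParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Lay a non-paralog's profile alongside a reference and truncate to match.

    The candidate's trimmed raw counts are aligned from the first position
    at the 5' end, truncated at the 3' end to exactly the reference profile
    length, and then run through the identical interpolate -> smooth ->
    normalize chain as the pair profiles, so that under the null the
    competitor profile is statistically exchangeable with a pair member's.

    Raises ProfileRejection("too_short") if the candidate cannot cover the
    reference length (triggering another random selection upstream) and
    propagates "uninterpolatable" for degenerate count stretches.
    """
    if entry.trimmed is None or len(entry.trimmed.counts) < ref_len:
        have = 0 if entry.trimmed is None else len(entry.trimmed.counts)
        raise ProfileRejection("too_short", f"{have} < {ref_len}")
    values = entry.trimmed.counts[:ref_len]
    filled = interpolate_profile(values)
    return normalize_auc(smooth(filled, params.smooth_window))


def select_nonparalogs(
    pair: PairComparison,
    pool: Sequence[PoolEntry],
    n: int = 19,
    rng: np.random.Generator | None = None,
    length_tolerance: int = 25,
    params: ProcessingParams = DEFAULT_PARAMS,
    candidates: Sequence[PoolEntry] | None = None,
    cache: dict | None = None,
) -> list[tuple[PoolEntry, np.ndarray]]:
    """Randomly select ``n`` eligible non-paralogs without replacement.

    Candidates whose profile is too short to cover the pair profile are
    rejected and another selected at random.  Returns the selected entries
    with their truncated, reprocessed profiles.  Raises RuntimeError naming
    the pair if the pool is exhausted first.
    """
    rng = rng or np.random.default_rng()
    if candidates is None:
        candidates = eligible_nonparalogs(pair, pool, length_tolerance, params)
    order = rng.permutation(len(candidates))
    selected: list[tuple[PoolEntry, np.ndarray]] = []
    for i in order:
        entry = candidates[i]
        key = (entry.domain_id, pair.profile_len)
        if cache is not None and key in cache:
            truncated = cache[key]
        else:
            try:
                truncated = align_nonparalog(entry, pair.profile_len, params)
            except ProfileRejection:
                truncated = None
            if cache is not None:
                cache[key] = truncated
        if truncated is None:
            continue
        selected.append((entry, truncated))
        if len(selected) == n:
            return selected
    raise RuntimeError(
        f"pool exhausted for pair {pair.pair_id}: "
        f"{len(selected)} of {n} non-paralogs found"
    )


def rank_pair(
    pair_fsmf: float,
    nonparalog_fsmfs: Sequence[float],
    rng: np.random.Generator | None = None,
) -> int:
    """Rank of the paralogous pair among all 20 fsmf values (1 = most similar).

    Ties with non-paralog values are broken uniformly at random.
    """
    rng = rng or np.random.default_rng()
    values = np.asarray(nonparalog_fsmfs, dtype=float)
    greater = int(np.sum(values > pair_fsmf))
    ties = int(np.sum(values == pair_fsmf))
    return 1 + greater + int(rng.integers(0, ties + 1))


@dataclass
class RankTable:
    """Per-trial rank counts for a set of pairs.

    ``counts[t, r-1]`` is the number of pairs placed in rank r during trial
    t; each row sums to the number of pairs evaluated that trial.
    ``assignments[t, p]`` is pair p's rank in trial t (0 if skipped).
    """

    counts: np.ndarray
    n_pairs: int
    assignments: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_ranks(self) -> int:
        return self.counts.shape[1]

    @property
    def mean_per_rank(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def ci_halfwidth_per_rank(self) -> np.ndarray:
        """95% CI half-width from the spread over trials (normal approximation)."""
        if self.n_trials < 2:
            return np.zeros(self.n_ranks)
        sd = self.counts.std(axis=0, ddof=1)
        return 1.96 * sd / np.sqrt(self.n_trials)

    @property
    def expected_per_rank(self) -> float:
        """Expected count per rank under a uniform (random) rank distribution."""
        return self.n_pairs / self.n_ranks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.n_ranks + 1),
                "mean_count": self.mean_per_rank,
                "ci95_halfwidth": self.ci_halfwidth_per_rank,
                "expected": self.expected_per_rank,
            }
        )


def run_trials(
    pairs: Sequence[PairComparison],
    pool: Sequence[PoolEntry],
    n_trials: int = 20,
    n_competitors: int = 19,
    length_tolerance: int = 25,
    params: ProcessingParams = DEFAULT_PARAMS,
    seed: int | None = None,
) -> RankTable:
    """Rank every pair against fresh non-paralog draws in each of ``n_trials``.

    Pairs whose non-paralog pool is exhausted are skipped for that trial
    (assignment 0) rather than imputed.
    """
    n_ranks = n_competitors + 1
    counts = np.zeros((n_trials, n_ranks), dtype=np.int64)
    assignments = np.zeros((n_trials, len(pairs)), dtype=np.int64)
    candidate_cache = [
        eligible_nonparalogs(pair, pool, length_tolerance, params) for pair in pairs
    ]
    trial_seeds = _as_seedseq(seed).spawn(n_trials)
    truncation_cache: dict = {}
    for t in range(n_trials):
        rng = np.random.default_rng(trial_seeds[t])
        for p, pair in enumerate(pairs):
            try:
                chosen = select_nonparalogs(
                    pair,
                    pool,
                    n=n_competitors,
                    rng=rng,
                    length_tolerance=length_tolerance,
                    params=params,
                    candidates=candidate_cache[p],
                    cache=truncation_cache,
                )
            except RuntimeError:
                continue
            ref = pair.profile_a.values
            np_fsmfs = [fsmf(ref, truncated) for _, truncated in chosen]
            rank = rank_pair(pair.fsmf_value, np_fsmfs, rng)
            counts[t, rank - 1] += 1
            assignments[t, p] = rank
    return RankTable(counts=counts, n_pairs=len(pairs), assignments=assignments)


def random_control(
    pool: Sequence[PoolEntry],
    n_pairs: int,
    n_trials: int = 20,
    n_competitors: int = 19,
    length_tolerance: int = 25,
    params: ProcessingParams = DEFAULT_PARAMS,
    seed: int | np.random.SeedSequence | None = None,
    max_attempts_per_pair: int = 5000,
) -> tuple[RankTable, list[PairComparison]]:
    """Rank randomly chosen domain pairs through the identical machinery.

    Unlike paralogous pairs, random pairs need not share a family and no
    DNA-identity band is applied; every processing filter (gap statistics,
    trimming, minimum profile length) still is.  Rejected pairs are redrawn
    until ``n_pairs`` have been generated; unrelated sequences frequently
    fail the gap filter, so many draws per accepted pair are normal.
    """
    root = _as_seedseq(seed).spawn(2)
    rng = np.random.default_rng(root[0])
    pairs: list[PairComparison] = []
    attempts = 0
    max_attempts = max(max_attempts_per_pair * n_pairs, 100)
    while len(pairs) < n_pairs:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"random control: only {len(pairs)} of {n_pairs} pairs "
                f"after {attempts} attempts"
            )
        attempts += 1
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[int(i)], pool[int(j)]
        if a.domain.gene_id == b.domain.gene_id:
            continue
        try:
            pairs.append(compare_pair(a, b, params, compute_identity=False))
        except ProfileRejection:
            continue
    table = run_trials(
        pairs,
        pool,
        n_trials=n_trials,
        n_competitors=n_competitors,
        length_tolerance=length_tolerance,
        params=params,
        seed=root[1],
    )
    return table, pairs


def permutation_test_per_rank(
    table_a: RankTable,
    table_b: RankTable,
    n_perm: int = 1_000_000,
    alpha: float = 0.05,
    seed: int | None = None,
    batch: int = 20_000,
) -> pd.DataFrame:
    """Two-sided permutation test of per-rank mean counts between two tables.

    The statistic per rank is the absolute difference of the two groups'
    mean per-trial counts; the null is built by randomly reassigning the
    pooled trial rows to two groups of the original sizes.  P-values use
    the add-one estimator ``(1 + #{null >= observed}) / (1 + n_perm)``; no
    multiple-testing correction is applied (per-rank significance flags).
    """
    if table_a.n_trials != table_b.n_trials:
        raise ValueError("rank tables have different numbers of trials")
    if table_a.n_ranks != table_b.n_ranks:
        raise ValueError("rank tables have different numbers of ranks")
    na = table_a.n_trials
    pooled = np.vstack([table_a.counts, table_b.counts]).astype(float)
    n_rows = pooled.shape[0]
    observed = np.abs(
        table_a.counts.mean(axis=0) - table_b.counts.mean(axis=0)
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros(table_a.n_ranks, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        # each row of `orders` is a random permutation of the 2n trial rows
        orders = np.argsort(rng.random((m, n_rows)), axis=1)
        group_a = orders[:, :na]
        sums_a = pooled[group_a].sum(axis=1)
        total = pooled.sum(axis=0)
        stat = np.abs(sums_a / na - (total - sums_a) / (n_rows - na))
        exceed += (stat >= observed - 1e-12).sum(axis=0)
        done += m
    pvals = (1 + exceed) / (1 + n_perm)
    return pd.DataFrame(
        {
            "rank": np.arange(1, table_a.n_ranks + 1),
            "observed_abs_diff": observed,
            "p_value": pvals,
            "significant": pvals < alpha,
        }
    )


# ---------------------------------------------------------------------------
# Rank-group characterization


@dataclass
class RankGroupSummary:
    """Rank-1 pairs versus all other pairs, characterized for one trial."""

    pairs: pd.DataFrame
    scop_class_fractions: pd.DataFrame
    aa_composition: pd.DataFrame


def characterize_rank_groups(
    table: RankTable, pairs: Sequence[PairComparison], trial: int = 0
) -> RankGroupSummary:
    """Characterize rank-1 pairs against all other pairs for one trial.

    Produces a per-pair table (DNA identity, mean domain length, SCOP
    class, rank group), SCOP-class fractions per group, and per-amino-acid
    composition fractions per group (pooled over both members' domain
    sequences; fractions sum to one within each group).
    """
    ranks = table.assignments[trial]
    rows = []
    comp: dict[str, np.ndarray] = {
        "rank1": np.zeros(len(AMINO_ACIDS)),
        "other": np.zeros(len(AMINO_ACIDS)),
    }
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for pair, rank in zip(pairs, ranks):
        if rank == 0:
            continue
        group = "rank1" if rank == 1 else "other"
        rows.append(
            {
                "pair_id": pair.pair_id,
                "group": group,
                "rank": int(rank),
                "dna_identity": pair.dna_identity,
                "mean_length": 0.5
                * (pair.entry_a.domain.n_residues + pair.entry_b.domain.n_residues),
                "scop_class": pair.entry_a.domain.scop_class,
            }
        )
        for seq in (pair.entry_a.protein, pair.entry_b.protein):
            for ch in seq:
                comp[group][aa_index[ch]] += 1
    pair_df = pd.DataFrame(
        rows, columns=["pair_id", "group", "rank", "dna_identity", "mean_length",
                       "scop_class"]
    )
    if len(pair_df):
        class_frac = (
            pair_df.groupby("group")["scop_class"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
    else:
        class_frac = pd.DataFrame()
    comp_rows = {}
    for group, vec in comp.items():
        total = vec.sum()
        comp_rows[group] = vec / total if total > 0 else vec
    aa_df = pd.DataFrame(comp_rows, index=list(AMINO_ACIDS)).T
    return RankGroupSummary(
        pairs=pair_df, scop_class_fractions=class_frac, aa_composition=aa_df
    )
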