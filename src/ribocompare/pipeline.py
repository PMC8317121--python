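"""Configuration-driven orchestration of the full study.

simulate (or load) -> domain QC -> paralog pair selection (same family,
DNA identity within the 30-80% band) -> profile processing -> ranking
against non-paralogs over independent trials -> random-pair control ->
per-rank permutation tests -> %MinMax arm -> rank-group characterization.

Every filter's rejection tally is recorded in a manifest so the funnel from
annotated domains to the final pair count is auditable, and every source of
randomness derives from the single configured seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import align_global, percent_identity
from .codon_usage import MinMaxProfile, minmax_profile, shift_to_min_one
from .io_formats import (
    CodonUsageTable,
    DomainAnnotation,
    GeneRecord,
    build_gene_records,
    read_asite_counts,
    read_codon_usage,
    read_domain_table,
    read_fasta,
)
from .profile_processing import (
    ProcessingParams,
    ProfileRejection,
    RawDomainProfile,
    filter_domains,
    process_single,
)
from .ranking import (
    PairComparison,
    PoolEntry,
    _make_entry,
    RankTable,
    build_pool,
    characterize_rank_groups,
    compare_pair,
    permutation_test_per_rank,
    random_control,
    run_trials,
)
from .synthetic_data import SimulationConfig, SyntheticStudy, simulate_study
from .usage_data import yeast_codon_usage


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and design constants for one study run.

    Defaults are the published analysis values: DNA identity band 30-80%,
    domains >= 100 residues with >= 70% coverage, 40/20-codon gene-end
    trims, 15-codon smoothing, 50-position minimum profile, at most 10 gap
    runs none of length >= 5, 19 size-matched competitors within 25
    residues, 20 trials, and a 1e6-sample permutation test at alpha 0.05.
    """

    identity_band: tuple[float, float] = (0.30, 0.80)
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    length_tolerance: int = 25
    n_competitors: int = 19
    n_trials: int = 20
    n_perm: int = 1_000_000
    alpha: float = 0.05
    run_control: bool = True
    run_minmax: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.identity_band
        if not 0.0 < lo < hi <= 1.0:
            raise ValueError(f"identity band must lie within (0, 1], got {(lo, hi)}")
        for name in ("length_tolerance", "n_competitors", "n_trials", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class StudyInputs:
    genes: dict[str, GeneRecord]
    domains: list[DomainAnnotation]
    usage: CodonUsageTable


def load_inputs(
    cds_fasta: str | Path,
    counts_tsv: str | Path,
    domains_tsv: str | Path,
    usage_csv: str | Path | None = None,
    lengths_tsv: str | Path | None = None,
) -> StudyInputs:
    """Read a study from disk in the package's external formats."""
    counts = read_asite_counts(counts_tsv, lengths_tsv)
    genes = build_gene_records(read_fasta(cds_fasta), counts)
    domains = read_domain_table(domains_tsv, genes)
    usage = read_codon_usage(usage_csv) if usage_csv else yeast_codon_usage()
    return StudyInputs(genes=genes, domains=domains, usage=usage)


def inputs_from_simulation(study: SyntheticStudy) -> StudyInputs:
    return StudyInputs(
        genes=study.genes, domains=list(study.domains), usage=study.usage
    )


# ---------------------------------------------------------------------------
# Pair selection


def select_paralog_pairs(
    entries: Sequence[PoolEntry],
    identity_band: tuple[float, float] | None = (0.30, 0.80),
) -> tuple[list[tuple[PoolEntry, PoolEntry, float]], dict[str, int]]:
    """All unordered same-family domain pairs within the DNA identity band.

    Identity is computed from the global DNA alignment of the two domains'
    coding sequences.  Returns the retained (entry_a, entry_b, identity)
    triples and a tally of pairs rejected by the band.
    """
    by_family: dict[str, list[PoolEntry]] = {}
    for e in entries:
        by_family.setdefault(e.domain.family, []).append(e)
    selected: list[tuple[PoolEntry, PoolEntry, float]] = []
    tally = {"candidate_pairs": 0, "identity_band": 0, "same_gene": 0}
    for members in by_family.values():
        for a, b in itertools.combinations(members, 2):
            tally["candidate_pairs"] += 1
            if a.domain.gene_id == b.domain.gene_id:
                tally["same_gene"] += 1
                continue
            identity = percent_identity(align_global(a.cds, b.cds, kind="dna"))
            if identity_band is not None and not (
                identity_band[0] <= identity <= identity_band[1]
            ):
                tally["identity_band"] += 1
                continue
            selected.append((a, b, identity))
    return selected, tally


def evaluate_pairs(
    pair_entries: Sequence[tuple[PoolEntry, PoolEntry, float | None]],
    params: ProcessingParams,
) -> tuple[list[PairComparison], dict[str, int]]:
    """Run profile processing on each selected pair; tally rejections by rule."""
    pairs: list[PairComparison] = []
    tally: dict[str, int] = {}
    for a, b, identity in pair_entries:
        try:
            pair = compare_pair(a, b, params, compute_identity=False)
        except ProfileRejection as exc:
            tally[exc.rule] = tally.get(exc.rule, 0) + 1
            continue
        pair.dna_identity = identity
        pairs.append(pair)
    return pairs, tally


def prepare_study(
    inputs: StudyInputs,
    config: RunConfig = RunConfig(),
    identity_band: tuple[float, float] | None | str = "config",
) -> tuple[list[PoolEntry], list[PairComparison], dict]:
    """Domain QC, pool construction, pair selection and pair processing.

    ``identity_band="config"`` uses the configured band; pass ``None`` to
    skip the DNA-identity filter (and its alignments) for experiments where
    relatedness banding is irrelevant.  Returns the pool, the processed
    paralogous pairs and a tally dict for the manifest.
    """
    params = config.processing
    retained, rejections = filter_domains(inputs.domains, inputs.genes, params=params)
    rule_tally: dict[str, int] = {}
    for _, rule in rejections:
        rule_tally[rule] = rule_tally.get(rule, 0) + 1
    pool, pool_failures = build_pool(retained, inputs.genes, params=params)
    band = config.identity_band if identity_band == "config" else identity_band
    pair_entries, pair_tally = select_paralog_pairs(pool, band)
    pairs, eval_tally = evaluate_pairs(pair_entries, params)
    tallies = {
        "domains_annotated": len(inputs.domains),
        "domains_retained": len(retained),
        "domain_rejections": rule_tally,
        "pool_profile_failures": len(pool_failures),
        "pair_selection": pair_tally,
        "pair_processing_rejections": eval_tally,
        "pairs_final": len(pairs),
    }
    return pool, pairs, tallies


# ---------------------------------------------------------------------------
# %MinMax arm


def minmax_pool(
    entries: Sequence[PoolEntry],
    genes: Mapping[str, GeneRecord],
    usage: CodonUsageTable,
    params: ProcessingParams,
) -> list[PoolEntry]:
    """Clone pool entries with shifted %MinMax values in place of read counts.

    Each domain's per-codon %MinMax profile (window 1) over its gene is
    sliced to the domain range and shifted so its minimum is 1, making every
    position an interpolation anchor; the entries then flow through the
    identical processing and ranking machinery.
    """
    per_gene: dict[str, np.ndarray] = {}
    out: list[PoolEntry] = []
    for e in entries:
        gene = genes[e.domain.gene_id]
        if gene.gene_id not in per_gene:
            per_gene[gene.gene_id] = minmax_profile(gene.cds, usage, window=1).values
        dom = e.domain
        sliced = per_gene[gene.gene_id][dom.start_res - 1 : dom.end_res]
        shifted = shift_to_min_one(MinMaxProfile(values=sliced)).values
        raw = RawDomainProfile(
            domain_id=dom.domain_id,
            counts=shifted,
            gene_codon_indices=np.arange(dom.start_res - 1, dom.end_res),
            gene_len=gene.n_codons,
        )
        out.append(
            _make_entry(dom, raw, protein=e.protein, cds=e.cds, params=params, cov=1.0)
        )
    return out


def compare_minmax(
    pairs: Sequence[PairComparison],
    mm_entries: Sequence[PoolEntry],
    config: RunConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[RankTable, list[PairComparison]]:
    """Re-run the ranking analysis with %MinMax profiles for the same pairs."""
    by_id = {e.domain_id: e for e in mm_entries}
    mm_pairs: list[PairComparison] = []
    for pair in pairs:
        a = by_id[pair.entry_a.domain_id]
        b = by_id[pair.entry_b.domain_id]
        try:
            mm_pair = compare_pair(a, b, config.processing, compute_identity=False)
        except ProfileRejection:
            continue
        mm_pair.dna_identity = pair.dna_identity
        mm_pairs.append(mm_pair)
    table = run_trials(
        mm_pairs,
        mm_entries,
        n_trials=config.n_trials,
        n_competitors=config.n_competitors,
        length_tolerance=config.length_tolerance,
        params=config.processing,
        seed=seed,
    )
    return table, mm_pairs


def rank1_overlap(
    table_a: RankTable,
    pairs_a: Sequence[PairComparison],
    table_b: RankTable,
    pairs_b: Sequence[PairComparison],
    trial: int = 0,
) -> float:
    """Fraction of pairs rank-1 under analysis B that are also rank-1 under A.

    Used to ask how many pairs with highly conserved codon-usage profiles
    also have highly conserved occupancy profiles.
    """
    rank1_a = {
        p.pair_id
        for p, r in zip(pairs_a, table_a.assignments[trial])
        if r == 1
    }
    rank1_b = {
        p.pair_id
        for p, r in zip(pairs_b, table_b.assignments[trial])
        if r == 1
    }
    if not rank1_b:
        return float("nan")
    return len(rank1_a & rank1_b) / len(rank1_b)


# ---------------------------------------------------------------------------
# Full study


@dataclass
class StudyResult:
    pairs: list[PairComparison]
    rank_table: RankTable
    control_table: RankTable | None
    control_pairs: list[PairComparison] | None
    permutation: pd.DataFrame | None
    minmax_table: RankTable | None
    minmax_pairs: list[PairComparison] | None
    minmax_rank1_overlap: float | None
    characterization: object
    manifest: dict


def run_study(
    inputs: StudyInputs,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Execute the full comparison study; optionally write tables and manifest.

    Deterministic given ``config.seed``.  The manifest records the rejection
    tally of every filter so the funnel from annotated domains to ranked
    pairs is auditable.
    """
    params = config.processing
    ss = np.random.SeedSequence(config.seed)
    seed_rank, seed_control, seed_minmax, seed_perm = ss.spawn(4)

    pool, pairs, tallies = prepare_study(inputs, config)
    manifest: dict = {"config": _config_dict(config), "funnel": tallies}

    rank_table = run_trials(
        pairs,
        pool,
        n_trials=config.n_trials,
        n_competitors=config.n_competitors,
        length_tolerance=config.length_tolerance,
        params=params,
        seed=seed_rank,
    )

    control_table = control_pairs = permutation = None
    if config.run_control and pairs:
        control_table, control_pairs = random_control(
            pool,
            n_pairs=len(pairs),
            n_trials=config.n_trials,
            n_competitors=config.n_competitors,
            length_tolerance=config.length_tolerance,
            params=params,
            seed=seed_control,
        )
        permutation = permutation_test_per_rank(
            rank_table,
            control_table,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=np.random.default_rng(seed_perm).integers(2**31),
        )

    mm_table = mm_pairs = None
    overlap = None
    if config.run_minmax and pairs:
        mm_entries = minmax_pool(pool, inputs.genes, inputs.usage, params)
        mm_table, mm_pairs = compare_minmax(pairs, mm_entries, config, seed_minmax)
        overlap = rank1_overlap(rank_table, pairs, mm_table, mm_pairs)

    characterization = characterize_rank_groups(rank_table, pairs) if pairs else None

    result = StudyResult(
        pairs=pairs,
        rank_table=rank_table,
        control_table=control_table,
        control_pairs=control_pairs,
        permutation=permutation,
        minmax_table=mm_table,
        minmax_pairs=mm_pairs,
        minmax_rank1_overlap=overlap,
        characterization=characterization,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["processing"] = asdict(config.processing)
    return d


def _write_outputs(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(
        out_dir / "rank_counts.tsv",
        result.rank_table.counts,
        fmt="%d",
        delimiter="\t",
        header="\t".join(f"rank{r}" for r in range(1, result.rank_table.n_ranks + 1)),
        comments="",
    )
    result.rank_table.to_frame().to_csv(
        out_dir / "rank_summary.tsv", sep="\t", index=False
    )
    if result.control_table is not None:
        np.savetxt(
            out_dir / "control_counts.tsv",
            result.control_table.counts,
            fmt="%d",
            delimiter="\t",
            header="\t".join(
                f"rank{r}" for r in range(1, result.control_table.n_ranks + 1)
            ),
            comments="",
        )
        result.control_table.to_frame().to_csv(
            out_dir / "control_summary.tsv", sep="\t", index=False
        )
    if result.permutation is not None:
        result.permutation.to_csv(out_dir / "permutation.tsv", sep="\t", index=False)
    if result.minmax_table is not None:
        result.minmax_table.to_frame().to_csv(
            out_dir / "minmax_summary.tsv", sep="\t", index=False
        )
        result.manifest["minmax_rank1_overlap"] = result.minmax_rank1_overlap
    if result.characterization is not None:
        result.characterization.pairs.to_csv(
            out_dir / "rank_groups_pairs.tsv", sep="\t", index=False
        )
        result.characterization.scop_class_fractions.to_csv(
            out_dir / "rank_groups_scop.tsv", sep="\t"
        )
        result.characterization.aa_composition.to_csv(
            out_dir / "rank_groups_aa.tsv", sep="\t"
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
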