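"""Synthetic transcriptomes with paralog families of controlled similarity.

The generator emulates the statistical structure the comparison machinery is
designed to detect: families of paralogous domains share an ancestral
per-codon dwell-time profile, with a tunable correlation ``rho`` between the
paralogs' latent log-dwell vectors, while unrelated singleton domains form
the non-paralogous comparison pool.

Per family, an ancestral log-dwell vector a ~ Normal(0, sigma^2) per codon
is moving-average smoothed (window ``smooth_w``) to give the dwell signal
local autocorrelation.  Each paralog's domain log-dwell is
``rho * a + sqrt(1 - rho^2) * e`` with fresh, identically smoothed noise e,
so paralog pairs have latent correlation rho^2 (rho=1: identical profiles;
rho=0: independent).  Flanking regions receive independent noise.  Dwell is
``exp(log-dwell)``, optionally multiplied by a linear 5' ramp emulating the
elevated read density near initiation, and read counts are Poisson with
mean ``depth * dwell / mean(dwell)`` per codon (optionally Gamma-mixed for
overdispersion).

Sequences: the ancestral domain protein is uniform over the 20 amino acids;
paralogs substitute residues at the per-site rate that makes the expected
DNA identity of the back-translated domains equal ``target_dna_identity``,
with codons drawn proportionally to a supplied usage table.  There are no
indels, so paralogous domains align gaplessly and have equal length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    CodonUsageTable,
    DomainAnnotation,
    GeneRecord,
    write_asite_counts,
    write_codon_usage,
    write_domain_table,
    write_fasta,
)
from .usage_data import yeast_codon_usage

SINGLETON_CLASSES = "abcd"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic transcriptome.

    ``rho`` couples paralog log-dwell profiles to the family ancestor
    (latent pairwise correlation rho^2); ``sigma`` is the log-dwell SD;
    ``depth`` the expected reads per codon; ``ramp`` an optional
    (height, length) multiplicative 5' ramp; ``target_dna_identity`` the
    expected DNA identity between paralogous domains.
    """

    n_families: int = 50
    paralogs_per_family: int = 2
    n_singletons: int = 150
    domain_len_range: tuple[int, int] = (100, 200)
    flank_len_range: tuple[int, int] = (20, 60)
    rho: float = 0.9
    sigma: float = 0.5
    smooth_w: int = 5
    depth: float = 50.0
    ramp: tuple[float, int] | None = None
    overdispersion: float = 0.0
    target_dna_identity: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.n_singletons < 0:
            raise ValueError("n_families and n_singletons must be non-negative")
        if self.paralogs_per_family < 2:
            raise ValueError("paralogs_per_family must be >= 2")
        for name in ("domain_len_range", "flank_len_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be a non-empty range, got {(lo, hi)}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.smooth_w < 1:
            raise ValueError("smooth_w must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")
        if not 0.0 < self.target_dna_identity <= 1.0:
            raise ValueError("target_dna_identity must be in (0, 1]")
        if self.ramp is not None:
            height, length = self.ramp
            if height < 1 or length < 1:
                raise ValueError("ramp height must be >= 1 and length >= 1")


@dataclass
class GroundTruth:
    """What the generator knows: latent dwell, membership, realized similarity."""

    latent_dwell: dict[str, np.ndarray] = field(default_factory=dict)
    families: dict[str, list[str]] = field(default_factory=dict)
    pair_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    dna_identities: dict[tuple[str, str], float] = field(default_factory=dict)
    protein_identities: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    genes: dict[str, GeneRecord]
    domains: list[DomainAnnotation]
    truth: GroundTruth
    usage: CodonUsageTable
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Sequence machinery


def _usage_weights(usage: CodonUsageTable) -> dict[str, tuple[list[str], np.ndarray]]:
    out = {}
    for aa, codons in usage.synonymous_families.items():
        w = np.array([usage.frequencies[c] for c in codons], dtype=float)
        if w.sum() <= 0:
            w = np.ones(len(codons))
        out[aa] = (list(codons), w / w.sum())
    return out


def _codon_match_matrix(usage: CodonUsageTable) -> np.ndarray:
    """M[x, y]: expected fraction of matching nucleotides between codons
    independently drawn from amino acids x and y under the usage weights."""
    weights = _usage_weights(usage)
    n = len(AMINO_ACIDS)
    M = np.zeros((n, n))
    for ix, x in enumerate(AMINO_ACIDS):
        cx, px = weights[x]
        for iy, y in enumerate(AMINO_ACIDS):
            cy, py = weights[y]
            m = 0.0
            for ci, pi in zip(cx, px):
                for cj, pj in zip(cy, py):
                    matches = sum(a == b for a, b in zip(ci, cj))
                    m += pi * pj * matches / 3.0
            M[ix, iy] = m
    return M


def mutation_rate_for_identity(
    target_dna_identity: float, usage: CodonUsageTable
) -> float:
    """Per-residue substitution rate giving the requested expected DNA identity.

    Both paralogs independently substitute each ancestral residue with
    probability m (uniformly to one of the 19 other amino acids); codons are
    then sampled per paralog from the usage weights.  The expected
    per-nucleotide identity is quadratic in m and is solved exactly.
    """
    M = _codon_match_matrix(usage)
    n = len(AMINO_ACIDS)
    off_mask = ~np.eye(n, dtype=bool)
    S = float(np.mean(np.diag(M)))
    A = float(np.mean([M[z, off_mask[z]].mean() for z in range(n)]))
    B = float(
        np.mean([M[np.ix_(off_mask[z], off_mask[z])].mean() for z in range(n)])
    )
    if target_dna_identity > S + 1e-12:
        raise ValueError(
            f"target DNA identity {target_dna_identity:.3f} exceeds the maximum "
            f"{S:.3f} achievable with independent synonymous codon sampling"
        )
    # E(m) = (1-m)^2 S + 2 m (1-m) A + m^2 B
    c2, c1, c0 = S - 2 * A + B, 2 * (A - S), S - target_dna_identity
    roots = np.roots([c2, c1, c0]) if abs(c2) > 1e-15 else np.array([-c0 / c1])
    real = [float(r.real) for r in np.atleast_1d(roots) if abs(r.imag) < 1e-9]
    valid = [r for r in real if -1e-9 <= r <= 1 + 1e-9]
    if not valid:
        raise ValueError("no valid mutation rate for requested identity")
    return float(np.clip(min(valid), 0.0, 1.0))


def _sample_protein(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, len(AMINO_ACIDS), size=n)


def _mutate_protein(
    ancestor: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    out = ancestor.copy()
    hit = rng.random(len(ancestor)) < rate
    # substitute uniformly among the 19 other amino acids
    shift = rng.integers(1, len(AMINO_ACIDS), size=int(hit.sum()))
    out[hit] = (out[hit] + shift) % len(AMINO_ACIDS)
    return out


def _back_translate(
    protein_idx: np.ndarray,
    weights: Mapping[str, tuple[list[str], np.ndarray]],
    rng: np.random.Generator,
) -> str:
    codons = [""] * len(protein_idx)
    for ia, aa in enumerate(AMINO_ACIDS):
        pos = np.flatnonzero(protein_idx == ia)
        if len(pos) == 0:
            continue
        syn, p = weights[aa]
        choice = rng.choice(len(syn), size=len(pos), p=p)
        for where, which in zip(pos, choice):
            codons[where] = syn[which]
    return "".join(codons)


def _protein_string(protein_idx: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in protein_idx)


# ---------------------------------------------------------------------------
# Latent profiles and counts


def _smoothed_noise(n: int, sigma: float, w: int, rng: np.random.Generator) -> np.ndarray:
    raw = rng.normal(0.0, sigma, size=n)
    if w <= 1 or n == 0:
        return raw
    kernel = np.ones(w)
    sums = np.convolve(raw, kernel, mode="same")
    norms = np.convolve(np.ones(n), kernel, mode="same")
    return sums / norms


def _counts_from_dwell(
    dwell: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    lam = config.depth * dwell / dwell.mean()
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        lam = lam * rng.gamma(shape, scale=1.0 / shape, size=len(lam))
    return rng.poisson(lam).astype(np.int64)


def _apply_ramp(dwell: np.ndarray, ramp: tuple[float, int] | None) -> np.ndarray:
    if ramp is None:
        return dwell
    height, length = ramp
    length = min(int(length), len(dwell))
    factor = np.ones(len(dwell))
    factor[:length] = np.linspace(height, 1.0, length)
    return dwell * factor


def _hamming_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# Families and studies


def simulate_family(
    config: SimulationConfig,
    family_id: int,
    rng: np.random.Generator,
    usage: CodonUsageTable | None = None,
    scop_class: str | None = None,
) -> tuple[dict[str, GeneRecord], list[DomainAnnotation], GroundTruth]:
    """Simulate one paralog family: genes, domain annotations and ground truth."""
    usage = usage or yeast_codon_usage()
    weights = _usage_weights(usage)
    mut_rate = mutation_rate_for_identity(config.target_dna_identity, usage)
    lo, hi = config.domain_len_range
    domain_len = int(rng.integers(lo, hi + 1))
    ancestor_log = _smoothed_noise(domain_len, config.sigma, config.smooth_w, rng)
    ancestor_protein = _sample_protein(domain_len, rng)
    if scop_class is None:
        scop_class = SINGLETON_CLASSES[rng.integers(0, len(SINGLETON_CLASSES))]
    family = f"FAM{family_id:05d}"
    superfamily = f"SF{family_id:05d}"

    genes: dict[str, GeneRecord] = {}
    domains: list[DomainAnnotation] = []
    truth = GroundTruth(families={family: []})
    domain_latents: dict[str, np.ndarray] = {}
    domain_cds: dict[str, str] = {}
    flo, fhi = config.flank_len_range
    for k in range(config.paralogs_per_family):
        gene_id = f"G{family_id:05d}P{k}"
        noise = _smoothed_noise(domain_len, config.sigma, config.smooth_w, rng)
        v_domain = config.rho * ancestor_log + np.sqrt(1 - config.rho**2) * noise
        flank5 = int(rng.integers(flo, fhi + 1))
        flank3 = int(rng.integers(flo, fhi + 1))
        log_dwell = np.concatenate(
            [
                _smoothed_noise(flank5, config.sigma, config.smooth_w, rng),
                v_domain,
                _smoothed_noise(flank3, config.sigma, config.smooth_w, rng),
            ]
        )
        dwell = _apply_ramp(np.exp(log_dwell), config.ramp)
        counts = _counts_from_dwell(dwell, config, rng)

        protein_idx = np.concatenate(
            [
                _sample_protein(flank5, rng),
                _mutate_protein(ancestor_protein, mut_rate, rng),
                _sample_protein(flank3, rng),
            ]
        )
        cds = _back_translate(protein_idx, weights, rng)
        genes[gene_id] = GeneRecord(
            gene_id=gene_id,
            cds=cds,
            protein=_protein_string(protein_idx),
            counts=counts,
        )
        domains.append(
            DomainAnnotation(
                domain_id=f"{gene_id}_dom",
                gene_id=gene_id,
                start_res=flank5 + 1,
                end_res=flank5 + domain_len,
                family=family,
                superfamily=superfamily,
                scop_class=scop_class,
            )
        )
        truth.families[family].append(gene_id)
        truth.latent_dwell[gene_id] = dwell
        domain_latents[gene_id] = v_domain
        domain_cds[gene_id] = cds[flank5 * 3 : (flank5 + domain_len) * 3]

    gene_ids = list(genes)
    for i in range(len(gene_ids)):
        for j in range(i + 1, len(gene_ids)):
            gi, gj = gene_ids[i], gene_ids[j]
            corr = float(np.corrcoef(domain_latents[gi], domain_latents[gj])[0, 1])
            truth.pair_correlations[(gi, gj)] = corr
            truth.dna_identities[(gi, gj)] = _hamming_identity(
                domain_cds[gi], domain_cds[gj]
            )
            pi = genes[gi].protein
            pj = genes[gj].protein
            di = domains[i]
            dj = domains[j]
            truth.protein_identities[(gi, gj)] = _hamming_identity(
                pi[di.start_res - 1 : di.end_res], pj[dj.start_res - 1 : dj.end_res]
            )
    return genes, domains, truth


def _simulate_singleton(
    config: SimulationConfig,
    index: int,
    rng: np.random.Generator,
    usage: CodonUsageTable,
) -> tuple[dict[str, GeneRecord], list[DomainAnnotation], GroundTruth]:
    """A one-member family with its own labels; rho is irrelevant."""
    singleton_cfg = SimulationConfig(
        **{
            **asdict(config),
            "rho": 0.0,
            "paralogs_per_family": 2,  # satisfied trivially; we keep one member
        }
    )
    genes, domains, truth = simulate_family(
        singleton_cfg, family_id=100_000 + index, rng=rng, usage=usage
    )
    # keep only the first member and relabel as a singleton family
    gene_id = next(iter(genes))
    gene = genes[gene_id]
    new_gene_id = f"S{index:05d}"
    dom = domains[0]
    gene = GeneRecord(new_gene_id, gene.cds, gene.protein, gene.counts)
    dom = DomainAnnotation(
        domain_id=f"{new_gene_id}_dom",
        gene_id=new_gene_id,
        start_res=dom.start_res,
        end_res=dom.end_res,
        family=f"SFAM{index:05d}",
        superfamily=f"SSF{index:05d}",
        scop_class=dom.scop_class,
    )
    out_truth = GroundTruth(
        latent_dwell={new_gene_id: truth.latent_dwell[gene_id]},
        families={dom.family: [new_gene_id]},
    )
    return {new_gene_id: gene}, [dom], out_truth


def simulate_study(
    config: SimulationConfig, usage: CodonUsageTable | None = None
) -> SyntheticStudy:
    """Simulate ``n_families`` paralog families plus ``n_singletons`` unrelated
    singleton domains.  Deterministic given ``config.seed``: a single seed
    sequence is spawned into one child stream per family and per singleton.
    """
    usage = usage or yeast_codon_usage()
    children = np.random.SeedSequence(config.seed).spawn(
        config.n_families + config.n_singletons
    )
    genes: dict[str, GeneRecord] = {}
    domains: list[DomainAnnotation] = []
    truth = GroundTruth()
    for f in range(config.n_families):
        rng = np.random.default_rng(children[f])
        g, d, t = simulate_family(config, f, rng, usage)
        genes.update(g)
        domains.extend(d)
        truth.latent_dwell.update(t.latent_dwell)
        truth.families.update(t.families)
        truth.pair_correlations.update(t.pair_correlations)
        truth.dna_identities.update(t.dna_identities)
        truth.protein_identities.update(t.protein_identities)
    for s in range(config.n_singletons):
        rng = np.random.default_rng(children[config.n_families + s])
        g, d, t = _simulate_singleton(config, s, rng, usage)
        genes.update(g)
        domains.extend(d)
        truth.latent_dwell.update(t.latent_dwell)
        truth.families.update(t.families)
    return SyntheticStudy(
        genes=genes, domains=domains, truth=truth, usage=usage, config=config
    )


def thin_counts(
    counts: np.ndarray,
    fraction: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binomially thin a count vector: each read kept with probability ``fraction``.

    Emulates reduced sequencing depth for coverage-titration experiments.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if fraction == 1.0:
        return counts.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.binomial(counts.astype(np.int64), fraction)


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the study in the same formats the readers consume, plus a JSON
    ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta({g: r.cds for g, r in study.genes.items()}, outdir / "cds.fasta")
    write_fasta(
        {g: r.protein for g, r in study.genes.items()}, outdir / "protein.fasta"
    )
    write_asite_counts(
        {g: r.counts for g, r in study.genes.items()}, outdir / "counts.tsv"
    )
    with open(outdir / "lengths.tsv", "w") as fh:
        fh.write("gene_id\tn_codons\n")
        for g in sorted(study.genes):
            fh.write(f"{g}\t{study.genes[g].n_codons}\n")
    write_domain_table(study.domains, outdir / "domains.tsv")
    write_codon_usage(study.usage, outdir / "codon_usage.csv")
    truth = {
        "families": study.truth.families,
        "pair_correlations": {
            f"{a}|{b}": v for (a, b), v in study.truth.pair_correlations.items()
        },
        "dna_identities": {
            f"{a}|{b}": v for (a, b), v in study.truth.dna_identities.items()
        },
        "protein_identities": {
            f"{a}|{b}": v for (a, b), v in study.truth.protein_identities.items()
        },
        "latent_dwell": {g: v.tolist() for g, v in study.truth.latent_dwell.items()},
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh)
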