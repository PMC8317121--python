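"""Readers, writers and validated record types for every external format.

The pipeline exchanges four plain-text representations:

* per-codon A-site read counts: long-format TSV with columns
  ``gene_id``, ``codon_index`` (0-based), ``count``, optionally accompanied
  by a lengths sidecar TSV (``gene_id``, ``n_codons``);
* coding DNA and protein sequences: FASTA;
* domain annotations: TSV with one contiguous residue range per row and
  SCOP-style family / superfamily / class labels;
* codon usage: CSV of ``codon,frequency_per_1000`` (CoCoPUTs-style).

Only frame-0 A-site counts are represented; any frame filtering is assumed
to have been applied by the producer of the counts file.  Stop codons are
excluded from both the CDS and the count vector, so one count per codon
equals one count per protein residue.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA_ALPHABET = set("ACGT")
SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(standard_dna_table.forward_table.values())))
SCOP_CLASSES = "abcdefg"


def translate_cds(cds: str) -> str:
    """Translate a stop-free coding sequence under the standard genetic code."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    if not set(cds) <= _DNA_ALPHABET:
        bad = sorted(set(cds) - _DNA_ALPHABET)
        raise ValueError(f"CDS contains non-ACGT characters: {bad}")
    protein = str(Seq(cds).translate())
    if "*" in protein:
        raise ValueError("CDS contains an in-frame stop codon")
    return protein


@dataclass(frozen=True)
class GeneRecord:
    """One gene's coding sequence, protein and per-codon A-site counts.

    Invariants: ``len(counts) == len(cds) / 3 == len(protein)``; the CDS
    translates to ``protein`` under the standard code; counts are
    non-negative integers.  The stop codon is excluded throughout.
    """

    gene_id: str
    cds: str
    protein: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError(f"{self.gene_id}: counts must be a 1-D vector")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError(f"{self.gene_id}: counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError(f"{self.gene_id}: negative counts")
        object.__setattr__(self, "counts", counts)
        expected = translate_cds(self.cds)
        if expected != self.protein:
            raise ValueError(f"{self.gene_id}: CDS does not translate to protein")
        if len(self.counts) != len(self.protein):
            raise ValueError(
                f"{self.gene_id}: {len(self.counts)} counts for "
                f"{len(self.protein)} codons"
            )

    @classmethod
    def from_cds(cls, gene_id: str, cds: str, counts: np.ndarray) -> "GeneRecord":
        return cls(gene_id, cds, translate_cds(cds), counts)

    @property
    def n_codons(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class DomainAnnotation:
    """A contiguous residue range on a gene with SCOP-style labels.

    ``start_res`` / ``end_res`` are 1-based inclusive residue indices.
    Non-contiguous domain definitions are representable only as multiple
    rows sharing a ``domain_id`` and are rejected upstream.
    """

    domain_id: str
    gene_id: str
    start_res: int
    end_res: int
    family: str
    superfamily: str
    scop_class: str

    def __post_init__(self) -> None:
        if not 1 <= self.start_res <= self.end_res:
            raise ValueError(
                f"{self.domain_id}: invalid residue range "
                f"{self.start_res}-{self.end_res}"
            )
        if self.scop_class not in SCOP_CLASSES:
            raise ValueError(
                f"{self.domain_id}: SCOP class must be one of "
                f"{SCOP_CLASSES!r}, got {self.scop_class!r}"
            )

    @property
    def n_residues(self) -> int:
        return self.end_res - self.start_res + 1


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon usage frequencies (occurrences per 1000 codons) for one organism."""

    frequencies: Mapping[str, float]
    organism: str = "unspecified"

    def __post_init__(self) -> None:
        freqs = dict(self.frequencies)
        unknown = sorted(set(freqs) - set(SENSE_CODONS))
        if unknown:
            raise ValueError(f"unknown or stop codons in usage table: {unknown}")
        missing = sorted(set(SENSE_CODONS) - set(freqs))
        if missing:
            raise ValueError(f"usage table missing sense codons: {missing}")
        for codon, f in freqs.items():
            if f < 0:
                raise ValueError(f"negative usage frequency for {codon}")
        object.__setattr__(self, "frequencies", freqs)

    def frequency(self, codon: str) -> float:
        try:
            return self.frequencies[codon]
        except KeyError:
            raise KeyError(f"unknown codon {codon!r}") from None

    @staticmethod
    def amino_acid_of(codon: str) -> str:
        try:
            return standard_dna_table.forward_table[codon]
        except KeyError:
            raise KeyError(f"{codon!r} is not a sense codon") from None

    @cached_property
    def synonymous_families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> its sense codons (total over the 20 amino acids)."""
        fam: dict[str, list[str]] = {}
        for codon, aa in standard_dna_table.forward_table.items():
            fam.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(codons)) for aa, codons in fam.items()}

    def synonymous_codons(self, amino_acid: str) -> tuple[str, ...]:
        try:
            return self.synonymous_families[amino_acid]
        except KeyError:
            raise KeyError(f"unknown amino acid {amino_acid!r}") from None

    @cached_property
    def family_stats(self) -> dict[str, tuple[float, float, float]]:
        """Amino acid -> (max, min, mean) usage over its synonymous codons."""
        out = {}
        for aa, codons in self.synonymous_families.items():
            vals = [self.frequencies[c] for c in codons]
            out[aa] = (max(vals), min(vals), float(np.mean(vals)))
        return out


# ---------------------------------------------------------------------------
# A-site count profiles


def read_asite_counts(
    path: str | Path, lengths_path: str | Path | None = None
) -> dict[str, np.ndarray]:
    """Read long-format per-codon A-site counts into dense per-gene vectors.

    Absent codon indices are filled with zero.  Each vector's length is
    ``1 + max(codon_index)`` for that gene unless a lengths sidecar
    (TSV: gene_id, n_codons) is given, in which case the declared length is
    used and out-of-range indices are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "codon_index", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: counts TSV must have columns {sorted(required)}")
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative count at line {neg[0] + 2}")
    dup = df.duplicated(subset=["gene_id", "codon_index"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (gene_id, codon_index) at line {dup.idxmax() + 2}"
        )
    lengths: dict[str, int] | None = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", dtype={"gene_id": str})
        if not {"gene_id", "n_codons"} <= set(ldf.columns):
            raise ValueError(f"{lengths_path}: sidecar needs gene_id, n_codons")
        lengths = dict(zip(ldf["gene_id"], ldf["n_codons"].astype(int)))

    out: dict[str, np.ndarray] = {}
    for gene_id, sub in df.groupby("gene_id", sort=True):
        idx = sub["codon_index"].to_numpy(dtype=np.int64)
        if np.any(idx < 0):
            line = sub.index[idx < 0][0] + 2
            raise ValueError(f"{path}: negative codon_index at line {line}")
        if lengths is not None:
            if gene_id not in lengths:
                raise ValueError(f"{path}: gene {gene_id} missing from lengths sidecar")
            n = lengths[gene_id]
            if np.any(idx >= n):
                line = sub.index[idx >= n][0] + 2
                raise ValueError(
                    f"{path}: codon_index beyond declared length {n} at line {line}"
                )
        else:
            n = int(idx.max()) + 1
        vec = np.zeros(n, dtype=np.int64)
        vec[idx] = sub["count"].to_numpy(dtype=np.int64)
        out[gene_id] = vec
    if lengths is not None:
        for gene_id, n in lengths.items():
            out.setdefault(gene_id, np.zeros(n, dtype=np.int64))
    return out


def write_asite_counts(counts: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write dense per-gene count vectors as long-format TSV (all positions)."""
    with open(path, "w", newline="") as fh:
        fh.write("gene_id\tcodon_index\tcount\n")
        for gene_id in sorted(counts):
            for i, c in enumerate(np.asarray(counts[gene_id])):
                fh.write(f"{gene_id}\t{i}\t{int(c)}\n")


def pool_profiles(
    count_sets: Sequence[Mapping[str, np.ndarray]]
) -> dict[str, np.ndarray]:
    """Sum per-gene count vectors elementwise across experiments.

    All sets must cover the same genes at the same lengths; this is how
    reads from independent ribosome-profiling experiments are pooled into
    a single high-coverage count profile per gene.
    """
    if not count_sets:
        raise ValueError("no count sets to pool")
    reference = set(count_sets[0])
    for k, cs in enumerate(count_sets[1:], start=2):
        if set(cs) != reference:
            offenders = sorted(set(cs) ^ reference)
            raise ValueError(f"count set {k}: mismatched gene set, offenders {offenders}")
    pooled: dict[str, np.ndarray] = {}
    for gene_id in sorted(reference):
        vecs = [np.asarray(cs[gene_id], dtype=np.int64) for cs in count_sets]
        lens = {len(v) for v in vecs}
        if len(lens) > 1:
            raise ValueError(f"gene {gene_id}: mismatched lengths {sorted(lens)}")
        pooled[gene_id] = np.sum(vecs, axis=0)
    return pooled


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def build_gene_records(
    cds: Mapping[str, str], counts: Mapping[str, np.ndarray]
) -> dict[str, GeneRecord]:
    """Combine a CDS FASTA mapping with count vectors into validated records."""
    missing = sorted(set(cds) - set(counts))
    if missing:
        raise ValueError(f"genes without count vectors: {missing}")
    return {g: GeneRecord.from_cds(g, cds[g], counts[g]) for g in sorted(cds)}


# ---------------------------------------------------------------------------
# Domain tables

_DOMAIN_COLUMNS = [
    "domain_id",
    "gene_id",
    "start_res",
    "end_res",
    "family",
    "superfamily",
    "scop_class",
]


def read_domain_table(
    path: str | Path, genes: Mapping[str, GeneRecord] | None = None
) -> list[DomainAnnotation]:
    """Read a domain annotation TSV, cross-checking ranges against genes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not set(_DOMAIN_COLUMNS) <= set(df.columns):
        raise ValueError(f"{path}: domain TSV must have columns {_DOMAIN_COLUMNS}")
    domains = []
    for row in df.itertuples(index=False):
        dom = DomainAnnotation(
            domain_id=row.domain_id,
            gene_id=row.gene_id,
            start_res=int(row.start_res),
            end_res=int(row.end_res),
            family=row.family,
            superfamily=row.superfamily,
            scop_class=row.scop_class,
        )
        if genes is not None:
            if dom.gene_id not in genes:
                raise ValueError(f"{dom.domain_id}: unknown gene {dom.gene_id}")
            n = genes[dom.gene_id].n_codons
            if dom.end_res > n:
                raise ValueError(
                    f"{dom.domain_id}: range {dom.start_res}-{dom.end_res} "
                    f"outside gene of {n} codons"
                )
        domains.append(dom)
    return domains


def write_domain_table(domains: Iterable[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_DOMAIN_COLUMNS)
        for d in domains:
            writer.writerow(
                [d.domain_id, d.gene_id, d.start_res, d.end_res, d.family,
                 d.superfamily, d.scop_class]
            )


# ---------------------------------------------------------------------------
# Codon usage


def read_codon_usage(path: str | Path, organism: str = "unspecified") -> CodonUsageTable:
    df = pd.read_csv(path, dtype={"codon": str})
    if not {"codon", "frequency_per_1000"} <= set(df.columns):
        raise ValueError(f"{path}: usage CSV needs columns codon, frequency_per_1000")
    freqs = dict(zip(df["codon"].str.upper(), df["frequency_per_1000"].astype(float)))
    return CodonUsageTable(frequencies=freqs, organism=organism)


def write_codon_usage(table: CodonUsageTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("codon,frequency_per_1000\n")
        for codon in SENSE_CODONS:
            fh.write(f"{codon},{table.frequencies[codon]}\n")
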