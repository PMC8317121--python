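"""%MinMax codon-usage-bias profiles at single-codon resolution.

For a window of codons, %MinMax compares the mean usage of the codons
actually present (X_actual) against the most frequent (X_max), least
frequent (X_min) and average (X_avg) synonymous choice for the encoded
amino acids:

    value = 100 * (X_actual - X_avg) / (X_max - X_avg)   if X_actual >= X_avg
    value = -100 * (X_avg - X_actual) / (X_avg - X_min)  otherwise

so +100 means every codon is its amino acid's most common synonym and -100
the least common.  A window size of one gives the same per-codon resolution
as A-site ribosome occupancy.  Windows consisting solely of single-codon
amino acids (Met, Trp), where max = min = avg, score 0 by convention.

%Min values are negative by convention, so before profiles enter the
occupancy-comparison machinery each profile is shifted additively so its
minimum equals 1; the shift is order-preserving, so the rank-based fsmf
statistic is unchanged by it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CodonUsageTable


@dataclass(frozen=True)
class MinMaxProfile:
    """A per-window %MinMax vector, optionally shifted to a positive scale."""

    values: np.ndarray
    shifted: bool = False
    shift_constant: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) == 0:
            raise ValueError("values must be a non-empty 1-D vector")
        if self.shifted and abs(values.min() - 1.0) > 1e-9:
            raise ValueError("shifted profile minimum must equal 1")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def minmax_profile(
    cds: str, usage: CodonUsageTable, window: int = 1
) -> MinMaxProfile:
    """Compute the unshifted %MinMax profile of a coding sequence.

    With ``window=1`` the output has one value per codon; generally it has
    ``n_codons - window + 1`` values, one per sliding window.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3].upper() for i in range(0, len(cds), 3)]
    if window < 1 or window > len(codons):
        raise ValueError(f"window {window} invalid for {len(codons)} codons")
    actual = np.empty(len(codons))
    cmax = np.empty(len(codons))
    cmin = np.empty(len(codons))
    cavg = np.empty(len(codons))
    for i, codon in enumerate(codons):
        aa = CodonUsageTable.amino_acid_of(codon)  # raises on stop/unknown
        actual[i] = usage.frequency(codon)
        cmax[i], cmin[i], cavg[i] = usage.family_stats[aa]
    if window == 1:
        x_act, x_max, x_min, x_avg = actual, cmax, cmin, cavg
    else:
        kernel = np.ones(window) / window
        x_act = np.convolve(actual, kernel, mode="valid")
        x_max = np.convolve(cmax, kernel, mode="valid")
        x_min = np.convolve(cmin, kernel, mode="valid")
        x_avg = np.convolve(cavg, kernel, mode="valid")
    values = np.zeros(len(x_act))
    up = x_act >= x_avg
    span_up = x_max - x_avg
    span_dn = x_avg - x_min
    nz_up = up & (span_up > 0)
    nz_dn = ~up & (span_dn > 0)
    # ratio computed before scaling so X_actual == X_max/X_min gives exactly +/-100
    values[nz_up] = 100.0 * ((x_act[nz_up] - x_avg[nz_up]) / span_up[nz_up])
    values[nz_dn] = -100.0 * ((x_avg[nz_dn] - x_act[nz_dn]) / span_dn[nz_dn])
    return MinMaxProfile(values=values, shifted=False, shift_constant=0.0)


def shift_to_min_one(profile: MinMaxProfile) -> MinMaxProfile:
    """Apply the global additive shift that sets the profile minimum to 1."""
    shift = 1.0 - float(profile.values.min())
    return MinMaxProfile(
        values=profile.values + shift, shifted=True, shift_constant=shift
    )


def export_minmax(
    gene_id: str, raw: MinMaxProfile, shifted: MinMaxProfile, path
) -> None:
    """Write a gene's %MinMax profile as TSV (gene_id, codon_index, raw, shifted)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcodon_index\traw_value\tshifted_value\n")
        for i, (r, s) in enumerate(zip(raw.values, shifted.values)):
            fh.write(f"{gene_id}\t{i}\t{r:.10g}\t{s:.10g}\n")
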