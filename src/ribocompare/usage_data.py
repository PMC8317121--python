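"""Built-in codon usage table for Saccharomyces cerevisiae.

Representative genome-wide usage frequencies (occurrences per 1000 codons)
for budding yeast, of the kind distributed by codon-usage databases.  The
synthetic-data generator uses this table as its default when sampling
synonymous codons, and the %MinMax profile computation accepts it wherever a
:class:`~ribocompare.io_formats.CodonUsageTable` is required.  Only ratios of
frequencies within a synonymous family enter any downstream computation, so
the overall scale is irrelevant.
"""

from __future__ import annotations

from .io_formats import CodonUsageTable

_YEAST_FREQUENCIES_PER_1000 = {
    "TTT": 26.1, "TTC": 18.4, "TTA": 26.2, "TTG": 27.2,
    "CTT": 12.3, "CTC": 5.4, "CTA": 13.4, "CTG": 10.5,
    "ATT": 30.1, "ATC": 17.2, "ATA": 17.8, "ATG": 20.9,
    "GTT": 22.1, "GTC": 11.8, "GTA": 11.8, "GTG": 10.8,
    "TCT": 23.5, "TCC": 14.2, "TCA": 18.7, "TCG": 8.6,
    "AGT": 14.2, "AGC": 9.8,
    "CCT": 13.5, "CCC": 6.8, "CCA": 18.3, "CCG": 5.3,
    "ACT": 20.3, "ACC": 12.7, "ACA": 17.8, "ACG": 8.0,
    "GCT": 21.2, "GCC": 12.6, "GCA": 16.2, "GCG": 6.2,
    "TAT": 18.8, "TAC": 14.8,
    "CAT": 13.6, "CAC": 7.8,
    "CAA": 27.3, "CAG": 12.1,
    "AAT": 35.7, "AAC": 24.8,
    "AAA": 41.9, "AAG": 30.8,
    "GAT": 37.6, "GAC": 20.2,
    "GAA": 45.6, "GAG": 19.2,
    "TGT": 8.1, "TGC": 4.8, "TGG": 10.4,
    "CGT": 6.4, "CGC": 2.6, "CGA": 3.0, "CGG": 1.7,
    "AGA": 21.3, "AGG": 9.2,
    "GGT": 23.9, "GGC": 9.8, "GGA": 10.9, "GGG": 6.0,
}


def yeast_codon_usage() -> CodonUsageTable:
    """Return the built-in S. cerevisiae codon usage table."""
    return CodonUsageTable(frequencies=dict(_YEAST_FREQUENCIES_PER_1000),
                           organism="Saccharomyces cerevisiae")
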