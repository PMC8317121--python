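# ribocompare

Are ribosome occupancy profiles conserved between paralogous protein
domains?  `ribocompare` implements the full comparison machinery for
answering that question from per-codon A-site ribosome-profiling read
counts: profile processing, the fsmf tercile-agreement statistic, ranking
of paralogous domain pairs against size-matched non-paralogous domains, a
random-pair control with per-rank permutation tests, and a parallel
%MinMax codon-usage-bias analysis.  A first-class synthetic-data generator
produces paralog families with tunable profile correlation so every stage
is testable without external data.

It is aimed at researchers analysing translation-elongation dynamics from
ribo-seq data — anyone who has per-codon A-site counts, coding sequences
and domain annotations and wants to quantify whether related sequences
share translation-speed profiles.

## The statistic

A processed occupancy profile is per-codon A-site counts over a domain,
projected onto the pair's amino-acid alignment, trimmed of gene ends
(first 40 / last 20 codons), spline-interpolated over zeros and alignment
gaps, smoothed with a 15-codon moving average and normalized to unit area.
Each position is classified **f**ast / **m**edium / **s**low by whether it
falls in the bottom, middle or top third of occupancy within its profile,
and for two profiles in shared coordinates

```
fsmf = (1/L) * Σ_i  1[ label_a(i) = label_b(i) ]
```

Two independent profiles give fsmf → 1/3; identical profiles give 1.  Each
paralogous pair's fsmf is ranked against the fsmf of 19 randomly selected
non-paralogous domains (different SCOP class, superfamily and family,
length within 25 residues), so under the null hypothesis the pair's rank is
uniform on 1..20 and each rank expects `n_pairs / 20` pairs.  Enrichment at
rank 1 over 20 independent competitor draws is the evidence for profile
conservation.

## Worked example

```python
import numpy as np
from ribocompare import SimulationConfig, simulate_study, RunConfig
from ribocompare.pipeline import inputs_from_simulation, run_study

cfg = SimulationConfig(n_families=20, n_singletons=150, rho=0.9,
                       depth=100, seed=7)
inputs = inputs_from_simulation(simulate_study(cfg))
result = run_study(inputs, RunConfig(n_trials=20, n_perm=100_000, seed=1))

t = result.rank_table
print(f"pairs analysed      : {len(result.pairs)}")
print(f"mean fsmf (pairs)   : {np.mean([p.fsmf_value for p in result.pairs]):.3f}")
print(f"rank-1 mean count   : {t.mean_per_rank[0]:.2f} +/- {t.ci_halfwidth_per_rank[0]:.2f}")
print(f"expected per rank   : {t.expected_per_rank:.2f}")
print(f"control rank-1 mean : {result.control_table.mean_per_rank[0]:.2f}")
print(f"significant ranks   : {int(result.permutation.significant.sum())}/20")
```

prints

```
pairs analysed      : 19
mean fsmf (pairs)   : 0.614
rank-1 mean count   : 12.60 +/- 0.36
expected per rank   : 0.95
control rank-1 mean : 10.85
significant ranks   : 4/20
```

Twenty simulated families with strongly coupled dwell profiles (latent
correlation ρ² = 0.81) yield 19 quality-controlled pairs whose mean fsmf,
0.614, is far above the 1/3 independence level; on average 12.6 of the 19
pairs land in rank 1 versus 0.95 expected by chance.  The random-pair
control is also enriched at rank 1 — on synthetic data the control
over-captures paralogous and interpolation-heavy pairs (see
`docs/methods.md`) — and the permutation test still separates the two
arms at 4 of 20 ranks at this small study size.

The same pipeline runs from the command line on files
(FASTA + counts TSV + domain TSV) or on a fresh simulation:

```
ribocompare simulate --config study.yaml --out-dir data/
ribocompare run-all  --config study.yaml --seed 1 --out-dir out/
```

`out/` then contains the rank-count matrices, per-rank summaries with 95%
CIs, permutation p-values, rank-group characterization tables and a JSON
manifest recording every filter's rejection tally.

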