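# codonflux

Codon-resolution analysis of ribosome-profiling data, steady-state
stable-isotope tracing flux calculus, and the integration of codon
composition with proteome change.

`codonflux` is aimed at researchers studying translational
reprogramming — for instance under polyamine depletion, where ribosomes
stall selectively at codons with adenosine in the third ("wobble")
position — and at metabolism groups quantifying in vivo nutrient fluxes
from [U-¹³C] tracer infusions. It provides:

* **Ribo-seq codon analysis** (`codonflux.riboseq`): 28/29-nt footprint
  filtering, start-codon-metagene P-site offset estimation, P/A/E-site
  depth profiles, PPKM expression filtering (PPKM > 1 in every sample),
  CDS-mean normalization, codon metagenes, per-codon occupancy tables,
  the **relative dwelling occupancy** between two conditions

      RDO(c) = log2( mean_occ_a(c) / mean_occ_b(c) ),

  per-position **relative pausing tracks** log2((a+1)/(b+1)), pausing
  sums bucketed by each codon's wobble base, polyproline-tract
  detection, and per-gene third-base codon fractions.
* **Isotope tracing** (`codonflux.flux`): circulatory turnover flux
  F_circ = R·(1−L[M+C])/L[M+C], its carbon-atom analogue
  F_circ^atom = C·R·(1−L)/L with L = Σᵢ i·L[M+i]/C, normalized labeling
  L_{Y←X} = L_Y/L_X, and non-negative least-squares deconvolution of
  direct metabolite contributions, min ‖M·f − L‖ s.t. f ≥ 0, with
  bootstrap standard errors (Gaussian resampling of M and L, n = 100),
  exposed statsmodels-style as
  `SourceContributionModel(M, L).fit()` → results with `params`, `bse`,
  `summary()`. `flux_network` turns an interconversion matrix plus
  per-nutrient atom fluxes into an inter-nutrient flux edge list.
* **Integration** (`codonflux.integration`): proteomics filtering
  (≥70 % valid values in at least one group) with mixed kNN/MinProb
  imputation (kNN where a group has ≥60 % valid values; otherwise
  Gaussian draws down-shifted by 1.8 sd with width 0.2 sd), pathway-level
  codon fractions (unweighted mean over member genes), and the Pearson
  correlation of pathway A-ending-codon fraction with mean protein
  log2 fold change.
* **Synthetic data** (`codonflux.synthetic`): generators with known
  ground truth — biased transcriptomes, footprints under a
  codon-type dwell model with condition-specific stall multipliers,
  labeling vectors from a known interconversion matrix — so every
  stage has a parameter-recovery test.

## Worked example

Recover an injected wobble-A stall end to end:

```python
from codonflux import workflows

res = workflows.rdo_recovery(seed=1, n_genes=150, read_depth=1_000_000,
                             nna_multiplier=1.5)
print(f"mean RDO over A-ending codons: {res['mean_rdo_nna']:.3f}")
print(f"closed-form expectation:       {res['expected_mean_rdo_nna']:.3f}")
print(f"A-over-G rank fraction:        {res['rank_fraction_a_over_g']:.3f}")
```

prints

```
mean RDO over A-ending codons: 0.373
closed-form expectation:       0.368
A-over-G rank fraction:        1.000
```

i.e. with a 1.5× dwell multiplier on A-ending codons, the measured RDO
of the 14 sense A-ending codons averages 2^0.37 ≈ 1.3-fold (the
renormalized expectation, not 1.5, because a gene's total footprint
mass is fixed) and every sense A-ending codon ranks above every sense
G-ending codon.

The deconvolution layer:

```python
import numpy as np
from codonflux import flux

M = np.array([[1.0, 0.2], [0.3, 1.0]])   # circulating interconversion
L = np.array([0.40, 0.50])               # tissue normalized labeling
res = flux.SourceContributionModel(M, L, sources=["proline", "arginine"],
                                   target="tumour proline").fit(
    M_sd=0.01, L_sd=0.01, n_boot=100, seed=0)
print(res.summary())
```

```
Direct contributions to tumour proline
  n sources: 2   residual norm: 0   unexplained: 0.2766
  source                       f     boot SE
  proline                 0.3191      0.0123
  arginine                0.4043      0.0126
```

A command-line entry point `codonflux` wraps the main steps
(`simulate`, `psite`, `occupancy`, `rdo`, `pausing`, `codonfrac`,
`flux`, `integrate`); see `codonflux --help`.

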