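# Methods

This note describes the models and procedures implemented in
`codonflux`, the assumptions behind them, the tunable parameters, and
the numerical choices that would otherwise be invisible from the API.

## 1. Ribosome-profiling codon analysis (`codonflux.riboseq`)

### Footprint filtering and P-site assignment

Ribosome-protected fragments (RPFs) are restricted to **28 and 29 nt**
(`filter_reads`, parameter `lengths`, default `{28, 29}`), the lengths
at which mammalian monosome footprints have well-defined P-site
register. The **5′-end-to-P-site offset** is estimated per read length
from the start-codon metagene: for each candidate offset *o* in
**9–15 nt** (`search_range`), the score is the number of reads whose
5′ end plus *o* lands inside the start codon's three nucleotides; the
arg-max wins and ties resolve to **12 nt**, the canonical mammalian
offset. If a length has no reads near start codons, the estimator
falls back to 12 nt and warns. A and E sites are P ± 3 nt.

Assumption: the transcript annotation provides the CDS start within
the transcript (`TranscriptCDS.cds_start`); offset estimation is
meaningless without 5′ UTR sequence for initiation-peak reads to
map into.

### Expression filtering and normalization

Per-sample expression is **PPKM** — P-sites per kilobase of CDS per
million assigned P-sites. A gene is kept when PPKM **> 1 in every
sample** (`filter_expressed`, `threshold=1.0`, strict inequality).
Profiles are normalized to **mean 1 over the CDS**
(`normalize_profiles`), so downstream occupancies are dimensionless
enrichments relative to the gene's own average and are insensitive to
expression level.

### Codon occupancy and RDO

Per-codon-type occupancy averages the three normalized per-nucleotide
values of each codon instance, then averages over instances (each
instance equally weighted), per sample; samples are then averaged with
equal weight (`codon_occupancy`). The **relative dwelling occupancy**
between two conditions is

    RDO(c) = log2( occ_a(c) / occ_b(c) ),

with `NaN` (and a log message) for codon types absent or with zero
occupancy in either condition. Codons inside polyproline tracts can be
excluded (`exclude_polypro=True`) because eIF5A-dependent polyproline
stalling is a distinct mechanism that would otherwise contaminate
proline-codon RDOs.

Of the 64 codons, **14 sense codons end in A** (TAA and TGA are
stops) and **15 end in G**; rank statistics in the validation
workflows use these counts.

### Metagenes and pausing tracks

`metagene_codon` and `metagene_start_stop` average normalized
occupancy over a window anchored at the first nucleotide of the
anchor codon. The returned index runs **−window … window + 2** so the
anchor codon's own three positions are always included; with
`window=0` the metagene is exactly the anchor codon's mean occupancy.
Genes whose window would extend past the CDS are dropped from that
metagene (no padding).

Per-position **pausing tracks** are log2((a+1)/(b+1)) on normalized
profiles; the pseudocount keeps zero-coverage positions finite. Track
values are summed per codon and bucketed by the codon's **third
(wobble) base** (`pausing_sum_by_base`).

**Polyproline tracts** are runs of **≥ 3 consecutive proline codons**
(CCA/CCC/CCG/CCT) (`find_polypro_tracts`, `min_run=3`).

### Codon composition

`third_base_fraction` reports the fraction of codons ending in each
base; the start and stop codons are **included by default**
(`include_start_stop=True`) because published per-gene censuses count
all codons of the CDS. Pathway-level fractions are unweighted means
over member genes.

## 2. Isotope-tracing flux calculus (`codonflux.flux`)

At pseudo-steady state during a primed [U-¹³C] tracer infusion at rate
R (nmol·min⁻¹·g⁻¹), with C carbons and serum mass-isotopomer
distribution L[M+0…M+C]:

* circulatory turnover flux  **F_circ = R · (1 − L[M+C]) / L[M+C]**
  (molecule flux, from the fully labeled fraction);
* labeled-atom fraction  **L = Σᵢ i·L[M+i] / C**, and the atom-level
  flux  **F_circ^atom = C · R · (1 − L) / L** (nmol carbon·min⁻¹·g⁻¹);
* normalized labeling of metabolite Y from infused tracer X:
  **L_{Y←X} = L_Y / L_X** (serum enrichments).

### Direct-contribution deconvolution

With interconversion matrix M — entry (X, Y) = L_{Y←X}, **rows =
infused tracers**, unit diagonal — and a tissue metabolite's
normalized labeling vector L across the same tracer experiments, the
direct contribution fractions solve

    min_f ‖ M·f − L ‖₂   subject to  f ≥ 0

via `scipy.optimize.nnls`. This is exposed statsmodels-style:
`SourceContributionModel(M, L).fit()` returns a `ContributionResults`
with `params` (fractions), `resid_norm`, `unexplained = 1 − Σf`,
`bse`, and `summary()`. Standard errors come from a **parametric
bootstrap** (default `n_boot=100`): Gaussian noise of user-supplied sd
is added to M (off-diagonal only; the diagonal is 1 by construction)
and to L, entries are clipped at 0 (`clip_negative=True`), NNLS is
re-solved, and the SE is the sd (ddof = 1) over draws. Fractions are
identifiable only when M is well-conditioned; near-collinear tracer
labeling inflates bootstrap SEs, which is the intended signal.

`validate_interconversion` checks the unit diagonal and value range;
`flux_network` combines M with per-nutrient F_circ^atom values into an
inter-nutrient atom-flux edge list by solving, for each target
nutrient, the NNLS problem restricted to the other nutrients as
sources, with the right-hand side taken from the target's **column**
of M (rows are tracers).

## 3. Proteomics integration (`codonflux.integration`)

Intensities are log2-transformed. A protein is kept when it has
**≥ 70 % valid values in at least one group** (`min_valid_frac=0.7`).
Imputation is **mixed**: within each group, proteins with **≥ 60 %**
valid values in that group are imputed by kNN (`k=10`,
`sklearn.impute.KNNImputer`, fit on the group's kNN-eligible block);
the remainder are treated as missing-not-at-random and drawn per
sample from a Gaussian with **width 0.2 × sample sd** and mean
**down-shifted 1.8 × sample sd** below the sample mean (MinProb-style).
Observed values are never altered; draws are seeded.

`fraction_foldchange_correlation` reports Pearson r, p-value, slope
and intercept of pathway protein log2 fold change against pathway
A-ending-codon fraction, refusing degenerate inputs (zero range in
either variable).

## 4. Synthetic generator (`codonflux.synthetic`)

The generator emulates the **measurement process**, not the biology:

* **Transcriptomes**: per-gene-set third-base codon bias (defaults:
  a "cell_cycle_like" set with A = 0.40 and a "neuronal_like" set with
  A = 0.10 at the wobble position), CDS lengths uniform in
  `cds_length_range` (default 150–600 nt, multiples of 3), ATG start,
  random stop, no internal stops, fixed **18 nt UTRs** on both ends.
* **Dwell model**: each codon gets a multiplicative weight from
  `stall_multipliers` patterns ("NNA", "CCA", "STOP", "START", with N
  wildcards); the start codon additionally gets
  `start_multiplier=3.0`, emulating the initiation peak that real
  offset estimation relies on. Weights are **renormalized per gene**
  (w / mean w), matching the CDS-mean-normalized readout — so a 1.5×
  A-ending multiplier does *not* produce a 1.5× occupancy; the
  closed-form expectation `expected_codon_occupancy` is the oracle.
* **Footprints**: one multinomial draw of `read_depth` reads over all
  (gene, codon) cells with probability ∝ expression × length ×
  normalized weight; expression follows a log-uniform law. Reads get
  the configured length mix (28:29 = 1:1) and true offsets
  ({28: 12, 29: 12} by default).
* **Labeling**: L = M·f + Gaussian noise clipped to [0, 1], with
  off-diagonal noise on M; serum MIDs invert the F_circ formula
  exactly.

Not emulated: sequence-specific ligation/PCR bias, multimapping, UTR
ribosome occupancy, drop-off, or biological replicate variance. The
generator's defaults are the study conditions for validation; recovery
tests measure estimator correctness, not robustness to unmodeled bias.

## 5. Validation scales and numerical choices

Recovery workflows (`codonflux.workflows`) use problem sizes chosen to
make sampling noise small relative to the tested effect while keeping
the full suite under ~10 s:

* RDO recovery: 150 genes, 10⁶ P-sites per condition, 1.5× A-ending
  multiplier; criteria: perfect A-over-G rank separation and < 0.05
  log2 gap to the analytic expectation.
* Metagene signatures: 80 genes, 4 × 10⁵ P-sites; stop peak within
  10 % of expectation and > 2× baseline; CCA-specific tract response.
* Deconvolution: 3 metabolites, noise sd 0.01, 100 bootstrap draws;
  noiseless recovery < 10⁻⁸, noisy bias < 0.02, same-seed SEs
  identical.

Other numerical conventions: offset ties break to 12; PPKM threshold
is strict; RDO of zero-occupancy codons is NaN, not −inf; pausing
tracks use a +1 pseudocount; bootstrap draws clip at 0 rather than
resampling; reads that leave their transcript after offset mapping
are dropped and counted.

## 6. Known limitations

* Offset estimation needs 5′ UTR coverage; transcripts annotated
  CDS-only fall back to the 12-nt default.
* The pinned external codon-census check requires a reference CDS
  FASTA that is deliberately not bundled (see
  `tests/test_acceptance.py`); without it that single test fails.
* The NNLS deconvolution assumes the interconversion matrix is
  measured in the same physiological state as the tissue labeling;
  no correction for state mismatch is attempted.
* `flux_network` is a contract-level implementation of the edge-list
  construction; it is validated on self-consistent synthetic networks,
  not against published in vivo flux maps.
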