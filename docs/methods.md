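# Methods

## The assay being modeled

`combisort` analyzes a Sort-seq experiment over a combinatorial Golden Gate
reporter library in budding yeast. Each cassette is an ordered five-part
assembly — UAS enhancer, core promoter, 5′ UTR, fluorescent reporter, 3′ UTR —
in which 4-nt Type-IIS (BsaI) overhangs dictate the junction order
(AACG|enhancer|TGGC|promoter|TTCT|5′UTR|TATG|reporter|ATCC|3′UTR|GCTG). The
promoter part carries a 6-bp `TATGCC` suffix directly after the TGGC scar, so
assembly inserts exactly 10 bp between the enhancer and the promoter core,
the spacing optimal for enhancer-driven transcription. Cells carrying the
library are sorted by FACS into four expression fractions (none / low /
medium / high) and each fraction is sequenced; the analysis problem is to
infer per-element and per-element-pair expression from per-bin read counts.

## Parts model and combinatorial arithmetic

The emulated catalog holds 26 genes × 4 variable part classes plus one fixed
reporter. Two structural exclusions are reproduced: the HIS3 core promoter is
absent (it was never cloned), and the PHO5 and ADH1 enhancer parts carry an
internal BsaI recognition site on one strand, which destroys them during
assembly; their `usable` flag is False. Internal-site screening checks only
the combinatorial-assembly enzyme (BsaI, `GGTCTC`) on both strands — the
parts-entry enzyme is irrelevant because parts are supplied post-entry.

`enumerate_space` counts cassettes as the product of per-class part counts.
By default it counts every cloned part (26 × 25 × 26 × 26 = 439,400 — the
design space); with `usable_only=True` it counts parts that survive assembly
(24 × 25 × 26 × 26 = 405,600 — the space observable in sequencing). Library
coverage under uniform sampling with replacement is the occupancy expectation
1 − (1 − 1/N)^n, computed via `expm1`/`log1p` so it stays exact when
(1 − 1/N)^n underflows; at n = 600,000 and N = 439,400 it gives 74.5%.

Part sequences are synthetic placeholders (random A/C/G/T screened free of
incidental BsaI sites): real part boundaries are not published, and nothing
downstream depends on sequence content beyond k-mer identifiability.
Coordinates are 0-based half-open; ambiguity codes are rejected at load.

## Synthetic ground truth

Single-cell fluorescence of a construct is log-normal(log μ, σ) with

  log10 μ = log10(baseline) + e_E + e_P + e_U5 + e_U3 (+ optional E×P term)

Element effects are normal per class, median-centered, with class SDs in
log10 units chosen to encode the assay's qualitative structure: enhancers
dominate (SD 0.8), promoters modulate (SD 0.4), UTRs contribute little
(SD 0.08 each). A configurable fraction (default 15%) of enhancers is
"inactive" under the simulated growth condition and shifted −2.5 log10 —
emulating glucose-repressed genes whose cells pile into the non-expressing
fraction. The baseline μ (1,000 a.u.) puts the median construct at the
central gate. Cell-to-cell σ is deterministic per construct: the midpoint of
the configured range (default 0.4–0.8 natural-log units, typical of yeast
reporter cytometry) plus small per-element offsets, clipped to the range.

Gates default to (10², 10³, 10⁴) arbitrary units; the real instrument gates
were never published, so only the synthetic gates are meaningful. Sorting
draws each construct's bin allocation from the multinomial over the
closed-form normal-CDF bin probabilities — exactly equivalent to binning
per-cell draws, and cell-conserving by construction. Reads are drawn per bin
proportionally to construct abundance in that bin; by default read depth is
proportional to sorted cell counts, with an option to impose arbitrary per-bin
shares (e.g. the uneven 61/19/5/14% depths seen in practice). Each of the
four fragment positions is lost independently with probability d; the default
analyses use d = 1 − 0.73^(1/4) ≈ 0.0757, the rate at which 73% of reads
remain complete. Fragment loss is modeled as independent per position because
no per-fragment loss profile is available; a per-part bias would change QC
numbers but not the estimators.

What the generator does **not** emulate: nanopore base-calling errors,
chimeric/concatemeric reads, barcode cross-talk, PCR amplification bias, FACS
sorting impurity, or extrinsic day effects. Passing tests therefore show the
estimators are correct under the model's assumptions — not that those
assumptions hold for any particular instrument run. The simulated sorted-cell
shares under the defaults (~22/26/37/15%) are flatter than the strongly
skewed shares a heavily repressed real library shows; the skew can be
reproduced by lowering `baseline_mu` or raising the inactive fraction, and
the estimators are insensitive to it by design (prevalence rescales by cell
shares explicitly).

## Read processing

Reads arriving with candidate ids are passed through; raw cassette sequences
are resolved by k-mer voting with k = 15 and the requirement that a matched
k-mer be unique to one part across the whole catalog. A position with zero or
≥2 candidate parts degrades to missing rather than erroring; if the surviving
fragments are not in cassette order along the read, the read is treated as
chimeric and all its positions are dropped. k = 15 makes matching
deterministic and collision-free on the synthetic sequences (random 60–150 bp
parts share no 15-mers with overwhelming probability, and the screen enforces
uniqueness explicitly).

Tallies come in three granularities: `single_element` counts a read for every
position it carries (incomplete reads still inform the fragments they show);
`element_pair` requires both members of the pair; `full_tuple` requires all
four in order. R_b is all mapped reads in bin b regardless of completeness,
matching how the per-bin totals are reported in practice;
`complete_only_totals` restricts it for sensitivity analysis.

## Expression estimation

Prevalence: x_i,b = (r_i,b / R_b) · (C_b / Σ_b C_b) — the fragment's share of
bin b's reads, rescaled by bin b's share of sorted cells. When every read in
a tally is fully attributed, per-class column sums of x equal the cell shares
C_b/ΣC_b exactly (the conservation law the tests assert at 1e-9).

The binned log-normal fit maximizes the x-weighted multinomial log-likelihood
Σ_b w_b log p_b(μ, σ), w_b = x_i,b/Σx_i, where p_b are the four normal-CDF
integrals between the log gate boundaries. Numerical choices:

* optimization over (log μ, log σ): L-BFGS-B from a method-of-moments start
  (moments of the bin-representative log-fluorescences), polished by
  Nelder-Mead; recovers forward-generated (μ = 500, σ = 0.6) to ~1e-9
  relative.
* σ floor 0.05 log-units: finite bins cannot identify spread below gate
  resolution, and the floor prevents degenerate point-mass fits (an interior
  point mass then lands at the bin's geometric midpoint, e.g. √(A1·A2) ≈ 316).
* zero-weight bins contribute 0·log p = 0, keeping the objective finite;
  probabilities are clipped at 1e-300.
* censoring: ≥99% of mass in the bottom or top bin flags the fit censored
  low/high and pins μ at that bin's representative — the gates bound such a
  fragment but cannot locate it, and reporting an "estimate" would be
  fabrication.

The weighted-average estimator Σ_b w_b f_b uses per-bin representative
fluorescences f_b: geometric means of the gate edges for interior bins, and
the adjacent bin's log-width reflected outward for the two open bins
(f_none = A1/√(A2/A1), f_high = A3·√(A3/A2)); no representative convention is
published, and this one is scale-consistent with the gates. The two
estimators rank elements near-identically (Spearman ρ ≥ 0.95 in tests), so
either supports the rank-order analytics; the log-normal fit additionally
yields σ and the censoring flag. Class-level summaries min-max rescale log μ
to [0, 1]; an all-equal class returns 0.5 with a warning.

## Combinatorial analytics

Stacked fractions normalize each element's prevalence across bins and rank by
weighted mean (descending, ties lexicographic). Pair matrices pivot per-pair
expression into gene × gene grids with explicit NaN for unobserved pairs —
never silent zeros — and a native-pair mask. Clustering uses average linkage
on Euclidean distances of log10 rows, after dropping rows/columns with >50%
missing cells and imputing the remainder with column means; input is sorted
lexicographically first so leaf order is bit-reproducible and permutation
invariant. PCA centers features (no variance scaling — all features share one
fluorescence scale) on log10 values and uses exact SVD with a
largest-loading-positive sign convention; samples with missing cells are
dropped rather than imputed unless `impute=True` is requested. On an additive
(log-rank-1) truth with 5% multiplicative noise, PC1 carries ≥90% of the
variance by construction, which is the qualitative signature the analysis is
designed to detect.

## Arrayed-matrix and noise analytics

Percent-of-total normalization expresses each cell of a replicate-averaged
fluorescence grid as a percentage of the grid sum (output sums to 100,
invariant under uniform rescaling — the property that makes cross-day and
cross-instrument plates comparable). Replicates are averaged before
normalization; a per-replicate option exists for day-effect robustness.
Condition difference maps subtract percent-of-total grids (grand total
exactly 0; antisymmetric under argument swap) and report row/column marginal
sums, which localize condition-switched elements. Noise statistics use the
unbiased (n−1) sample variance; Fano = variance/mean, with the log-normal
closed form mean·(exp(σ²)−1) used as the analytic cross-check. Under the
default σ range every construct with mean ≥ 10 is super-Poissonian; note the
closed form dips below 1 for small means (mean·(e^0.09−1) < 1 when σ = 0.3
and mean ≤ 10.6), so sub-Poisson values at very low expression are a property
of the model, not a bug.

## Problem sizes

The default-scale simulation used throughout (100,000 clones, 100 sorted
cells per clone, 10⁶ reads) recovers enhancer rank order at Spearman
ρ ≈ 0.99 and runs in a few seconds; the shared test pipeline is scaled to
30,000 clones × 50 cells × 3×10⁵ reads, and the parameter-recovery sweep uses
200 fragments at 10⁴ effective cells each. These sizes were chosen as the
smallest at which sampling error is clearly below the effect sizes under
study.

## Known limitations

* Interaction terms beyond additive log-effects are available in the
  generator but default to zero; the estimators never assume additivity, but
  the PCA benchmarks do.
* Censored fits report a representative value, not an estimate; downstream
  rank statistics treat them like any other value, which compresses ranks
  among fully repressed elements.
* The k-mer assigner is exact-match only and is not a read aligner; it is
  correct for synthetic sequences and structured id records, not for raw
  error-prone long reads.
* Cytometry noise is purely the model's log-normal cell-to-cell variation;
  no shot noise, gating impurity or instrument floor is added.
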