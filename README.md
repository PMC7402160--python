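# combisort

Analysis pipeline for Sort-seq experiments over combinatorial Golden Gate
regulatory-element libraries in yeast.

A cassette library joins one UAS enhancer, one core promoter, one 5′ UTR and
one 3′ UTR around a fixed fluorescent reporter, with 4-nt Type-IIS overhangs
enforcing part order (26 genes → a 26 × 25 × 26 × 26 = 439,400-cassette
design space). Cells carrying the library are FACS-sorted into four
expression fractions (none/low/medium/high) and each fraction is sequenced.
`combisort` answers the downstream question: *given per-bin read counts, how
strongly does each element — and each element pair — drive expression?*

## The model

Reads r_i,b for fragment *i* in bin *b* are converted to a cell-share
prevalence using the per-bin totals of mapped reads (R_b) and sorted cells
(C_b):

    x_i,b = (r_i,b / R_b) · (C_b / Σ_b C_b)

Single-cell fluorescence of a fragment's cells is modeled as
log-normal(log μ_i, σ_i) observed only through gate membership. With gate
boundaries A1 < A2 < A3, the bin probabilities are normal-CDF integrals,
e.g. p_low = Φ((log A2 − log μ)/σ) − Φ((log A1 − log μ)/σ), and (μ_i, σ_i)
maximize the x-weighted multinomial log-likelihood Σ_b w_b log p_b(μ, σ)
with w_b = x_i,b/Σ_b x_i,b. A prevalence-weighted average over fixed per-bin
representative fluorescences provides an independent cross-check estimator.

Because the deposited raw data require external downloads, the package ships
a first-class synthetic-data module that emulates the experiment end to end
(additive log-effects with enhancer ≫ UTR spread, inactive enhancers, 4-bin
gating, per-bin reads with ~7.6% per-fragment dropout so 73% of reads stay
complete), making every stage testable against known ground truth.

## Worked example

```python
import combisort as cs

catalog = cs.default_catalog(seed=0)
print(cs.enumerate_space(catalog))                    # 439400
print(round(100 * cs.expected_coverage(600_000, 439_400), 1))  # 74.5

truth = cs.draw_effects(catalog, seed=1)
library = cs.simulate_library(truth, 100_000, seed=2)
pop = cs.simulate_sort(truth, library, cells_per_construct=100, seed=3)
reads = cs.simulate_reads(pop, 1_000_000, dropout_rate=1 - 0.73**0.25, seed=4)

counts, qc = cs.tally(reads, dict(zip(cs.BIN_LABELS, pop.cells_per_bin)))
print(round(qc.complete_fraction, 3))                 # 0.73

prev = cs.normalize_prevalence(cs.counts_for_class(counts, "enhancer"))
fits = cs.fit_all(prev)
print(fits[["mu", "sigma", "censored"]].head(3))
```

prints per-enhancer fitted means μ in arbitrary fluorescence units with
their cell-to-cell log-SD σ (here ACO1 ≈ 1603, ADH2 ≈ 4046), and flags
elements whose cells sit almost entirely in the bottom (or top) gate as
censored — CCW12 above is an inactive enhancer pinned at the bottom-bin
representative μ ≈ 31.6: the gates bound such elements but cannot locate
them. Running the numbered drivers

```
python analysis/01_simulate_library.py --seed 1
python analysis/02_count_reads.py
python analysis/03_fit_expression.py
python analysis/04_combinatorics.py
python analysis/05_matrix_noise.py --seed 1
```

reproduces the full narrative: the 439,400 design space at 74.5% expected
coverage, 73.0% complete reads, per-class element ranks recovered against
ground truth at Spearman ρ ≈ 0.95–0.99, an enhancer × promoter pair matrix
whose PC1 explains ~95–98% of the variance in both orientations, a 9×9
percent-of-total grid summing to 100 with a condition-difference map whose
row marginal flags the planted condition-switched enhancer, and an 81-construct
Fano-vs-mean curve with Spearman ρ ≈ 1.0. Tables land in `results/`.

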