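# Methods

## Estimators

All statistics are plain averages of per-SNP products of frequency
differences: `f4(A,B;C,D)` averages `(pA-pB)(pC-pD)`, with `f2` and `f3` as
the definitional special cases and `D` the same numerator normalized by the
ABBA-BABA denominator `sum (pA+pB-2 pA pB)(pC+pD-2 pC pD)`. The defaults are
deliberately the *uncorrected* sample means, so that the five linear
identities among f-statistics —

```
f4(A,B;C,D) =  f4(C,D;A,B) = -f4(B,A;C,D) = -f4(A,B;D,C)
f4(A,B;C,D) =  f4(A,C;B,D) + f4(A,D;C,B)
f4(A,B;C,D) =  f3(A;B,D) - f3(A;B,C)
```

— hold exactly (to machine precision) on any fixed panel. With four distinct
populations the plain f4 mean is unbiased. `f2` and `f3` are inflated by
finite-sample noise; the optional `bias_correction` subtracts the
heterozygosity terms `hX/nX` with `hX = pX(1-pX) nX/(nX-1)` (`nX` = observed
allele copies). It is off by default and breaks the exact identities by
design; turn it on whenever the *sign or absolute size* of f2/f3 matters,
most importantly for the three-population admixture test (see "Finite-sample
noise" below).

**Missing data.** Every statistic uses the complete-case policy: the SNPs
covered in all populations it involves. All statistics entering one analysis
(a quartet report, a basis system, a residual table) share one SNP set, since
f-statistics computed on different SNP sets are not comparable (adding fixed
sites shrinks them toward zero). A per-statistic max-overlap mode is possible
in principle but known to be unreliable and is not used anywhere.

**Monomorphic sites** are retained by default — they carry the absolute scale
of the statistics; `polymorphic_only` is available as an option.

## Block jackknife

Standard errors come from a delete-one-block weighted jackknife with
contiguous genomic blocks (default 5 Mb by position, falling back to 500-SNP
chunks without positions) and weights equal to SNPs per block, using the
weighted-jackknife variance with `h_j = W/w_j`; for equal weights this
reduces to the classic `((m-1)/m) * sum (theta_{-j} - mean)^2`. The joint
covariance `Q` of a statistic set is built from the *same* leave-one-block-out
replicates for every statistic, as a sum of scaled outer products — hence
symmetric and positive semidefinite with diagonal equal to the individual
jackknife variances. Calibration against the empirical spread over replicate
simulations is part of the test suite (ratio within ~3% at 200 replicates).

## Admixture graphs and expected f-statistics

A graph is a rooted DAG: drift edges carry lengths in f-statistic units;
an admixture node has exactly two parents with proportions `alpha`/`1-alpha`
and no drift on the incoming arrows. For each leaf, a root-ward dynamic
program accumulates the probability that a sampled lineage traverses each
drift edge (products of mixture proportions summed over ancestry routes).
Expected statistics are then linear forms with coefficients
`(wA - wB)(wC - wD)` per edge. Properties guaranteed by construction and
verified by tests:

- agreement with brute-force enumeration of every ancestry route;
- invariance under re-rooting along any drift edge;
- the admixture linearity
  `f4(A,B;C,D) = a f4(A,B;C',D) + (1-a) f4(A,B;C'',D)`, checked by grafting
  zero-length ghost leaves at the source positions;
- the identity suite holding edge-wise on the coefficients.

**Parameter counting.** `n` leaves give `n(n-1)/2` independent constraints;
a topology with `a` admixture events has `2n + 2a - 3` free parameters.
Around an admixture event with unsampled sources the three surrounding
branches enter expectations only through the compound
`alpha^2 x + (1-alpha)^2 y + z`; `count_parameters` flags the syntactic
candidates (admixed side leading to a single leaf, both sources stub nodes),
while the definitive answer — including the exceptional case where several
populations draw on the same two sources in different proportions — comes
from the numerical rank of the Jacobian of the basis-prediction map
(`identifiability_report`; SVD with singular values below `1e-9 x max`
treated as zero, evaluated at the graph's own parameters or at a seeded
random interior point to avoid measure-zero coincidences). The raw rooted
parameterization carries two known structural degeneracies that the report
lists in its null space: the two root-child edges act through their sum, and
the compound triple above.

## Fitting

The basis anchored at a base population (all `f2(base,X)` and
`f3(base;X,Y)`) spans every f-statistic on the populations, so fitting those
n(n-1)/2 numbers fits everything. The score is
`S(G) = 1/2 (g-f)' Q^{-1} (g-f)` with `diag_reg` (default `1e-4`, following
standard practice for this objective) added to the diagonal of `Q` before
the Cholesky whitening. Note the regularizer is absolute: at simulation
scales where jackknife variances are ~1e-9 it dominates `Q` and the fit
behaves like (well-scaled) least squares; smaller values preserve more of
the GLS weighting and are accepted. `lsq` mode replaces `Q` by the identity
outright; its scores are in different units and `compare_models` refuses to
mix the two.

Because `g` is linear in the branch lengths at fixed proportions, the inner
problem is solved *exactly* by active-set NNLS on the whitened system; the
outer problem over the (few) proportions uses bounded Nelder-Mead from 10
seeded restarts (first start at 0.5). Among restarts within `1e-12` of the
best score the lexicographically smallest parameter vector is returned, so
fits are reproducible even on flat score ridges (for example the
four-population single-admixture model, where any proportion in an interval
fits perfectly). Fixed parameters (for `profile_parameter` or pre-specified
proportions) are handled by pinning an alpha or moving a fixed-length
column to the data side of the NNLS.

**Residuals.** Every f2, f3 and f4 (three pairings per quartet) is compared
with its model prediction. Observed values and their SEs are exact linear
combinations of the basis vector and of `Q` — identical, for uncorrected
estimators on the shared SNP set, to direct re-estimation. The SE of
`(obs - pred)` is approximated by the SE of the observed statistic (the
prediction's sampling error is not propagated); the table is sorted by |Z|
with lexicographic tie-breaks. No Z threshold is imposed; 3 is the
conventional reporting default and is a config knob.

**Trifurcation scan.** Internal drift edges fitted below `1e-6` f-units are
reported as likely split-order misspecifications, with terminal edges, edges
incident to the root (root placement is a convention) and admixture-source
stubs (identified only through the compound) excluded, since zero length is
legitimate there.

**Model comparison** reports the score difference on an identical basis
(same base population, populations, SNP set). With equal admixture-event
counts it can be read as a log-likelihood-ratio heuristic. Chi-squared
p-values are *not* produced: the basis statistics are strongly correlated
and naive degrees-of-freedom counts are poorly calibrated; with unequal
event counts even the change in degrees of freedom is ill-defined, so only
the raw difference is reported.

## Simulator

Per SNP, a root frequency `p0` is drawn (default Uniform(0.40, 0.60)); each
drift edge of length `l` adds an independent Gaussian increment with
variance `l * p0(1-p0) / E[p0(1-p0)]`, frequencies are clipped to [0,1],
admixture nodes mix parents linearly, and leaves are observed through
binomial sampling of `2 x samples_per_pop` allele copies (default 25
diploids; `None` = noise-free frequencies). The heterozygosity scaling makes
every expected f-statistic *exactly* the path-overlap linear form — branch
lengths are in f-units by construction, not approximately — at the cost of
boundary clipping when drift is large relative to the root frequency's
distance from 0/1. The shipped fixtures keep total root-to-leaf drift near
0.02 so clipping stays below 0.1% of SNP x branch events (tested), and a
warning fires when any path exceeds 0.2.

What the simulator does **not** emulate: linkage disequilibrium within
blocks (SNPs are independent, so jackknife blocks are exactly exchangeable —
real genomes are less kind), realistic site-frequency spectra (the narrow
root law is chosen for linearity and low clipping, not realism),
ascertainment bias, sequencing error or ancient-DNA damage, and
current-frequency-dependent drift (true Wright-Fisher variance shrinks near
the boundaries; the root-frequency scaling is a small-drift approximation
made exact in expectation by design). Passing tests therefore demonstrate
the correctness of the estimators, algebra and optimizer under the model's
own assumptions, not robustness to those real-data complications.

**Fixtures.** The canned scenarios mirror the canonical study designs: a
quartet (African outgroup, western/eastern Eurasians, Native-American analog
with alpha = 0.7 eastern ancestry); a recently-admixed variant
("quartet_kyrgyz": 50/50 mixture, near-tip sources, terminal drift 0.0005 so
the corrected f3 is negative in expectation); five-population variants
adding a leaf near the eastern source (identifiable), a sister of the
western leaf (redundant, rank drops), and a swapped eastern split order
(misspecified; the connector branch collapses); and a two-event masking
graph whose second proportion is solved in closed form so one f4 permutation
has expectation exactly zero. Branch lengths and sample sizes were set once
by closed-form power analysis (expected statistic over analytic SE at 2e5
SNPs) so the qualitative Z-score orderings hold with margin while respecting
the clipping budget; they are frozen in code and are not meant to reproduce
any real population's values.

**Finite-sample noise and fitting.** Binomial sampling inflates uncorrected
f2/f3 by the heterozygosity terms. In graph fitting this inflation is
absorbed into terminal branch lengths, leaving internal structure, mixture
proportions and residual diagnostics unaffected — with one important
exception: the negative-f3 signature of recent admixture is itself a
statement about an absolute f3, so the four-population diagnosis of the
admixed population requires the bias-corrected basis
(`options=EstimatorOptions(bias_correction=True)`). The test suite exercises
both regimes.

## Numerical choices and limitations

- NNLS splits of structurally degenerate directions (root-edge pair,
  compound triples) are deterministic but arbitrary; only the identified
  combinations are meaningful. DOT output rounds lengths (x1000) to
  integers, so short-but-positive branches can display as 0.
- Nelder-Mead restarts make the outer search robust for the one-or-two
  proportion graphs in scope; graphs with many interacting events may need
  more restarts (`n_restarts`).
- Problem sizes in tests and in the acceptance script (2e5 SNPs, 100 blocks,
  25 diploids, 10 recovery seeds, 200 calibration replicates) are the
  package's chosen synthetic scale; statistics scale as expected with SNP
  count (SE ~ 1/sqrt(S), tested).
- Automated topology search, an all-SNPs missing-data mode, FST-style
  rescaling and outgroup-polymorphism filters are out of scope; the config
  reader accepts only the supported settings and rejects the rest
  explicitly.
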