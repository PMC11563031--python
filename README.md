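# admixkit

f-statistics and admixture-graph inference for population genetics.

`admixkit` is for researchers who use allele-sharing statistics to test
hypotheses about population relationships and past gene flow. It estimates
**f2, f3, f4 and D statistics** from genotype or allele-frequency data with
block-jackknife standard errors, computes **exact expected f-statistics under
admixture graphs** (phylogenies augmented with admixture events), **fits
graph parameters** by generalized least squares, and diagnoses fit quality
and parameter identifiability. A built-in allele-frequency drift simulator
regenerates the canonical four- and five-population study designs so that
every part of the tool chain is validated end to end.

## The statistics and the model

For allele frequencies `p` averaged over many biallelic SNPs,

```
f4(A,B;C,D) = E[(pA - pB)(pC - pD)]
f2(A,B)     = f4(A,B;A,B)
f3(A;B,C)   = f4(A,B;A,C)
```

`f4(A,B;C,D)` is zero in expectation when the unrooted tree `((A,B),(C,D))`
holds without admixture; a significantly negative `f3(A;B,C)` implies A is
admixed (the three-population test). Under an admixture graph with drift
edges of length `l` (in f-statistic units) and mixture proportions `alpha`,
every expected f-statistic is a linear form over edges,

```
E f4(A,B;C,D) = sum_e (w_Ae - w_Be)(w_Ce - w_De) * l_e
```

where `w_Xe` is the probability that a lineage sampled from X traverses edge
e — the weighted path-overlap picture. Fitting minimizes the score

```
S(G) = 1/2 (g - f)' Q^{-1} (g - f)
```

over `l >= 0` and `alpha in [0,1]`, where `f` is the observed vector of the
n(n-1)/2 basis statistics (all f2 and f3 anchored at a base population), `g`
the model prediction, and `Q` their block-jackknife covariance; under
multivariate-normal errors the score is a negative log-likelihood. The inner
problem in `l` is solved exactly by non-negative GLS (active-set NNLS on the
whitened system); the outer problem over the `alpha`s is a seeded multi-start
bounded search.

## Worked example

Simulate a human-like quartet — an African outgroup, western and eastern
Eurasians, and a Native-American analog ("Mixe") with 70% eastern / 30%
western Eurasian ancestry — then test the quartet and fit the graph:

```python
import admixkit as ak

spec = ak.paper_fixture("quartet_mixe", n_snps=100_000, n_blocks=100, seed=1)
panel = ak.simulate_panel(spec)

q = ak.quartet_report(panel, "Mixe", "Baka", "Han", "French")
for r in q:
    print(r)
print("admixture implied:", q.admixture_implied)
```

```
f4(Mixe,Baka,Han,French) = 0.000929944 +/- 7.96e-05 (Z = 11.68, 100000 SNPs, 100 blocks)
f4(Mixe,Han,Baka,French) = -0.000486596 +/- 7.7e-05 (Z = -6.32, 100000 SNPs, 100 blocks)
f4(Mixe,French,Baka,Han) = -0.00141654 +/- 9.03e-05 (Z = -15.69, 100000 SNPs, 100 blocks)
admixture implied: True
```

All three permutations of the quartet are significantly non-zero (|Z| > 3),
so no tree fits these four populations: at least one must be admixed.
Fitting the admixed-Mixe topology:

```python
res = ak.fit_graph(panel, spec.graph, random_state=1)
print(f"score = {res.score:.3g}")
print(f"alpha(pAM) = {res.alphas['pAM']:.3f}")

rep = ak.identifiability_report(spec.graph, seed=0)
print(f"rank {rep.rank} / {rep.n_free_formula} free parameters "
      f"-> underdetermined: {rep.underdetermined}")
```

```
score = 0
alpha(pAM) = 0.158
rank 6 / 7 free parameters -> underdetermined: True
```

The fit is perfect (score 0: all six basis statistics reproduced exactly),
but the mixture proportion is **not** the simulated 0.7 — with four
populations there are 6 constraints for 7 free parameters, so the likelihood
is flat over an interval of proportions and the reported value is one point
on that ridge, exactly what the rank report flags. Adding a fifth population
with a distinct position ("Ulchi", splitting closer to Mixe's eastern
source) makes the proportion identifiable:

```python
spec5 = ak.paper_fixture("five_ulchi", seed=1)
res5 = ak.fit_graph(ak.simulate_panel(spec5), spec5.graph, random_state=1)
print(round(res5.alphas["pAM"], 2))   # -> 0.7
```

`residual_report`, `profile_parameter`, `compare_models` and
`trifurcation_scan` provide the corresponding diagnostics: the full sorted
table of observed-vs-predicted Z-scores for every f-statistic, score
profiles for confidence intervals, score-based model comparison, and
detection of internal branches collapsed to zero length (the signature of a
misspecified split order).

## Command line

```
admixkit simulate --fixture five_ulchi --snps 200000 --blocks 100 --seed 7 --out-prefix sim
admixkit fstats --freqs sim.freqs.tsv --stat f4 --pops Mixe,Baka,Han,French --out f4
admixkit fit --freqs sim.freqs.tsv --graph sim.graph.txt --seed 3 --out-prefix fit
admixkit residuals --freqs sim.freqs.tsv --graph fit.graph.txt --out resid.tsv
admixkit identify --graph sim.graph.txt
```

Inputs are EIGENSTRAT genotype trios (`--geno/--snp/--ind`) or tab-separated
frequency tables; outputs are deterministic TSV/JSON plus graph text and
Graphviz DOT (drift lengths x1000, rounded; proportions as percentages).

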