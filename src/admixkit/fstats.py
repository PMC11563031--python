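"""f-statistic estimators with block-jackknife standard errors.

The f4-statistic f4(A,B;C,D) is the genome-wide average of
(pA - pB)(pC - pD); f2(A,B) = f4(A,B;A,B) and f3(A;B,C) = f4(A,B;A,C) are
the two- and three-population special cases, and D is the same quantity
normalized by the ABBA-BABA denominator.  Standard errors come from a
delete-one-block weighted jackknife (weights = SNPs per block), which is
robust to linkage between nearby SNPs.

All estimators use a complete-cases policy by default: each statistic is
computed on the SNPs covered in every population it involves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import FrequencyPanel, PanelError

__all__ = [
    "EstimatorOptions",
    "FStatResult",
    "QuartetReport",
    "compute_f2",
    "compute_f3",
    "compute_f4",
    "compute_d",
    "jackknife",
    "jackknife_covariance",
    "quartet_report",
]


class FStatError(ValueError):
    """Raised when a statistic cannot be computed (no sites, too few blocks...)."""


@dataclass
class EstimatorOptions:
    """Knobs shared by the f-statistic estimators.

    bias_correction
        Subtract finite-sample heterozygosity terms from f2/f3 (off by
        default so the exact f-statistic identity suite holds).
    polymorphic_only
        Drop sites fixed (0 or 1 everywhere) across the populations of the
        current analysis.  Monomorphic sites are retained by default since
        they set the absolute scale of the statistics.
    z_threshold
        |Z| above which a statistic is called significantly non-zero.
    """

    bias_correction: bool = False
    polymorphic_only: bool = False
    z_threshold: float = 3.0


@dataclass
class FStatResult:
    kind: str
    pops: tuple[str, ...]
    value: float
    se: float
    z: float
    n_snps: int
    n_blocks: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        pops = ",".join(self.pops)
        return (
            f"{self.kind}({pops}) = {self.value:.6g} +/- {self.se:.3g} "
            f"(Z = {self.z:.2f}, {self.n_snps} SNPs, {self.n_blocks} blocks)"
        )


# ---------------------------------------------------------------------------
# weighted delete-one-block jackknife
# ---------------------------------------------------------------------------


def _jackknife_se(theta: float, loo: np.ndarray, weights: np.ndarray) -> float:
    """Weighted delete-one jackknife SE from leave-one-block-out values.

    Uses the weighted-jackknife variance with h_j = W / w_j; for equal
    weights this reduces to sqrt(((m-1)/m) * sum (theta_-j - mean)^2).
    """
    w = np.asarray(weights, dtype=float)
    m = len(w)
    W = w.sum()
    h = W / w
    theta_j = m * theta - float(((1.0 - w / W) * loo).sum())
    pseudo = h * theta - (h - 1.0) * loo
    var = float(((pseudo - theta_j) ** 2 / (h - 1.0)).sum() / m)
    return float(np.sqrt(max(var, 0.0)))


def jackknife(per_block_sums: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Delete-one weighted block jackknife for a genome-wide mean.

    Parameters
    ----------
    per_block_sums
        Sum of the per-site statistic within each block.
    weights
        Number of SNPs contributing in each block.

    Returns
    -------
    (estimate, se) : the overall weighted mean and its jackknife SE.
    """
    sums = np.asarray(per_block_sums, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    sums, w = sums[keep], w[keep]
    m = len(w)
    if m < 2:
        raise FStatError(
            f"jackknife needs >= 2 non-empty blocks, got {m}; "
            "use more blocks or more data"
        )
    W = w.sum()
    theta = float(sums.sum() / W)
    loo = (sums.sum() - sums) / (W - w)
    return theta, _jackknife_se(theta, loo, w)


def _block_sums(values: np.ndarray, blocks: np.ndarray, n_blocks: int):
    sums = np.bincount(blocks, weights=values, minlength=n_blocks)
    counts = np.bincount(blocks, minlength=n_blocks).astype(float)
    return sums, counts


# ---------------------------------------------------------------------------
# per-site statistic values
# ---------------------------------------------------------------------------


def _het_correction(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """hX/nX with hX = p(1-p) n/(n-1): sampling-noise term of one population."""
    n = n.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = p * (1.0 - p) * n / (n - 1.0)
    return h / n


def _select(panel: FrequencyPanel, pops: list[str], options: EstimatorOptions):
    """Complete-case site selection; returns (freqs-per-pop, counts, mask)."""
    idx = [panel.pop_index(p) for p in pops]
    mask = panel.complete_mask(list(dict.fromkeys(pops)))
    if options.polymorphic_only:
        sub = panel.freqs[:, idx]
        fixed = np.all(sub <= 0, axis=1) | np.all(sub >= 1, axis=1)
        mask = mask & ~fixed
    if not mask.any():
        raise FStatError(
            "no overlapping sites: zero SNPs have data in all of "
            + ", ".join(dict.fromkeys(pops))
        )
    f = [panel.freqs[mask, j] for j in idx]
    c = [panel.counts[mask, j] for j in idx]
    return f, c, mask


def _finish(kind, pops, per_site, panel, mask, *, denom_per_site=None) -> FStatResult:
    blocks = panel.blocks[mask]
    nb = panel.n_blocks
    num_sums, counts = _block_sums(per_site, blocks, nb)
    keep = counts > 0
    if denom_per_site is None:
        if keep.sum() < 2:
            # single-block panel: the point estimate is defined, the SE is not
            value, se = float(num_sums.sum() / counts.sum()), float("nan")
        else:
            value, se = jackknife(num_sums[keep], counts[keep])
    else:
        den_sums, _ = _block_sums(denom_per_site, blocks, nb)
        N, D = num_sums[keep].sum(), den_sums[keep].sum()
        if D == 0:
            raise FStatError("zero denominator in D-statistic normalization")
        value = float(N / D)
        if keep.sum() < 2:
            se = float("nan")
        else:
            loo_d = D - den_sums[keep]
            if np.any(loo_d == 0):
                raise FStatError("zero denominator in a jackknife replicate")
            loo = (N - num_sums[keep]) / loo_d
            se = _jackknife_se(value, loo, counts[keep])
    if np.isnan(se):
        z = float("nan")
    else:
        z = value / se if se > 0 else 0.0
    return FStatResult(
        kind=kind,
        pops=tuple(pops),
        value=float(value),
        se=float(se),
        z=float(z),
        n_snps=int(mask.sum()),
        n_blocks=int(keep.sum()),
    )


def compute_f4(
    panel: FrequencyPanel, A: str, B: str, C: str, D: str,
    options: EstimatorOptions | None = None,
) -> FStatResult:
    """f4(A,B;C,D): mean over SNPs of (pA - pB)(pC - pD).

    With four distinct populations this plain mean is unbiased, so no
    finite-sample correction is applied.
    """
    options = options or EstimatorOptions()
    (pA, pB, pC, pD), _, mask = _select(panel, [A, B, C, D], options)
    per_site = (pA - pB) * (pC - pD)
    return _finish("f4", (A, B, C, D), per_site, panel, mask)


def compute_f2(
    panel: FrequencyPanel, A: str, B: str, options: EstimatorOptions | None = None
) -> FStatResult:
    """f2(A,B) = f4(A,B;A,B): mean of (pA - pB)^2, optionally bias-corrected."""
    options = options or EstimatorOptions()
    (pA, pB), (nA, nB), mask = _select(panel, [A, B], options)
    per_site = (pA - pB) ** 2
    if options.bias_correction:
        per_site = per_site - _het_correction(pA, nA) - _het_correction(pB, nB)
    return _finish("f2", (A, B), per_site, panel, mask)


def compute_f3(
    panel: FrequencyPanel, A: str, B: str, C: str,
    options: EstimatorOptions | None = None,
) -> FStatResult:
    """f3(A;B,C) = f4(A,B;A,C): mean of (pA - pB)(pA - pC).

    A significantly negative value (Z below -z_threshold) is direct evidence
    that A is admixed (three-population test).
    """
    options = options or EstimatorOptions()
    (pA, pB, pC), (nA, _, _), mask = _select(panel, [A, B, C], options)
    per_site = (pA - pB) * (pA - pC)
    if options.bias_correction:
        per_site = per_site - _het_correction(pA, nA)
    return _finish("f3", (A, B, C), per_site, panel, mask)


def compute_d(
    panel: FrequencyPanel, A: str, B: str, C: str, D: str,
    options: EstimatorOptions | None = None,
) -> FStatResult:
    """Normalized D-statistic (ABBA-BABA): same sign as f4, bounded scale.

    D = sum (pA-pB)(pC-pD) / sum (pA+pB-2 pA pB)(pC+pD-2 pC pD).
    """
    options = options or EstimatorOptions()
    (pA, pB, pC, pD), _, mask = _select(panel, [A, B, C, D], options)
    num = (pA - pB) * (pC - pD)
    den = (pA + pB - 2 * pA * pB) * (pC + pD - 2 * pC * pD)
    return _finish("D", (A, B, C, D), num, panel, mask, denom_per_site=den)


# ---------------------------------------------------------------------------
# joint jackknife covariance
# ---------------------------------------------------------------------------

Statistic = tuple[str, tuple[str, ...]]


def _per_site_stat(
    kind: str, pops: tuple[str, ...], freq_of, count_of=None, bias_correction: bool = False
) -> np.ndarray:
    if kind == "f2":
        a, b = pops
        out = (freq_of(a) - freq_of(b)) ** 2
        if bias_correction:
            out = out - _het_correction(freq_of(a), count_of(a)) - _het_correction(
                freq_of(b), count_of(b)
            )
        return out
    if kind == "f3":
        a, b, c = pops
        out = (freq_of(a) - freq_of(b)) * (freq_of(a) - freq_of(c))
        if bias_correction:
            out = out - _het_correction(freq_of(a), count_of(a))
        return out
    if kind == "f4":
        a, b, c, d = pops
        return (freq_of(a) - freq_of(b)) * (freq_of(c) - freq_of(d))
    raise FStatError(f"unknown statistic kind {kind!r}")


def _jackknife_multi(
    panel: FrequencyPanel,
    statistics: list[Statistic],
    options: EstimatorOptions | None = None,
):
    """Joint leave-one-block-out machinery on one common SNP set.

    Returns (estimates, Q, loo_matrix, weights, mask): Q[i, j] is the
    jackknife covariance between statistics i and j, computed from the same
    replicates for every statistic.
    """
    options = options or EstimatorOptions()
    all_pops: list[str] = []
    for _, pops in statistics:
        for p in pops:
            if p not in all_pops:
                all_pops.append(p)
    _, _, mask = _select(panel, all_pops, options)
    blocks = panel.blocks[mask]
    nb = panel.n_blocks
    cache = {p: panel.freqs[mask, panel.pop_index(p)] for p in all_pops}
    ccache = {p: panel.counts[mask, panel.pop_index(p)] for p in all_pops}
    freq_of = cache.__getitem__
    count_of = ccache.__getitem__

    K = len(statistics)
    sums = np.zeros((K, nb))
    for i, (kind, pops) in enumerate(statistics):
        per_site = _per_site_stat(
            kind, pops, freq_of, count_of, options.bias_correction
        )
        sums[i], counts = _block_sums(per_site, blocks, nb)
    keep = counts > 0
    sums = sums[:, keep]
    w = counts[keep]
    m = len(w)
    if m < 2:
        raise FStatError("jackknife needs >= 2 non-empty blocks")
    W = w.sum()
    T = sums.sum(axis=1)
    theta = T / W
    loo = (T[:, None] - sums) / (W - w)[None, :]
    h = W / w
    theta_j = m * theta - ((1.0 - w / W)[None, :] * loo).sum(axis=1)
    pseudo = h[None, :] * theta[:, None] - (h - 1.0)[None, :] * loo
    U = (pseudo - theta_j[:, None]) / np.sqrt(h - 1.0)[None, :]
    Q = U @ U.T / m
    return theta, Q, loo, w, mask


def jackknife_covariance(
    statistics: list[Statistic],
    panel: FrequencyPanel,
    options: EstimatorOptions | None = None,
) -> np.ndarray:
    """Jackknife covariance matrix Q among a set of f-statistics.

    All statistics are computed on the common complete-case SNP set and the
    identical leave-one-block-out replicates, so Q is symmetric PSD and its
    diagonal equals each statistic's jackknife variance.
    """
    _, Q, *_ = _jackknife_multi(panel, statistics, options)
    return Q


# ---------------------------------------------------------------------------
# quartet diagnostics
# ---------------------------------------------------------------------------


@dataclass
class QuartetReport:
    results: tuple[FStatResult, FStatResult, FStatResult]
    admixture_implied: bool
    z_threshold: float

    def __iter__(self):
        return iter(self.results)


def quartet_report(
    panel: FrequencyPanel, A: str, B: str, C: str, D: str,
    options: EstimatorOptions | None = None,
) -> QuartetReport:
    """All three f4 permutations of a quartet on one identical SNP set.

    If all three |Z| exceed the threshold, no permutation of the quartet is
    tree-like, so at least one of the four populations must be admixed.
    """
    options = options or EstimatorOptions()
    perms = [(A, B, C, D), (A, C, B, D), (A, D, B, C)]
    stats: list[Statistic] = [("f4", p) for p in perms]
    theta, Q, loo, w, mask = _jackknife_multi(panel, stats, options)
    results = []
    for i, pops in enumerate(perms):
        se = float(np.sqrt(max(Q[i, i], 0.0)))
        results.append(
            FStatResult(
                kind="f4",
                pops=pops,
                value=float(theta[i]),
                se=se,
                z=float(theta[i] / se) if se > 0 else 0.0,
                n_snps=int(mask.sum()),
                n_blocks=len(w),
            )
        )
    implied = all(abs(r.z) > options.z_threshold for r in results)
    return QuartetReport(tuple(results), implied, options.z_threshold)
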