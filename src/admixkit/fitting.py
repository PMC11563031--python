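"""Fitting admixture-graph parameters to observed f-statistics.

Given a basis of n(n-1)/2 f-statistics (all f2(base, X) and f3(base; X, Y)
anchored at a base population) with observed vector f and jackknife
covariance Q, the fit minimizes the generalized least-squares score

    S(G) = 1/2 (g - f)' Q^-1 (g - f)

over branch lengths l >= 0 and mixture proportions alpha in [0, 1], where g
is the model-predicted vector.  Because g is linear in the branch lengths,
the inner problem at fixed alpha is an exactly-solved non-negative GLS
(active-set NNLS on the whitened system); the outer problem over the alphas
is a bounded multi-start local search.  Under multivariate-normal errors the
score is the model's negative log-likelihood up to a constant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from sklearn.base import BaseEstimator

from .fstats import EstimatorOptions, FStatError, _jackknife_multi
from .graph import AdmixtureGraph, branch_weights, count_parameters
from .panel import FrequencyPanel

__all__ = [
    "BasisSystem",
    "FitResult",
    "AdmixtureGraphFit",
    "build_basis",
    "basis_from_graph",
    "fit_graph",
    "lsq_fit",
    "residual_report",
    "identifiability_report",
    "profile_parameter",
    "compare_models",
    "trifurcation_scan",
    "enumerate_statistics",
    "statistic_basis_coefficients",
]


class FitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------


def _basis_statistics(base: str, others: list[str]) -> list[tuple[str, tuple[str, ...]]]:
    stats: list[tuple[str, tuple[str, ...]]] = [("f2", (base, x)) for x in others]
    stats += [("f3", (base, x, y)) for x, y in itertools.combinations(others, 2)]
    return stats


@dataclass
class BasisSystem:
    """Observed basis f-statistics, their covariance, and provenance.

    The n(n-1)/2 statistics are all f2(base, X) plus all f3(base; X, Y); every
    other f-statistic on the same populations is a fixed linear combination of
    them.  ``Q`` is the raw jackknife covariance; ``Q_reg`` adds ``diag_reg``
    to the diagonal for numerical stability of the GLS weighting.
    """

    base_pop: str
    pops: list[str]  # base first
    statistics: list[tuple[str, tuple[str, ...]]]
    f_obs: np.ndarray
    Q: np.ndarray
    diag_reg: float
    n_snps: int
    n_blocks: int

    @property
    def Q_reg(self) -> np.ndarray:
        return self.Q + self.diag_reg * np.eye(len(self.f_obs))

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.Q), 0.0, None))

    def key(self) -> tuple:
        """Comparability fingerprint: same populations, base, and SNP set."""
        return (self.base_pop, tuple(self.pops), self.n_snps, self.n_blocks)


def build_basis(
    panel: FrequencyPanel,
    populations: list[str] | None = None,
    base_pop: str | None = None,
    options: EstimatorOptions | None = None,
    diag_reg: float = 1e-4,
) -> BasisSystem:
    """Estimate the basis vector and its jackknife covariance from a panel.

    All statistics are computed on the single SNP set covered in every
    population (complete cases), with uncorrected estimators so that the
    linear identities among f-statistics hold exactly.
    """
    pops = list(populations) if populations else list(panel.pop_names)
    base = base_pop or pops[0]
    if base not in pops:
        raise FitError(f"base population {base!r} not among {pops}")
    others = [p for p in pops if p != base]
    stats = _basis_statistics(base, others)
    options = options or EstimatorOptions()
    try:
        theta, Q, _, w, mask = _jackknife_multi(panel, stats, options)
    except FStatError as exc:
        raise FitError(
            f"cannot build basis: {exc}; try different populations or more data"
        ) from exc
    return BasisSystem(
        base_pop=base,
        pops=[base] + others,
        statistics=stats,
        f_obs=np.asarray(theta, dtype=float),
        Q=Q,
        diag_reg=diag_reg,
        n_snps=int(mask.sum()),
        n_blocks=len(w),
    )


def basis_from_graph(
    graph: AdmixtureGraph,
    base_pop: str | None = None,
    sigma: float = 1.0,
    diag_reg: float = 0.0,
) -> BasisSystem:
    """Exact (noise-free) basis generated from a fully parameterized graph.

    Useful for self-consistency checks: fitting the generating topology to
    this basis must reach score 0.  Q is sigma^2 * I.
    """
    pops = graph.leaves
    base = base_pop or pops[0]
    others = [p for p in pops if p != base]
    stats = _basis_statistics(base, others)
    X = _design_matrix(graph, stats, None)
    lengths = np.array([graph.lengths[e] for e in graph.edge_names], dtype=float)
    if np.any(np.isnan(lengths)):
        raise FitError("all branch lengths must be set to generate an exact basis")
    f = X @ lengths
    k = len(stats)
    return BasisSystem(
        base_pop=base,
        pops=[base] + others,
        statistics=stats,
        f_obs=f,
        Q=sigma**2 * np.eye(k),
        diag_reg=diag_reg,
        n_snps=0,
        n_blocks=0,
    )


# ---------------------------------------------------------------------------
# model side: design matrix and basis-coefficient expansion
# ---------------------------------------------------------------------------


def _design_matrix(
    graph: AdmixtureGraph,
    stats: list[tuple[str, tuple[str, ...]]],
    alphas: dict[str, float] | None,
) -> np.ndarray:
    """Rows = statistics, columns = drift edges; entries are the path-overlap
    coefficients, which depend on the mixture proportions."""
    W = branch_weights(graph, alphas)
    rows = []
    for kind, pops in stats:
        if kind == "f2":
            a, b = pops
            rows.append((W.row(a) - W.row(b)) ** 2)
        elif kind == "f3":
            a, b, c = pops
            rows.append((W.row(a) - W.row(b)) * (W.row(a) - W.row(c)))
        else:
            a, b, c, d = pops
            rows.append((W.row(a) - W.row(b)) * (W.row(c) - W.row(d)))
    return np.array(rows)


def statistic_basis_coefficients(
    kind: str, pops: tuple[str, ...], basis: BasisSystem
) -> np.ndarray:
    """Expansion of any f-statistic as a linear combination of the basis.

    Uses g(U,V) := E (pU - pbase)(pV - pbase), with g(U,U) = f2(base, U),
    g(U,V) = f3(base; U, V) and g(base, .) = 0; then
    f4(W,X;Y,Z) = g(W,Y) - g(W,Z) - g(X,Y) + g(X,Z).
    """
    index: dict[tuple[str, ...], int] = {}
    for i, (k, ps) in enumerate(basis.statistics):
        if k == "f2":
            index[(ps[1], ps[1])] = i
        else:
            index[(ps[1], ps[2])] = i
            index[(ps[2], ps[1])] = i
    vec = np.zeros(len(basis.statistics))

    def add_g(u: str, v: str, c: float) -> None:
        if u == basis.base_pop or v == basis.base_pop:
            return
        vec[index[(u, v)]] += c

    if kind == "f2":
        w, x = pops
        quads = [(w, x, w, x)]
    elif kind == "f3":
        a, b, c = pops
        quads = [(a, b, a, c)]
    elif kind == "f4":
        quads = [pops]
    else:
        raise FitError(f"unknown statistic kind {kind!r}")
    for w, x, y, z in quads:
        add_g(w, y, 1.0)
        add_g(w, z, -1.0)
        add_g(x, y, -1.0)
        add_g(x, z, 1.0)
    return vec


def enumerate_statistics(pops: list[str]) -> list[tuple[str, tuple[str, ...]]]:
    """Every f2, f3 and f4 on the populations (3 f4 pairings per quartet)."""
    ps = sorted(pops)
    out: list[tuple[str, tuple[str, ...]]] = []
    out += [("f2", pair) for pair in itertools.combinations(ps, 2)]
    for a in ps:
        rest = [p for p in ps if p != a]
        out += [("f3", (a, b, c)) for b, c in itertools.combinations(rest, 2)]
    for a, b, c, d in itertools.combinations(ps, 4):
        out += [("f4", (a, b, c, d)), ("f4", (a, c, b, d)), ("f4", (a, d, b, c))]
    return out


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a graph fit: fitted graph, GLS score, diagnostics."""

    graph: AdmixtureGraph
    score: float
    lengths: dict[str, float]
    alphas: dict[str, float]
    predicted: np.ndarray
    basis: BasisSystem
    converged: bool
    n_restarts_used: int
    lsq: bool = False
    residuals: pd.DataFrame | None = None
    identifiability: "IdentifiabilityReport | None" = None


class AdmixtureGraphFit(BaseEstimator):
    """Scikit-learn style estimator for admixture-graph parameters.

    Parameters
    ----------
    topology : AdmixtureGraph or graph-dialect text
        The fixed topology whose branch lengths and mixture proportions are
        estimated.  Provided lengths/proportions are ignored unless named in
        ``fixed``.
    base_pop : str, optional
        Base population anchoring the statistic basis (first panel
        population by default).
    diag_reg : float
        Value added to the diagonal of Q before inversion.
    lsq : bool
        Replace Q with the identity (plain least squares).  Scores from lsq
        fits are in different units and not comparable to GLS scores.
    n_restarts : int
        Multi-start count for the outer search over mixture proportions.
    random_state : int
        Seed for the restart draws.
    fixed : dict, optional
        {edge_name or admixture_child: value} parameters to pin.

    Attributes (after ``fit``)
    --------------------------
    graph_, score_, lengths_, alphas_, predicted_, basis_, residuals_,
    identifiability_, converged_, n_restarts_used_
    """

    def __init__(
        self,
        topology,
        base_pop: str | None = None,
        diag_reg: float = 1e-4,
        lsq: bool = False,
        n_restarts: int = 10,
        random_state: int = 0,
        fixed: dict | None = None,
        options: EstimatorOptions | None = None,
    ):
        self.topology = topology
        self.base_pop = base_pop
        self.diag_reg = diag_reg
        self.lsq = lsq
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.fixed = fixed
        self.options = options

    # -- internals ---------------------------------------------------------
    def _graph(self) -> AdmixtureGraph:
        if isinstance(self.topology, AdmixtureGraph):
            return self.topology
        from .graph import parse_graph

        return parse_graph(self.topology)

    def _whitener(self, basis: BasisSystem) -> np.ndarray | None:
        if self.lsq:
            return None
        try:
            return scipy.linalg.cholesky(basis.Q_reg, lower=True)
        except scipy.linalg.LinAlgError:
            raise FitError(
                "regularized covariance is singular; increase diag_reg"
            ) from None

    def _solve_lengths(self, graph, basis, L, alphas, fixed_edges):
        """Exact non-negative GLS for the branch lengths at fixed alphas."""
        X = _design_matrix(graph, basis.statistics, alphas)
        names = graph.edge_names
        f = basis.f_obs.copy()
        free_idx = []
        lengths = np.zeros(len(names))
        for j, name in enumerate(names):
            if name in fixed_edges:
                lengths[j] = fixed_edges[name]
                f -= lengths[j] * X[:, j]
            else:
                free_idx.append(j)
        A = X[:, free_idx]
        if L is not None:
            A = scipy.linalg.solve_triangular(L, A, lower=True)
            b = scipy.linalg.solve_triangular(L, f, lower=True)
        else:
            b = f
        sol, rnorm = scipy.optimize.nnls(A, b)
        lengths[free_idx] = sol
        return lengths, 0.5 * rnorm**2

    # -- sklearn surface -----------------------------------------------------
    def fit(self, X, y=None) -> "AdmixtureGraphFit":
        """Fit to a FrequencyPanel or a prebuilt BasisSystem."""
        graph = self._graph()
        if isinstance(X, BasisSystem):
            basis = X
        elif isinstance(X, FrequencyPanel):
            pops = [p for p in X.pop_names if p in set(graph.leaves)]
            basis = build_basis(
                X, populations=pops, base_pop=self.base_pop,
                options=self.options, diag_reg=self.diag_reg,
            )
        else:
            raise FitError("fit() expects a FrequencyPanel or a BasisSystem")
        if set(graph.leaves) != set(basis.pops):
            raise FitError(
                f"topology leaves {graph.leaves} do not match basis populations {basis.pops}"
            )
        fixed = dict(self.fixed or {})
        edge_names = set(graph.edge_names)
        admix_children = [a.child for a in graph.admixtures]
        fixed_edges = {k: v for k, v in fixed.items() if k in edge_names}
        fixed_alphas = {k: v for k, v in fixed.items() if k in admix_children}
        unknown = set(fixed) - set(fixed_edges) - set(fixed_alphas)
        if unknown:
            raise FitError(f"fixed parameters not in the topology: {sorted(unknown)}")
        free_alpha = [c for c in admix_children if c not in fixed_alphas]
        L = self._whitener(basis)

        def solve_at(avec: np.ndarray):
            alphas = dict(fixed_alphas)
            alphas.update({c: float(np.clip(v, 0.0, 1.0)) for c, v in zip(free_alpha, avec)})
            lengths, score = self._solve_lengths(graph, basis, L, alphas, fixed_edges)
            return alphas, lengths, score

        candidates = []
        converged = True
        n_used = 1
        if not free_alpha:
            alphas, lengths, score = solve_at(np.empty(0))
            candidates.append((score, np.empty(0), alphas, lengths))
        else:
            rng = np.random.default_rng(self.random_state)
            a = len(free_alpha)
            starts = [np.full(a, 0.5)]
            starts += list(rng.uniform(0.02, 0.98, size=(max(self.n_restarts - 1, 0), a)))
            n_used = len(starts)
            successes = []
            for x0 in starts:
                res = scipy.optimize.minimize(
                    lambda v: solve_at(v)[2],
                    x0,
                    method="Nelder-Mead",
                    bounds=[(0.0, 1.0)] * a,
                    options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
                )
                alphas, lengths, score = solve_at(res.x)
                candidates.append((score, np.clip(res.x, 0.0, 1.0), alphas, lengths))
                successes.append(bool(res.success))
            converged = any(successes)

        best_score = min(c[0] for c in candidates)
        tol = max(1e-12, 1e-9 * abs(best_score))
        ties = [c for c in candidates if c[0] <= best_score + tol]
        # reproducible tie-break: lexicographically smallest parameter vector
        ties.sort(key=lambda c: tuple(np.round(np.concatenate([c[1], c[3]]), 12)))
        score, _, alphas, lengths = ties[0]

        length_map = dict(zip(graph.edge_names, lengths.tolist()))
        self.graph_ = graph.with_params(lengths=length_map, alphas=alphas)
        self.score_ = float(score)
        self.lengths_ = length_map
        self.alphas_ = dict(alphas)
        self.predicted_ = _design_matrix(graph, basis.statistics, alphas) @ lengths
        self.basis_ = basis
        self.converged_ = converged
        self.n_restarts_used_ = n_used
        self.residuals_ = _residual_table(self.graph_, basis, self.predicted_)
        self.identifiability_ = identifiability_report(
            self.graph_, base_pop=basis.base_pop, seed=self.random_state
        )
        return self

    def predict(self, X=None) -> np.ndarray:
        """Model-predicted basis f-statistics (g) of the fitted graph."""
        if not hasattr(self, "graph_"):
            raise FitError("estimator is not fitted")
        return self.predicted_.copy()

    def score(self, X=None, y=None) -> float:
        """Negative GLS score (sklearn convention: larger is better)."""
        if not hasattr(self, "score_"):
            raise FitError("estimator is not fitted")
        return -self.score_

    def result(self) -> FitResult:
        if not hasattr(self, "graph_"):
            raise FitError("estimator is not fitted")
        return FitResult(
            graph=self.graph_,
            score=self.score_,
            lengths=self.lengths_,
            alphas=self.alphas_,
            predicted=self.predicted_,
            basis=self.basis_,
            converged=self.converged_,
            n_restarts_used=self.n_restarts_used_,
            lsq=self.lsq,
            residuals=self.residuals_,
            identifiability=self.identifiability_,
        )


def fit_graph(
    basis: BasisSystem | FrequencyPanel,
    topology: AdmixtureGraph | str,
    **kwargs,
) -> FitResult:
    """Minimize the GLS score of a topology against observed statistics."""
    est = AdmixtureGraphFit(topology, **kwargs)
    return est.fit(basis).result()


def lsq_fit(
    basis: BasisSystem | FrequencyPanel,
    topology: AdmixtureGraph | str,
    **kwargs,
) -> FitResult:
    """Plain least-squares fit (Q replaced by the identity).

    Correlated statistics are treated as independent and the score is not a
    log-likelihood, so GLS fitting is generally preferable; lsq scores are
    not comparable to GLS scores.
    """
    kwargs.pop("lsq", None)
    est = AdmixtureGraphFit(topology, lsq=True, **kwargs)
    return est.fit(basis).result()


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------


def _residual_table(graph: AdmixtureGraph, basis: BasisSystem, predicted_basis: np.ndarray) -> pd.DataFrame:
    stats = enumerate_statistics(basis.pops)
    lengths = np.array([graph.lengths[e] for e in graph.edge_names], dtype=float)
    Xall = _design_matrix(graph, stats, None)
    predicted = Xall @ lengths
    M = np.array([statistic_basis_coefficients(k, p, basis) for k, p in stats])
    observed = M @ basis.f_obs
    var = np.einsum("ij,jk,ik->i", M, basis.Q, M)
    se = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (observed - predicted) / se, 0.0)
    df = pd.DataFrame(
        {
            "kind": [k for k, _ in stats],
            "pops": [",".join(p) for _, p in stats],
            "observed": observed,
            "predicted": predicted,
            "se": se,
            "z": z,
        }
    )
    df["abs_z"] = df["z"].abs()
    df = df.sort_values(["abs_z", "kind", "pops"], ascending=[False, True, True]).drop(
        columns="abs_z"
    )
    return df.reset_index(drop=True)


def residual_report(
    fit: FitResult | AdmixtureGraphFit,
    panel: FrequencyPanel | None = None,
    options: EstimatorOptions | None = None,
) -> pd.DataFrame:
    """Observed vs predicted for every f2, f3 and f4 on the populations.

    Observed values and their SEs are exact linear combinations of the basis
    vector and its jackknife covariance (identical SNP set, uncorrected
    estimators), sorted by |Z| descending with lexicographic tie-breaks.
    The panel argument is accepted for interface compatibility; the basis
    carries everything needed.
    """
    if isinstance(fit, AdmixtureGraphFit):
        fit = fit.result()
    if fit.residuals is not None:
        return fit.residuals
    return _residual_table(fit.graph, fit.basis, fit.predicted)


# ---------------------------------------------------------------------------
# identifiability
# ---------------------------------------------------------------------------


@dataclass
class IdentifiabilityReport:
    """Numerical-rank analysis of the basis-prediction map.

    ``rank`` is the rank of the Jacobian of the predicted basis vector with
    respect to all raw parameters (every drift-edge length plus every mixture
    proportion) at the evaluation point.  ``n_free_formula`` is the model's
    2n + 2a - 3 count; ``underdetermined`` flags rank < that count.  The raw
    parameterization carries known structural degeneracies (the two root-edge
    lengths enter only through their sum; around an admixture event with
    unsampled sources only the compound a^2 x + (1-a)^2 y + z is constrained),
    which appear in ``null_space``.
    """

    param_names: list[str]
    point: dict[str, float]
    rank: int
    n_parameters: int
    n_constraints: int
    n_free_formula: int
    underdetermined: bool
    null_space: list[str] = field(default_factory=list)
    compound_candidates: list[str] = field(default_factory=list)
    singular_values: np.ndarray | None = None


def identifiability_report(
    topology: AdmixtureGraph,
    at: dict[str, float] | None = None,
    seed: int = 0,
    base_pop: str | None = None,
    rank_tol: float = 1e-9,
) -> IdentifiabilityReport:
    """Jacobian rank of the basis-prediction map at a parameter point.

    The point comes from ``at`` overrides, then the graph's own values, then
    seeded random interior draws (avoiding measure-zero coincidences).
    """
    rng = np.random.default_rng(seed)
    at = at or {}
    pops = topology.leaves
    base = base_pop or pops[0]
    others = [p for p in pops if p != base]
    stats = _basis_statistics(base, others)

    lengths = {}
    for name, l in topology.lengths.items():
        lengths[name] = float(at.get(name, l if l is not None else rng.uniform(0.002, 0.05)))
    alphas = {}
    for child, a in topology.alphas.items():
        alphas[child] = float(at.get(child, a if a is not None else rng.uniform(0.2, 0.8)))

    edge_names = topology.edge_names
    lvec = np.array([lengths[e] for e in edge_names])
    cols = []
    X = _design_matrix(topology, stats, alphas)
    for j in range(len(edge_names)):
        cols.append(X[:, j])
    h = 1e-6
    for child in alphas:
        up = dict(alphas, **{child: min(alphas[child] + h, 1.0)})
        dn = dict(alphas, **{child: max(alphas[child] - h, 0.0)})
        gu = _design_matrix(topology, stats, up) @ lvec
        gd = _design_matrix(topology, stats, dn) @ lvec
        cols.append((gu - gd) / (up[child] - dn[child]))
    J = np.column_stack(cols)
    names = edge_names + [f"alpha:{c}" for c in alphas]

    U, s, Vt = np.linalg.svd(J, full_matrices=True)
    tol = rank_tol * (s[0] if len(s) else 1.0)
    rank = int((s > tol).sum())
    null = []
    for k in range(rank, Vt.shape[0]):
        v = Vt[k]
        terms = [
            f"{v[i]:+.3f}*{names[i]}" for i in np.argsort(-np.abs(v)) if abs(v[i]) > 1e-6
        ]
        null.append(" ".join(terms[:6]))
    counts = count_parameters(topology)
    return IdentifiabilityReport(
        param_names=names,
        point={**lengths, **{f"alpha:{c}": v for c, v in alphas.items()}},
        rank=rank,
        n_parameters=len(names),
        n_constraints=counts.n_constraints,
        n_free_formula=counts.n_free_parameters,
        underdetermined=rank < counts.n_free_parameters,
        null_space=null,
        compound_candidates=counts.compound_reductions,
        singular_values=s,
    )


# ---------------------------------------------------------------------------
# profiling, comparison, trifurcation scan
# ---------------------------------------------------------------------------


@dataclass
class ProfileResult:
    parameter: str
    grid: np.ndarray
    scores: np.ndarray
    fits: list[FitResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.parameter: self.grid, "score": self.scores})


def profile_parameter(
    basis: BasisSystem,
    topology: AdmixtureGraph | str,
    parameter: str,
    grid,
    **kwargs,
) -> ProfileResult:
    """Score profile of one parameter: refit everything else at each value.

    A score-flat stretch of the profile is a non-identifiable interval; the
    minimum over the grid can never fall below the unconstrained optimum.
    """
    est = AdmixtureGraphFit(topology, **kwargs)
    graph = est._graph()
    if parameter not in set(graph.edge_names) and parameter not in {
        a.child for a in graph.admixtures
    }:
        raise FitError(
            f"no parameter named {parameter!r} (edges: {graph.edge_names}, "
            f"admixture nodes: {[a.child for a in graph.admixtures]})"
        )
    grid = np.asarray(list(grid), dtype=float)
    scores = np.empty(len(grid))
    fits = []
    fixed0 = dict(kwargs.pop("fixed", None) or {})
    for i, v in enumerate(grid):
        r = fit_graph(basis, topology, fixed={**fixed0, parameter: float(v)}, **kwargs)
        scores[i] = r.score
        fits.append(r)
    return ProfileResult(parameter=parameter, grid=grid, scores=scores, fits=fits)


@dataclass
class ModelComparison:
    score_a: float
    score_b: float
    delta: float
    preferred: str
    same_n_admixture: bool
    note: str


def compare_models(fit_a: FitResult, fit_b: FitResult) -> ModelComparison:
    """Score-based comparison of two fits on the identical basis.

    With equal admixture-event counts the score difference can be read as a
    log-likelihood-ratio heuristic; naive chi-squared p-values on these
    correlated statistics are poorly calibrated and are not produced.
    """
    if fit_a.lsq != fit_b.lsq:
        raise FitError("cannot compare a GLS fit with an lsq fit (different score units)")
    if fit_a.basis.key() != fit_b.basis.key():
        raise FitError(
            "fits use different bases (base population, populations or SNP set); "
            "scores are not comparable"
        )
    same_a = fit_a.graph.n_admixture == fit_b.graph.n_admixture
    delta = fit_a.score - fit_b.score
    note = (
        "equal admixture-event counts: interpret the score difference as a "
        "log-likelihood-ratio heuristic"
        if same_a
        else "unequal admixture-event counts: the effective change in degrees of "
        "freedom is not well defined; difference reported without a test"
    )
    return ModelComparison(
        score_a=fit_a.score,
        score_b=fit_b.score,
        delta=delta,
        preferred="A" if fit_a.score <= fit_b.score else "B",
        same_n_admixture=same_a,
        note=note,
    )


TRIFURCATION_ADVICE = (
    "internal branch fit at (near) zero length: the split order is likely "
    "misspecified; adjust the order of splits and re-try"
)


def trifurcation_scan(
    fit: FitResult | AdmixtureGraph, tolerance: float = 1e-6
) -> list[tuple[str, float]]:
    """Internal drift edges whose fitted length collapsed below tolerance.

    Terminal edges, edges incident to the root (root placement is a
    convention, not a split), and admixture-source stub edges (identified
    only through the compound parameter) are excluded.
    """
    graph = fit.graph if isinstance(fit, FitResult) else fit
    admix_children = {a.child for a in graph.admixtures}
    out = []
    for e in graph.edges:
        if e.parent == graph.root:
            continue
        kids = graph.children(e.child)
        if not kids:  # terminal
            continue
        if all(k in admix_children for k in kids):  # source stub
            continue
        if e.length is not None and e.length < tolerance:
            out.append((e.name, float(e.length)))
    return out
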