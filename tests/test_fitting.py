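"""Basis systems, GLS fitting, residuals, identifiability, profiles."""

import numpy as np
import pytest

from admixkit import (
    AdmixtureGraph,
    AdmixtureGraphFit,
    basis_from_graph,
    build_basis,
    compare_models,
    compute_f4,
    count_parameters,
    expected_f4,
    fit_graph,
    identifiability_report,
    lsq_fit,
    paper_fixture,
    profile_parameter,
    residual_report,
    simulate_panel,
    trifurcation_scan,
)
from admixkit.fitting import FitError, statistic_basis_coefficients

from conftest import random_panel


@pytest.fixture(scope="module")
def mixe_basis():
    panel = simulate_panel(paper_fixture("quartet_mixe", n_snps=30_000, n_blocks=30, seed=8))
    return build_basis(panel)


class TestBasis:
    def test_dimension_four_populations(self, mixe_basis):
        assert len(mixe_basis.statistics) == 6
        kinds = [k for k, _ in mixe_basis.statistics]
        assert kinds.count("f2") == 3 and kinds.count("f3") == 3

    def test_dimension_five_populations(self):
        panel = simulate_panel(paper_fixture("five_ulchi", n_snps=5_000, n_blocks=10, seed=1))
        basis = build_basis(panel)
        assert len(basis.statistics) == 10

    def test_any_f4_reconstructs_from_basis(self, rng):
        panel = random_panel(rng, n_snps=80, pops="ABCD")
        basis = build_basis(panel)
        for quad in [("A", "B", "C", "D"), ("B", "D", "A", "C"), ("C", "A", "D", "B")]:
            coeffs = statistic_basis_coefficients("f4", quad, basis)
            direct = compute_f4(panel, *quad).value
            assert coeffs @ basis.f_obs == pytest.approx(direct, abs=1e-12)

    def test_base_must_be_member(self, rng):
        with pytest.raises(FitError, match="base"):
            build_basis(random_panel(rng), base_pop="Zulu")


class TestExactRecovery:
    def test_score_zero_and_compound_recovery(self):
        g = paper_fixture("five_ulchi").graph
        basis = basis_from_graph(g, sigma=1e-4)
        res = fit_graph(basis, g, random_state=0)
        assert res.score < 1e-12
        a, ah = 0.7, res.alphas["pAM"]
        assert ah == pytest.approx(a, abs=2e-3)
        # uniquely identifiable branch lengths recovered
        for name in ["EUR_WST", "WST_French", "EUR_EAS", "EAS_Han", "EAS_EA2", "EA2_Ulchi"]:
            assert res.lengths[name] == pytest.approx(g.lengths[name], abs=1e-5)
        # the source/terminal triple is identified only as the compound
        comp_true = a**2 * 0.001 + (1 - a) ** 2 * 0.002 + 0.005
        comp_fit = (
            ah**2 * res.lengths["EA2_EastSrc"]
            + (1 - ah) ** 2 * res.lengths["WST_WestSrc"]
            + res.lengths["pAM_Mixe"]
        )
        assert comp_fit == pytest.approx(comp_true, abs=1e-5)

    def test_root_edges_identified_as_sum(self):
        g = paper_fixture("quartet_mixe").graph
        res = fit_graph(basis_from_graph(g, sigma=1e-4), g, random_state=0)
        assert res.score < 1e-12
        assert res.lengths["R_Baka"] + res.lengths["R_EUR"] == pytest.approx(0.014, abs=1e-6)

    def test_predicted_equals_expected_f_of_fitted_graph(self, mixe_basis):
        res = fit_graph(mixe_basis, paper_fixture("quartet_mixe").graph, random_state=0)
        for (kind, pops), pred in zip(mixe_basis.statistics, res.predicted):
            lf = {
                "f2": lambda: expected_f4(res.graph, pops[0], pops[1], pops[0], pops[1]),
                "f3": lambda: expected_f4(res.graph, pops[0], pops[1], pops[0], pops[2]),
            }[kind]()
            assert lf.value == pytest.approx(pred, abs=1e-14)

    def test_base_population_invariance_on_exact_data(self):
        g = paper_fixture("quartet_mixe").graph
        for base in ["Baka", "Mixe", "Han"]:
            res = fit_graph(basis_from_graph(g, base_pop=base, sigma=1e-4), g,
                            base_pop=base, random_state=0)
            assert res.score < 1e-8


class TestLsqMode:
    def test_lsq_equals_identity_weighted_gls(self, mixe_basis):
        g = paper_fixture("quartet_mixe").graph
        a = lsq_fit(mixe_basis, g, random_state=4)
        import dataclasses

        eye = dataclasses.replace(
            mixe_basis, Q=np.eye(len(mixe_basis.f_obs)), diag_reg=0.0
        )
        b = fit_graph(eye, g, random_state=4)
        assert a.score == pytest.approx(b.score, abs=1e-12)
        for k in a.lengths:
            assert a.lengths[k] == pytest.approx(b.lengths[k], abs=1e-9)

    def test_lsq_flagged_in_result(self, mixe_basis):
        g = paper_fixture("quartet_mixe").graph
        assert lsq_fit(mixe_basis, g, random_state=0).lsq is True

    def test_lsq_and_gls_same_zero_score_solution_on_exact_data(self):
        g = paper_fixture("quartet_mixe").graph
        basis = basis_from_graph(g, sigma=1e-4)
        assert lsq_fit(basis, g, random_state=0).score < 1e-12
        assert fit_graph(basis, g, random_state=0).score < 1e-12


class TestResiduals:
    def test_zero_residuals_on_exact_data(self):
        g = paper_fixture("quartet_mixe").graph
        res = fit_graph(basis_from_graph(g, sigma=1e-4), g, random_state=0)
        table = residual_report(res)
        assert np.allclose(table["observed"] - table["predicted"], 0.0, atol=1e-10)

    def test_row_count_four_populations(self, mixe_basis):
        res = fit_graph(mixe_basis, paper_fixture("quartet_mixe").graph, random_state=0)
        table = residual_report(res)
        # 6 f2 + 12 f3 + 3 f4 pairings
        assert len(table) == 21
        assert (table["kind"].value_counts().to_dict()
                == {"f3": 12, "f2": 6, "f4": 3})

    def test_sorted_by_abs_z(self, mixe_basis):
        res = fit_graph(mixe_basis, paper_fixture("quartet_mixe").graph, random_state=0)
        z = residual_report(res)["z"].abs().to_numpy()
        assert (np.diff(z) <= 1e-15).all()

    def test_misplaced_population_tops_residuals(self):
        """With the Han/Ulchi split order swapped, the worst residual involves
        the misplaced eastern populations."""
        panel = simulate_panel(paper_fixture("five_ulchi", seed=21))
        res = fit_graph(panel, paper_fixture("five_swapped").graph, random_state=1)
        worst = res.residuals.iloc[0]
        assert "Ulchi" in worst["pops"] or "Han" in worst["pops"]
        assert abs(worst["z"]) > 3


class TestIdentifiability:
    def test_quartet_underdetermined(self):
        rep = identifiability_report(paper_fixture("quartet_mixe").graph, seed=0)
        assert rep.n_constraints == 6
        assert rep.n_free_formula == 7
        assert rep.rank == 6
        assert rep.underdetermined

    def test_five_populations_determined(self):
        rep = identifiability_report(paper_fixture("five_ulchi").graph, seed=0)
        assert rep.n_constraints == 10
        assert rep.n_free_formula == 9
        assert rep.rank == 9
        assert not rep.underdetermined

    def test_sister_populations_lose_rank(self):
        rep_u = identifiability_report(paper_fixture("five_ulchi").graph, seed=0)
        rep_h = identifiability_report(paper_fixture("five_hungarian").graph, seed=0)
        assert rep_h.rank < rep_u.rank
        assert rep_h.underdetermined

    def test_null_space_reported_for_flat_direction(self):
        rep = identifiability_report(paper_fixture("quartet_mixe").graph, seed=0)
        assert len(rep.null_space) == rep.n_parameters - rep.rank
        assert rep.compound_candidates == ["pAM"]


@pytest.fixture(scope="module")
def five_basis():
    panel = simulate_panel(paper_fixture("five_ulchi", n_snps=60_000, n_blocks=50, seed=31))
    return build_basis(panel)


class TestProfile:
    def test_profile_minimum_bounded_by_free_fit(self, five_basis):
        g = paper_fixture("five_ulchi").graph
        free = fit_graph(five_basis, g, random_state=2)
        prof = profile_parameter(five_basis, g, "pAM",
                                 np.linspace(0.5, 0.9, 5), random_state=2, n_restarts=3)
        assert prof.scores.min() >= free.score - 1e-10
        pinned = fit_graph(five_basis, g, fixed={"pAM": free.alphas["pAM"]}, random_state=2)
        assert pinned.score == pytest.approx(free.score, abs=1e-10)

    def test_unknown_parameter_rejected(self, five_basis):
        g = paper_fixture("five_ulchi").graph
        with pytest.raises(FitError, match="no parameter"):
            profile_parameter(five_basis, g, "nope", [0.5])

    def test_fixed_edge_length_profile(self, five_basis):
        g = paper_fixture("five_ulchi").graph
        prof = profile_parameter(five_basis, g, "EAS_EA2", [0.0, 0.006, 0.02],
                                 random_state=2, n_restarts=3)
        assert prof.scores[1] <= prof.scores[2]
        assert prof.fits[0].lengths["EAS_EA2"] == 0.0


class TestCompareAndTrifurcation:
    def test_identical_fits_zero_difference(self, mixe_basis):
        g = paper_fixture("quartet_mixe").graph
        a = fit_graph(mixe_basis, g, random_state=0)
        b = fit_graph(mixe_basis, g, random_state=0)
        cmp = compare_models(a, b)
        assert cmp.delta == 0.0

    def test_correct_topology_beats_swapped(self):
        panel = simulate_panel(paper_fixture("five_ulchi", seed=17))
        basis = build_basis(panel)
        good = fit_graph(basis, paper_fixture("five_ulchi").graph, random_state=1)
        bad = fit_graph(basis, paper_fixture("five_swapped").graph, random_state=1)
        cmp = compare_models(good, bad)
        assert cmp.preferred == "A"
        assert good.score < bad.score

    def test_different_snp_sets_not_comparable(self, mixe_basis):
        g = paper_fixture("quartet_mixe").graph
        a = fit_graph(mixe_basis, g, random_state=0)
        other = build_basis(
            simulate_panel(paper_fixture("quartet_mixe", n_snps=10_000, n_blocks=10, seed=9))
        )
        b = fit_graph(other, g, random_state=0)
        with pytest.raises(FitError, match="not comparable"):
            compare_models(a, b)

    def test_score_nonincreasing_with_added_admixture(self):
        """A nested topology with an extra admixture event can only fit better."""
        panel = simulate_panel(paper_fixture("quartet_mixe", n_snps=30_000, n_blocks=30, seed=8))
        basis = build_basis(panel)
        tree = AdmixtureGraph.from_edges(
            "R",
            [("R", "Baka"), ("R", "EUR"), ("EUR", "WST"), ("WST", "French"),
             ("EUR", "EAS"), ("EAS", "Han"), ("EAS", "Mixe")],
        )
        admixed = paper_fixture("quartet_mixe").graph
        s_tree = fit_graph(basis, tree, random_state=3).score
        s_admx = fit_graph(basis, admixed, random_state=3).score
        assert s_admx <= s_tree + 1e-12

    def test_all_zero_graph_lists_internal_branches(self):
        g = paper_fixture("five_ulchi").graph.with_params(
            lengths={e: 0.0 for e in paper_fixture("five_ulchi").graph.edge_names}
        )
        names = {n for n, _ in trifurcation_scan(g)}
        # internal, non-root, non-stub edges
        assert names == {"EUR_WST", "EUR_EAS", "EAS_EA2"}

    def test_correct_topology_no_trifurcation(self):
        panel = simulate_panel(paper_fixture("five_ulchi", seed=11))
        res = fit_graph(panel, paper_fixture("five_ulchi").graph, random_state=1)
        assert trifurcation_scan(res) == []

    def test_swapped_topology_collapses_connector(self):
        panel = simulate_panel(paper_fixture("five_ulchi", seed=11))
        res = fit_graph(panel, paper_fixture("five_swapped").graph, random_state=1)
        collapsed = dict(trifurcation_scan(res))
        assert "EAS_EA2" in collapsed
        assert collapsed["EAS_EA2"] < 1e-6


class TestGridSearchEquivalence:
    def test_matches_brute_force_on_toy_graph(self):
        """Seeded optimizer agrees with an independent dense grid + unconstrained
        linear solve on a three-population single-admixture toy model."""
        toy = AdmixtureGraph.from_edges(
            "R",
            [("R", "SA", 0.002), ("SA", "A", 0.01), ("R", "SB", 0.003),
             ("SB", "B", 0.012), ("pC", "C", 0.004)],
            [("pC", "SA", "SB", 0.35)],
        )
        basis = basis_from_graph(toy, sigma=1e-3)
        res = fit_graph(basis, toy, random_state=5)

        from admixkit.fitting import _design_matrix

        best = (np.inf, None)
        for a in np.linspace(0.0, 1.0, 1001):
            X = _design_matrix(toy, basis.statistics, {"pC": float(a)})
            sol, *_ = np.linalg.lstsq(X, basis.f_obs, rcond=None)
            if (sol < -1e-9).any():
                continue
            r = X @ sol - basis.f_obs
            s = 0.5 * float(r @ np.linalg.solve(basis.Q_reg, r))
            if s < best[0]:
                best = (s, a)
        assert res.score == pytest.approx(best[0], abs=1e-4)

    def test_sklearn_interface(self, mixe_basis):
        est = AdmixtureGraphFit(paper_fixture("quartet_mixe").graph, n_restarts=3)
        params = est.get_params()
        assert params["n_restarts"] == 3
        est.set_params(n_restarts=5).fit(mixe_basis)
        assert est.n_restarts_used_ == 5
        assert est.score() == -est.score_
        assert est.predict().shape == (6,)
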