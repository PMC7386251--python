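"""In silico CRISPR/RNAi perturbation rules."""

import numpy as np
import pandas as pd
import pytest

from deepdep import perturb as pt
from deepdep.network import from_edges
from deepdep.simulate import make_dag, simulate_expression


def pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


class TestConfig:
    def test_mode_defaults(self):
        assert pt.PerturbationConfig(mode="crispr").residual_fraction == 0.0
        assert pt.PerturbationConfig(mode="rnai").residual_fraction == 0.2

    def test_knockdown_factor(self):
        assert pt.PerturbationConfig(mode="rnai").knockdown_factor == pytest.approx(0.8)

    def test_invalid_residual(self):
        with pytest.raises(ValueError):
            pt.PerturbationConfig(mode="crispr", residual_fraction=1.0)


class TestReferenceCorrelations:
    def test_identical_and_opposite(self, chain_net, toy_expr):
        net = from_edges([("A", "B"), ("A", "C")])
        corr = pt.reference_correlations(net, toy_expr)
        assert corr.get("A")["B"] == pytest.approx(1.0)  # B == A in fixture
        assert corr.get("A")["C"] == pytest.approx(-1.0)  # C == 10 - A

    def test_matches_textbook_pearson(self, toy_expr):
        net = from_edges([("A", "D")])
        corr = pt.reference_correlations(net, toy_expr)
        expected = pearson(toy_expr.loc["A"], toy_expr.loc["D"])
        assert corr.get("A")["D"] == pytest.approx(expected)

    def test_constant_gene_r_zero(self):
        net = from_edges([("A", "B")])
        expr = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=["A", "B"], dtype=float)
        corr = pt.reference_correlations(net, expr)
        assert corr.get("A")["B"] == 0.0

    def test_too_few_samples(self, chain_net):
        expr = pd.DataFrame([[1, 2], [3, 4], [5, 6]], index=["A", "B", "C"])
        with pytest.raises(ValueError):
            pt.reference_correlations(chain_net, expr)


def _simple_setup(r_value, basal_values):
    net = from_edges([("Y", "X")])
    corr = pt.ReferenceCorrelations(by_target={"Y": pd.Series({"X": r_value})})
    basal = pd.Series(basal_values, index=["Y", "X"], dtype=float)
    return net, corr, basal


class TestPerturbCorrelation:
    def test_crispr_full_positive_coupling(self):
        net, corr, basal = _simple_setup(1.0, [5.0, 7.0])
        prof = pt.perturb_correlation(net, corr, basal, "Y", pt.PerturbationConfig(mode="crispr"))
        assert prof.values["X"] == pytest.approx(0.0)
        assert prof.values["Y"] == 0.0

    def test_rnai_half_coupling(self):
        # x' = x - r * k * x = 10 - 0.5 * 0.8 * 10 = 6
        net, corr, basal = _simple_setup(0.5, [5.0, 10.0])
        prof = pt.perturb_correlation(net, corr, basal, "Y", pt.PerturbationConfig(mode="rnai"))
        assert prof.values["X"] == pytest.approx(6.0)
        assert prof.values["Y"] == pytest.approx(1.0)  # 0.2 * basal

    def test_uncorrelated_descendant_unchanged(self):
        net, corr, basal = _simple_setup(0.0, [5.0, 3.0])
        prof = pt.perturb_correlation(net, corr, basal, "Y", pt.PerturbationConfig(mode="crispr"))
        assert prof.values["X"] == 3.0

    def test_zero_basal_target_rejected(self):
        net, corr, basal = _simple_setup(0.5, [0.0, 3.0])
        with pytest.raises(ValueError, match="knockdown undefined"):
            pt.perturb_correlation(net, corr, basal, "Y", pt.PerturbationConfig(mode="crispr"))

    def test_locality(self):
        net = from_edges([("Y", "X"), ("Q", "Z")])
        corr = pt.ReferenceCorrelations(
            by_target={"Y": pd.Series({"X": 0.7}), "Q": pd.Series({"Z": 0.7})}
        )
        basal = pd.Series([5.0, 4.0, 3.0, 2.0], index=["Y", "X", "Q", "Z"])
        prof = pt.perturb_correlation(net, corr, basal, "Y", pt.PerturbationConfig(mode="crispr"))
        assert prof.values["Q"] == 3.0 and prof.values["Z"] == 2.0

    def test_monotone_in_knockdown_factor(self):
        net, corr, basal = _simple_setup(0.8, [5.0, 10.0])
        values = []
        for residual in (0.6, 0.4, 0.2, 0.0):
            cfg = pt.PerturbationConfig(mode="rnai", residual_fraction=residual)
            values.append(pt.perturb_correlation(net, corr, basal, "Y", cfg).values["X"])
        assert values == sorted(values, reverse=True)


class TestPerturbMatrix:
    def test_diagonal_residual(self):
        net, corr, basal = _simple_setup(0.5, [5.0, 10.0])
        cfg = pt.PerturbationConfig(mode="rnai")
        mat = pt.perturb_matrix(net, corr, basal, cfg, targets=["Y"])
        assert mat.loc["Y", "Y"] == pytest.approx(0.2 * 5.0)

    def test_zero_offdiagonal_keeps_basal(self):
        net = from_edges([("Y", "X")])
        corr = pt.ReferenceCorrelations(by_target={"Y": pd.Series({"X": 0.0})})
        basal = pd.Series([5.0, 3.0], index=["Y", "X"])
        mat = pt.perturb_matrix(net, corr, basal, pt.PerturbationConfig(mode="crispr"))
        assert mat.loc["Y", "X"] == 3.0

    @pytest.mark.parametrize("mode", ["crispr", "rnai"])
    def test_matrix_equals_loop(self, mode):
        """Matrix form reproduces gene-by-gene perturbation to 1e-10."""
        net = make_dag(30, mean_out_degree=2.0, seed=11)
        expr = simulate_expression(net, 50, seed=11)
        corr = pt.reference_correlations(net, expr)
        basal = expr.iloc[:, 0]
        cfg = pt.PerturbationConfig(mode=mode)
        targets = [t for t in corr.targets if basal[t] > 0]
        mat = pt.perturb_matrix(net, corr, basal, cfg, targets=targets)
        for t in targets:
            loop = pt.perturb_correlation(net, corr, basal, t, cfg)
            assert np.max(np.abs(mat.loc[t].to_numpy() - loop.values.to_numpy())) < 1e-10


def oriented_toy():
    return from_edges(
        [
            ("Y", "A", "activation", 1.0),
            ("Y", "B", "inhibition", 0.5),
            ("A", "C", "activation", 0.9),
        ]
    )


class TestPerturbConditional:
    def test_full_activation_crispr_zeroes_target_gene(self):
        net = oriented_toy()
        basal = pd.Series([5.0, 4.0, 10.0, 2.0], index=["Y", "A", "B", "C"])
        prof = pt.perturb_conditional(net, basal, "Y", pt.PerturbationConfig(mode="crispr", network_rule="conditional"))
        assert prof.values["A"] == pytest.approx(0.0)  # p=1, k=1

    def test_inhibition_rnai_raises_expression(self):
        # x' = x + p * k * x = 10 + 0.5 * 0.8 * 10 = 14
        net = oriented_toy()
        basal = pd.Series([5.0, 4.0, 10.0, 2.0], index=["Y", "A", "B", "C"])
        prof = pt.perturb_conditional(net, basal, "Y", pt.PerturbationConfig(mode="rnai", network_rule="conditional"))
        assert prof.values["B"] == pytest.approx(14.0)

    def test_two_hops_away_unchanged(self):
        net = oriented_toy()
        basal = pd.Series([5.0, 4.0, 10.0, 2.0], index=["Y", "A", "B", "C"])
        prof = pt.perturb_conditional(net, basal, "Y", pt.PerturbationConfig(mode="crispr", network_rule="conditional"))
        assert prof.values["C"] == 2.0

    def test_no_regulatory_targets_rejected(self):
        net = oriented_toy()
        basal = pd.Series([5.0, 4.0, 10.0, 2.0], index=["Y", "A", "B", "C"])
        with pytest.raises(ValueError, match="no regulatory targets"):
            pt.perturb_conditional(net, basal, "C", pt.PerturbationConfig(network_rule="conditional"))


class TestPerturbCohort:
    def test_cardinality(self):
        net = from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.uniform(1, 10, size=(4, 5)), index=["A", "B", "C", "D"]
        )
        ref = pd.DataFrame(rng.uniform(1, 10, size=(4, 30)), index=["A", "B", "C", "D"])
        corr = pt.reference_correlations(net, ref)
        cohort = pt.perturb_cohort(net, corr, expr.iloc[:, :2], pt.PerturbationConfig(mode="crispr"))
        assert len(cohort.profiles) == 2 * 3  # 2 samples x 3 eligible targets

    def test_restricted_targets(self):
        net = from_edges([("A", "B"), ("B", "C")])
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.uniform(1, 10, (3, 2)), index=["A", "B", "C"])
        ref = pd.DataFrame(rng.uniform(1, 10, (3, 20)), index=["A", "B", "C"])
        corr = pt.reference_correlations(net, ref)
        cohort = pt.perturb_cohort(net, corr, expr, pt.PerturbationConfig(mode="crispr"), targets=["A"])
        assert {p.target for p in cohort.profiles} == {"A"}
        assert len(cohort.profiles) == 2

    def test_skips_reported(self):
        net = from_edges([("A", "B")])
        expr = pd.DataFrame([[0.0], [2.0]], index=["A", "B"], columns=["S0"])
        ref = pd.DataFrame(
            np.random.default_rng(2).uniform(1, 10, (2, 10)), index=["A", "B"]
        )
        corr = pt.reference_correlations(net, ref)
        cohort = pt.perturb_cohort(net, corr, expr, pt.PerturbationConfig(mode="crispr"))
        assert len(cohort.profiles) == 0
        assert len(cohort.skipped) == 1
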