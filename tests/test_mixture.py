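import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.mixture import GaussianMixture

import mixde
from mixde.mixture import (MixtureConvergenceError, TwoComponentMixture,
                           call_de, compute_contrasts, fold_from_log2,
                           summarise_de)
from conftest import make_stats_frame


def sample_mixture(n, w_alt, mu_alt, seed, mu_null=0.0, sd_null=1.0,
                   sd_alt=1.0):
    rng = np.random.default_rng(seed)
    alt = rng.random(n) < w_alt
    x = rng.normal(mu_null, sd_null, n)
    x[alt] = rng.normal(mu_alt, sd_alt, alt.sum())
    return x, alt


class StubFit:
    """Deterministic stand-in for a fitted mixture: posterior given directly."""

    def __init__(self, posterior_fn):
        self._fn = posterior_fn

    def posterior_nonnull(self, x):
        return self._fn(np.asarray(x, float))


class TestComputeContrasts:
    def test_hand_example(self):
        profiles = pd.DataFrame({"Polled": [1.0], "Horned": [0.2],
                                 "Scurred": [0.0]}, index=["g0"])
        pev = np.array([[[0.04, 0.01, 0.0],
                         [0.01, 0.05, 0.0],
                         [0.0, 0.0, 0.02]]])
        out = compute_contrasts(profiles, pev).set_index("contrast")
        assert out.loc["PvH", "raw_diff"] == pytest.approx(0.8)
        # var = 0.04 + 0.05 - 2*0.01
        assert out.loc["PvH", "se"] == pytest.approx(np.sqrt(0.07))
        assert out.loc["PvH", "statistic"] == pytest.approx(0.8 / np.sqrt(0.07))
        assert out.loc["HvS", "raw_diff"] == pytest.approx(0.2)

    def test_misaligned_inputs_rejected(self):
        profiles = pd.DataFrame({"Polled": [0.0], "Horned": [0.0],
                                 "Scurred": [0.0]}, index=["g0"])
        with pytest.raises(ValueError):
            compute_contrasts(profiles, np.zeros((2, 3, 3)))

    def test_model_output_shape(self, default_sim):
        model = default_sim["model"]
        out = compute_contrasts(model.hg_solutions_, model.hg_pev_)
        per = out.groupby("contrast").size()
        assert set(per.index) == {"PvH", "PvS", "HvS"}
        assert (per == model.hg_solutions_.shape[0]).all()
        assert np.isfinite(out["statistic"]).all()


class TestTwoComponentMixture:
    def test_recovers_planted_mixture(self):
        x, _ = sample_mixture(5000, 0.10, 4.0, seed=7)
        fit = TwoComponentMixture(random_state=0).fit(x)
        assert fit.converged_
        assert fit.weights_[1] == pytest.approx(0.10, abs=0.02)
        assert fit.means_[0] == pytest.approx(0.0, abs=0.1)
        assert fit.means_[1] == pytest.approx(4.0, abs=0.2)

    def test_loglik_monotone(self):
        x, _ = sample_mixture(2000, 0.1, 3.0, seed=1)
        fit = TwoComponentMixture(random_state=0).fit(x)
        ll = np.asarray(fit.loglik_path_)
        assert np.all(np.diff(ll) >= -1e-9)

    def test_negation_swaps_sign_of_means_only(self):
        x, _ = sample_mixture(3000, 0.1, 4.0, seed=2)
        f1 = TwoComponentMixture(random_state=0).fit(x)
        f2 = TwoComponentMixture(random_state=0).fit(-x)
        assert f2.means_[1] == pytest.approx(-f1.means_[1], abs=0.05)
        assert f2.weights_[1] == pytest.approx(f1.weights_[1], abs=0.01)
        assert f2.variances_[0] == pytest.approx(f1.variances_[0], rel=0.1)

    def test_agrees_with_sklearn_gaussian_mixture(self):
        x, _ = sample_mixture(4000, 0.1, 4.0, seed=3)
        fit = TwoComponentMixture(random_state=0).fit(x)
        gm = GaussianMixture(2, random_state=0, n_init=5,
                             tol=1e-8).fit(x.reshape(-1, 1))
        k = int(np.argmax(np.abs(gm.means_.ravel())))
        assert fit.means_[1] == pytest.approx(gm.means_.ravel()[k], abs=0.05)
        assert fit.weights_[1] == pytest.approx(gm.weights_[k], abs=0.01)
        assert fit.variances_[1] == pytest.approx(
            gm.covariances_.ravel()[k], rel=0.1)

    def test_pure_null_calls_nothing(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 1.0, 3000)
        fit = TwoComponentMixture(random_state=0).fit(x)
        assert fit.weights_[1] < 0.15  # weakly identified but small
        res = call_de(make_stats_frame(x), fit, fdr_target=0.01)
        assert res["de_flag"].sum() == 0

    def test_too_few_statistics_rejected(self):
        with pytest.raises(ValueError, match="50"):
            TwoComponentMixture().fit(np.zeros(10) + np.arange(10))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            TwoComponentMixture(n_starts=3).fit(np.zeros(200))

    def test_null_statistics_have_unit_scale_at_defaults(self, default_sim):
        model, truth = default_sim["model"], default_sim["truth"]
        out = compute_contrasts(model.hg_solutions_, model.hg_pev_)
        null_ids = set(truth.loc[~truth["de_PvH"], "probe_id"])
        stats = out[(out["contrast"] == "PvH")
                    & out["gene_id"].isin(null_ids)]["statistic"]
        assert 0.9 < stats.std() < 1.6


class TestCallDe:
    def test_perfect_posteriors_select_exactly_signal(self):
        x = np.array([0.1, -0.2, 5.0, 6.0, 0.05] * 20)
        fit = StubFit(lambda v: (np.abs(v) > 3).astype(float))
        res = call_de(make_stats_frame(x), fit, fdr_target=0.01)
        assert (res["de_flag"] == (np.abs(x) > 3)).all()

    def test_fdr_prefix_rule(self):
        # posteriors 0.999 (ok alone), then 0.95: prefix of 2 has
        # mean(1-post) = 0.0255 > 0.01 -> only the first is kept
        post = {5.0: 0.999, 4.0: 0.95}
        fit = StubFit(lambda v: np.array([post.get(t, 0.0) for t in v]))
        res = call_de(make_stats_frame([5.0, 4.0, 0.0]), fit, 0.01)
        assert res["de_flag"].tolist() == [True, False, False]
        res2 = call_de(make_stats_frame([5.0, 4.0, 0.0]), fit, 0.05)
        assert res2["de_flag"].tolist() == [True, True, False]

    def test_fold_change_column(self):
        fit = StubFit(lambda v: np.zeros_like(v))
        res = call_de(make_stats_frame([3.0, -3.0]), fit, 0.01)
        assert res["fold_change"].tolist() == [8.0, -8.0]

    def test_empty_selection_valid(self):
        fit = StubFit(lambda v: np.full_like(v, 0.5))
        res = call_de(make_stats_frame(np.linspace(-1, 1, 30)), fit, 0.01)
        assert res["de_flag"].sum() == 0


class TestFoldFromLog2:
    @pytest.mark.parametrize("d,expected", [
        (0.0, 1.0), (1.0, 2.0), (3.0, 8.0), (-1.0, -2.0), (-3.0, -8.0),
        (0.99, 2.0 ** 0.99),
    ])
    def test_values(self, d, expected):
        assert fold_from_log2(d) == pytest.approx(expected)

    @given(d=st.floats(0.01, 20))
    def test_odd_involution(self, d):
        # odd away from zero; fold(0) = +1 by convention
        assert fold_from_log2(-d) == pytest.approx(-fold_from_log2(d))
        assert abs(fold_from_log2(d)) >= 1.0
        assert abs(fold_from_log2(-d)) >= 1.0


class TestSummariseDe:
    def test_set_algebra_oracle(self):
        rows = []
        sets = {"PvH": {"g1", "g2", "g3"}, "PvS": {"g2", "g3", "g4"},
                "HvS": {"g3", "g5"}}
        for c, genes in sets.items():
            for g in sorted(genes | {"g9"}):
                rows.append({"gene_id": g, "contrast": c,
                             "de_flag": g in genes})
        res = pd.DataFrame(rows)
        out = summarise_de(res)
        assert out["counts"] == {"PvH": 3, "PvS": 3, "HvS": 2}
        assert out["overlaps"]["PvH&PvS"] == 2
        assert out["overlaps"]["PvH&HvS"] == 1
        assert out["overlaps"]["PvS&HvS"] == 1
        assert out["overlaps"]["PvH&PvS&HvS"] == 1
        assert out["total_genes"] == 5

    def test_per_chromosome_counts(self):
        res = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                            "contrast": "PvH", "de_flag": True})
        cmap = {"g1": 5, "g2": 5}
        out = summarise_de(res, cmap)["per_chromosome"].set_index("chromosome")
        assert out.loc[5, "n_de"] == 2
        assert out.loc["unplaced", "n_de"] == 1
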