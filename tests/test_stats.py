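import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spindletopo.encoding import EncodingTopography
from spindletopo.events import EventTopography
from spindletopo.stats import (behavior_correlation, coupling_contrast, holm,
                               overlap, partial_spearman, permutation_null,
                               posthoc_tests, rm_anova_2x3, spearman)


class TestSpearman:
    def test_identity_and_reversal(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_d2_formula_oracle(self):
        assert spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_nan_pairwise_deletion(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 1, 7, 3, 5, 6]
        assert spearman(x, y) == pytest.approx(
            spearman([1, 2, 4, 5, 6], [2, 1, 3, 5, 6]))

    def test_constant_vector_is_missing(self):
        assert np.isnan(spearman([1, 1, 1, 1], [1, 2, 3, 4]))

    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=20,
                    unique=True),
           st.sampled_from([np.exp, np.arctan, lambda v: v ** 3]))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, xs, f):
        rng = np.random.default_rng(42)
        x = np.array(xs) / 250.0  # well-separated values in (-4, 4)
        y = rng.permutation(x)
        assert spearman(f(x), y) == pytest.approx(spearman(x, y), abs=1e-9)


def _brute_force_spearman(x, y):
    from scipy.stats import rankdata
    rx, ry = rankdata(x), rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestPartialSpearman:
    def test_matches_formula_on_ranks(self):
        rng = np.random.default_rng(0)
        x, y, c = rng.normal(size=(3, 30))
        r_xy = _brute_force_spearman(x, y)
        r_xc = _brute_force_spearman(x, c)
        r_yc = _brute_force_spearman(y, c)
        expect = (r_xy - r_xc * r_yc) / np.sqrt(
            (1 - r_xc ** 2) * (1 - r_yc ** 2))
        assert partial_spearman(x, y, c) == pytest.approx(expect, abs=1e-12)

    def test_independent_control_approximates_plain_rho(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=3000)
        y = x + rng.normal(size=3000)
        c = rng.normal(size=3000)
        assert partial_spearman(x, y, c) == pytest.approx(
            spearman(x, y), abs=0.03)

    def test_identical_control_is_undefined(self):
        y = np.arange(10.0)
        assert np.isnan(partial_spearman(np.random.default_rng(2).normal(
            size=10), y, y))

    def test_common_cause_partialled_out(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=5000)
        x = c + rng.normal(size=5000)
        y = c + rng.normal(size=5000)
        assert abs(partial_spearman(x, y, c)) < 0.05

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("xyc"))
        expected = pg.partial_corr(df, x="x", y="y", covar="c",
                                   method="spearman")["r"].iloc[0]
        assert partial_spearman(df.x, df.y, df.c) == pytest.approx(
            expected, abs=1e-10)


def _brute_force_rm_anova(y):
    """Direct SS decomposition via explicit cell-mean model sums."""
    n, a, b = y.shape
    out = {}
    grand = y.mean()
    ss = {
        "A": sum(n * b * (y[:, j, :].mean() - grand) ** 2 for j in range(a)),
        "B": sum(n * a * (y[:, :, k].mean() - grand) ** 2 for k in range(b)),
    }
    ss["AB"] = sum(
        n * (y[:, j, k].mean() - y[:, j, :].mean() - y[:, :, k].mean()
             + grand) ** 2 for j in range(a) for k in range(b))
    ss["AS"] = sum(
        b * (y[i, j, :].mean() - y[i].mean() - y[:, j, :].mean()
             + grand) ** 2 for i in range(n) for j in range(a))
    ss["BS"] = sum(
        a * (y[i, :, k].mean() - y[i].mean() - y[:, :, k].mean()
             + grand) ** 2 for i in range(n) for k in range(b))
    ss["subj"] = sum(a * b * (y[i].mean() - grand) ** 2 for i in range(n))
    ss["total"] = ((y - grand) ** 2).sum()
    ss["ABS"] = (ss["total"] - ss["A"] - ss["B"] - ss["AB"] - ss["subj"]
                 - ss["AS"] - ss["BS"])
    out["F_A"] = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    out["F_B"] = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    out["F_AB"] = (ss["AB"] / ((a - 1) * (b - 1))) / (
        ss["ABS"] / ((a - 1) * (b - 1) * (n - 1)))
    out["ss"] = ss
    return out


class TestRmAnova:
    def test_all_equal_cells_give_zero(self):
        res = rm_anova_2x3(np.full((5, 2, 3), 0.7))
        assert (res["F"] == 0).all()
        assert (res["partial_eta_sq"] == 0).all()
        assert (res["p"] == 1).all()

    def test_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(3, 2, 3))
        res = rm_anova_2x3(y).set_index("effect")
        oracle = _brute_force_rm_anova(y)
        assert res.loc["event_type", "F"] == pytest.approx(oracle["F_A"],
                                                           rel=1e-10)
        assert res.loc["characteristic", "F"] == pytest.approx(
            oracle["F_B"], rel=1e-10)
        assert res.loc["interaction", "F"] == pytest.approx(oracle["F_AB"],
                                                            rel=1e-10)

    def test_event_offset_moves_main_effect_not_interaction(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(6, 2, 3))
        base = rm_anova_2x3(y).set_index("effect")
        shifted = y.copy()
        shifted[:, 0, :] += 1.0  # constant offset on all spindle cells
        res = rm_anova_2x3(shifted).set_index("effect")
        assert res.loc["event_type", "F"] > base.loc["event_type", "F"]
        assert res.loc["interaction", "F"] == pytest.approx(
            base.loc["interaction", "F"], rel=1e-9)

    def test_ss_decomposition_closes(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(8, 2, 3))
        res = rm_anova_2x3(y)
        oracle = _brute_force_rm_anova(y)
        total_parts = (res["SS"].sum() + res["SS_error"].sum()
                       + oracle["ss"]["subj"])
        assert total_parts == pytest.approx(oracle["ss"]["total"],
                                            rel=1e-10)

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        y = rng.normal(size=(7, 2, 3))
        rows = [{"s": i, "ev": j, "ch": k, "y": y[i, j, k]}
                for i in range(7) for j in range(2) for k in range(3)]
        table = pg.rm_anova(data=pd.DataFrame(rows), dv="y",
                            within=["ev", "ch"], subject="s")
        res = rm_anova_2x3(y)
        p_col = "p_unc" if "p_unc" in table.columns else "p-unc"
        np.testing.assert_allclose(res["F"], table["F"], rtol=1e-8)
        np.testing.assert_allclose(res["p"], table[p_col], rtol=1e-8)

    def test_missing_cells_rejected(self):
        y = np.full((4, 2, 3), 1.0)
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2x3(y)


class TestPosthoc:
    def test_identical_columns_give_t0_p1(self):
        y = np.random.default_rng(0).normal(size=(6, 2, 3))
        y[:, 1, :] = y[:, 0, :]
        res = posthoc_tests(y).set_index("test")
        for ch in ("amplitude", "duration", "density"):
            row = res.loc[f"spindle_vs_so_{ch}"]
            assert row["t"] == pytest.approx(0.0, abs=1e-12)
            assert row["p"] == pytest.approx(1.0)

    def test_hand_computed_one_sample(self):
        # values (-1,-2,-3): mean -2, sd 1 -> t = -2*sqrt(3), d = -2
        y = np.zeros((3, 2, 3))
        y[:, 0, 0] = [-1.0, -2.0, -3.0]
        res = posthoc_tests(y).set_index("test")
        row = res.loc["spindle_amplitude_vs_zero"]
        assert row["t"] == pytest.approx(-3.464, abs=1e-3)
        assert row["cohen_d"] == pytest.approx(-2.0)

    def test_holm_step_down_by_hand(self):
        np.testing.assert_allclose(holm([0.01, 0.03, 0.04]),
                                   [0.03, 0.06, 0.06])

    @given(st.lists(st.floats(0.001, 1.0), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_holm_adjusted_p_dominates_raw(self, ps):
        adj = holm(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestOverlap:
    def _enc(self, values):
        labels = [f"ch{i}" for i in range(len(values))]
        return EncodingTopography(np.asarray(values, float), labels, "p1")

    def _topo(self, values, kind="spindle"):
        labels = [f"ch{i}" for i in range(len(values))]
        table = pd.DataFrame({
            "amplitude_uV": values, "duration_s": values,
            "density_per_min": values, "n_events": 10,
        }, index=pd.Index(labels, name="channel"))
        return EventTopography(kind=kind, table=table)

    def test_perfect_overlap_is_minus_one(self):
        rng = np.random.default_rng(0)
        enc_vals = -rng.uniform(1, 2, size=20)
        res = overlap(self._enc(enc_vals), self._topo(-3 * enc_vals),
                      "amplitude")
        assert res.rho == pytest.approx(-1.0)
        assert res.z == pytest.approx(np.arctanh(-(1 - 1e-6)))

    def test_independent_topographies_center_on_zero(self):
        rng = np.random.default_rng(1)
        rhos = [overlap(self._enc(-rng.uniform(1, 2, 58)),
                        self._topo(rng.uniform(1, 2, 58)),
                        "density").rho for _ in range(200)]
        assert abs(np.mean(rhos)) < 0.05

    def test_too_few_common_channels_rejected(self):
        with pytest.raises(ValueError, match="common channels"):
            overlap(self._enc(-np.arange(1.0, 6.0)),
                    self._topo(np.arange(1.0, 6.0)), "amplitude")


class TestBehaviorCorrelation:
    def test_monotone_decreasing_gives_minus_one(self):
        z = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
        ret = 100 - 10 * z
        rho, p = behavior_correlation(z, ret)
        assert rho == pytest.approx(-1.0)
        assert p < 0.05

    def test_exact_p_matches_enumeration_probability(self):
        # for n = 5 and rho = 1 the exact two-sided p is 2/5! = 1/60
        z = np.arange(5.0)
        rho, p = behavior_correlation(z, z * 2 + 1)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            z = rng.normal(size=14)
            ret = rng.normal(size=14)
            ps.append(behavior_correlation(z, ret)[1])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPermutationNull:
    def test_constant_retention_refused(self):
        rng = np.random.default_rng(0)
        enc = rng.normal(size=(8, 20))
        spin = rng.normal(size=(8, 20))
        with pytest.raises(ValueError, match="constant"):
            permutation_null(enc, spin, np.full(8, 100.0), "encoding", 50,
                             rng)

    def test_unknown_shuffle_target_rejected(self):
        rng = np.random.default_rng(0)
        enc = rng.normal(size=(6, 20))
        with pytest.raises(ValueError, match="shuffle_which"):
            permutation_null(enc, enc, np.arange(6.0), "behavior", 10, rng)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        enc = rng.normal(size=(10, 30))
        spin = rng.normal(size=(10, 30))
        ret = rng.normal(size=10)
        a = permutation_null(enc, spin, ret, "spindle", 200, 7)
        b = permutation_null(enc, spin, ret, "spindle", 200, 7)
        assert a.p == b.p
        np.testing.assert_array_equal(a.null, b.null)
        assert a.p >= 1 / 201

    def test_p_bounded_below(self):
        rng = np.random.default_rng(2)
        # perfectly planted monotone link
        enc = -np.sort(rng.uniform(1, 2, size=(8, 40)), axis=1)
        spin = -5 * enc
        ret = np.linspace(150, 50, 8)  # decreasing with overlap z
        pn = permutation_null(enc, spin, ret, "encoding", 100, rng)
        assert pn.p >= 1 / 101
        assert pn.null.size == 100


class TestCouplingContrast:
    def test_identical_subsets_give_t0(self):
        z = np.random.default_rng(0).normal(size=12)
        res = coupling_contrast(z, z)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)

    def test_needs_two_participants(self):
        with pytest.raises(ValueError):
            coupling_contrast([0.1], [0.2])
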