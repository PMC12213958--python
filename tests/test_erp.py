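import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from erpsource.containers import EpochsSet
from erpsource.erp import (
    CORONAL_LEVELS,
    SAGITTAL_LEVELS,
    cluster_means,
    collapsed_localizer,
    emm_tukey_posthoc,
    locate_lsw_window,
    locate_p2_window,
    rebaseline,
    rm_anova_2x3x3,
)
from erpsource.simulate import CONDITIONS


def _epochs(data, fs=512.0, t0=-100.0, conditions=None, n_ch=None):
    data = np.asarray(data, float)
    n_tr, n_chan, n_s = data.shape
    times = t0 + 1000.0 / fs * np.arange(n_s)
    conditions = conditions or [CONDITIONS[i % 2] for i in range(n_tr)]
    return EpochsSet(data, conditions, times, [f"c{i}" for i in range(n_chan)], fs)


def _gauss_trials(peaks_ms, n_ch, fs=512.0):
    times = -100.0 + 1000.0 / fs * np.arange(821)
    data = np.stack(
        [np.exp(-0.5 * ((times - p) / 15.0) ** 2) for p in peaks_ms]
    )[:, None, :]
    return _epochs(np.repeat(data, n_ch, axis=1), fs=fs)


class TestCollapsedLocalizer:
    def test_range_contains_planted_peak(self, montage16):
        ep = _gauss_trials([180.0] * 4, 16)
        _, p2_range, lsw_range = collapsed_localizer([ep], montage16)
        assert p2_range[0] <= 180.0 <= p2_range[1]
        assert lsw_range == (1100.0, 1500.0)

    def test_condition_labels_do_not_matter(self, montage16, rng):
        data = rng.normal(size=(6, 16, 821))
        a = _epochs(data, conditions=["source_correct"] * 3 + ["source_incorrect"] * 3)
        b = _epochs(data, conditions=["source_incorrect"] * 3 + ["source_correct"] * 3)
        ga, _, _ = collapsed_localizer([a], montage16)
        gb, _, _ = collapsed_localizer([b], montage16)
        np.testing.assert_array_equal(ga, gb)

    def test_grand_average_is_trial_weighted_pooled_mean(self, montage16, rng):
        d1 = rng.normal(size=(2, 16, 821))
        d2 = rng.normal(size=(5, 16, 821))
        grand, _, _ = collapsed_localizer([_epochs(d1), _epochs(d2)], montage16)
        pooled = np.concatenate([d1, d2]).mean(axis=0)  # brute-force pooled mean
        np.testing.assert_allclose(grand, pooled, atol=1e-12)


class TestP2Window:
    def test_noiseless_identical_trials(self, montage16):
        ep = _gauss_trials([180.0] * 5, 16)
        w = locate_p2_window(ep, montage16)
        assert abs(w.center_ms - 180.0) <= 1000.0 / 512.0
        assert w.start_ms == pytest.approx(w.center_ms - 25.0)
        assert w.stop_ms == pytest.approx(w.center_ms + 25.0)
        assert not w.low_confidence

    def test_median_of_three_peaks(self, montage16):
        ep = _gauss_trials([160.0, 180.0, 200.0], 16)
        w = locate_p2_window(ep, montage16)
        assert abs(w.center_ms - 180.0) <= 1000.0 / 512.0

    def test_lower_median_for_even_count(self, montage16):
        ep = _gauss_trials([160.0, 200.0], 16)
        w = locate_p2_window(ep, montage16)
        assert abs(w.center_ms - 160.0) <= 1000.0 / 512.0

    def test_flat_signal_low_confidence_at_range_start(self, montage16):
        ep = _epochs(np.zeros((3, 16, 821)))
        w = locate_p2_window(ep, montage16)
        assert w.low_confidence
        assert w.center_ms == pytest.approx(120.0, abs=1000.0 / 512.0)


class TestLswWindow:
    def test_default_window(self):
        w = locate_lsw_window()
        assert (w.start_ms, w.stop_ms) == (1175.0, 1225.0)
        assert w.baseline_ms == (610.0, 620.0)

    def test_150ms_window(self):
        w = locate_lsw_window(window_ms=150.0)
        assert (w.start_ms, w.stop_ms) == (1125.0, 1275.0)

    def test_clipping_flagged(self):
        w = locate_lsw_window(window_ms=700.0)
        assert w.clipped and w.stop_ms == 1500.0


class TestRebaseline:
    def test_constant_removed(self, montage16):
        ep = _epochs(np.full((2, 16, 821), 3.0))
        w = locate_lsw_window()
        assert np.all(rebaseline(ep, w).data == 0.0)

    def test_idempotent(self, montage16, rng):
        ep = _epochs(rng.normal(size=(2, 16, 821)))
        w = locate_lsw_window()
        once = rebaseline(ep, w)
        twice = rebaseline(once, w)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_ramp_baseline_mean_subtracted_exactly(self):
        ep = _epochs(np.tile(np.arange(821.0), (1, 4, 1)))
        w = locate_lsw_window()  # baseline 610-620 ms
        mask = ep.time_mask(610.0, 620.0)
        expected = ep.data[0, 0] - ep.data[0, 0, mask].mean()
        out = rebaseline(ep, w)
        np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-12)

    def test_baseline_outside_epoch_rejected(self):
        ep = _epochs(np.zeros((1, 4, 100)), t0=0.0)  # epoch ends ~193 ms
        with pytest.raises(ValueError, match="baseline"):
            rebaseline(ep, locate_lsw_window())


class TestClusterMeans:
    def test_constant_field(self, montage64):
        ep = _epochs(np.full((4, 64, 821), 2.0))
        cm = cluster_means(ep, locate_lsw_window(), montage64)
        assert np.allclose(cm["amplitude"], 2.0)
        assert len(cm) == 18  # 2 conditions x 9 cells

    def test_single_channel_boxcar_arithmetic(self, montage64):
        cells = montage64.cluster_channels()
        ch = cells[("frontal", "left")][0]
        n_in_cell = cells[("frontal", "left")].size
        data = np.zeros((2, 64, 821))
        ep0 = _epochs(data)
        w = locate_lsw_window()
        mask = ep0.time_mask(w.start_ms, w.stop_ms)
        data[:, ch, mask] = 9.0
        cm = cluster_means(_epochs(data), w, montage64)
        fl = cm[(cm.coronal == "frontal") & (cm.sagittal == "left")]
        assert np.allclose(fl["amplitude"], 9.0 / n_in_cell)
        rest = cm[~((cm.coronal == "frontal") & (cm.sagittal == "left"))]
        assert np.allclose(rest["amplitude"], 0.0)

    def test_trial_permutation_invariance(self, montage64, rng):
        data = rng.normal(size=(6, 64, 821))
        conds = [CONDITIONS[0]] * 3 + [CONDITIONS[1]] * 3
        perm = [1, 0, 2, 4, 3, 5]  # swap within conditions
        a = cluster_means(_epochs(data, conditions=conds), locate_lsw_window(),
                          montage64)
        b = cluster_means(_epochs(data[perm], conditions=conds),
                          locate_lsw_window(), montage64)
        np.testing.assert_allclose(a["amplitude"], b["amplitude"], atol=1e-12)


def _tidy(y):
    rows = []
    for s in range(y.shape[0]):
        for c, cond in enumerate(CONDITIONS):
            for a, cor in enumerate(CORONAL_LEVELS):
                for b, sag in enumerate(SAGITTAL_LEVELS):
                    rows.append(
                        {"subject": f"S{s:02d}", "condition": cond, "coronal": cor,
                         "sagittal": sag, "amplitude": y[s, c, a, b]}
                    )
    return pd.DataFrame(rows)


def _brute_force_ss(y, axes):
    """Textbook effect SS: sum over all cells of the squared interaction
    term, computed cell-by-cell with explicit loops."""
    shape = y.shape
    total = 0.0
    for idx in itertools.product(*[range(s) for s in shape]):
        term = 0.0
        for r in range(len(axes) + 1):
            for sub in itertools.combinations(axes, r):
                sel = [slice(None) if a in sub else idx[a] for a in range(4)]
                for a in sub:
                    sel[a] = idx[a]
                # marginal mean holding `sub` fixed, averaging the rest
                avg_axes = tuple(a for a in range(4) if a not in sub)
                marg = y[tuple(sel[a] if a not in avg_axes else slice(None)
                               for a in range(4))].mean()
                term += (-1) ** (len(axes) - len(sub)) * marg
        total += term**2
    return total


class TestRmAnova:
    def test_null_condition_gives_zero_F(self, rng):
        y = rng.normal(size=(5, 2, 3, 3))
        y[:, 1] = y[:, 0]  # identical condition means in every cell
        res = rm_anova_2x3x3(_tidy(y))
        assert res.effects.loc["condition", "F"] == 0.0

    def test_df_structure_for_95_subjects(self, rng):
        y = rng.normal(size=(95, 2, 3, 3))
        res = rm_anova_2x3x3(_tidy(y))
        cs = res.effects.loc["condition:sagittal"]
        assert (cs["df"], cs["df_err"]) == (2, 188)
        c3 = res.effects.loc["condition:coronal:sagittal"]
        assert (c3["df"], c3["df_err"]) == (4, 376)

    def test_ss_match_brute_force(self, rng):
        y = rng.normal(size=(4, 2, 3, 3))
        res = rm_anova_2x3x3(_tidy(y))
        for name, axes in [
            ("condition", (1,)),
            ("condition:coronal", (1, 2)),
            ("condition:sagittal", (1, 3)),
            ("condition:coronal:sagittal", (1, 2, 3)),
        ]:
            np.testing.assert_allclose(
                res.effects.loc[name, "ss"], _brute_force_ss(y, axes), rtol=1e-10
            )
            np.testing.assert_allclose(
                res.effects.loc[name, "ss_err"], _brute_force_ss(y, (0,) + axes),
                rtol=1e-10,
            )

    def test_matches_statsmodels_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        y = rng.normal(size=(6, 2, 3, 3))
        tidy = _tidy(y)
        res = rm_anova_2x3x3(tidy)
        sm_res = AnovaRM(
            tidy, depvar="amplitude", subject="subject",
            within=["condition", "coronal", "sagittal"],
        ).fit()
        tab = sm_res.anova_table
        for ours, theirs in [
            ("condition", "condition"),
            ("condition:coronal", "condition:coronal"),
            ("condition:sagittal", "condition:sagittal"),
            ("condition:coronal:sagittal", "condition:coronal:sagittal"),
        ]:
            np.testing.assert_allclose(
                res.effects.loc[ours, "F"], tab.loc[theirs, "F Value"], rtol=1e-8
            )
            np.testing.assert_allclose(
                res.effects.loc[ours, "p"], tab.loc[theirs, "Pr > F"], rtol=1e-8
            )

    def test_scale_equivariance_of_F(self, rng):
        y = rng.normal(size=(5, 2, 3, 3))
        f1 = rm_anova_2x3x3(_tidy(y)).effects["F"]
        f2 = rm_anova_2x3x3(_tidy(3.7 * y)).effects["F"]
        np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_unbalanced_rejected(self, rng):
        tidy = _tidy(rng.normal(size=(4, 2, 3, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced|missing"):
            rm_anova_2x3x3(tidy)


def _range_sf_oracle(q, k, df):
    """P(studentized range > q) by direct numerical integration."""

    def outer(u):
        s = np.sqrt(u)

        def inner(z):
            return (
                k * stats.norm.pdf(z)
                * (stats.norm.cdf(z) - stats.norm.cdf(z - q * s)) ** (k - 1)
            )

        p_range, _ = integrate.quad(inner, -8, 8, limit=200)
        return p_range * stats.chi2.pdf(u * df, df) * df

    cdf, _ = integrate.quad(outer, 1e-9, 8, limit=200)
    return 1.0 - cdf


class TestPosthoc:
    def test_null_gives_p_one(self, rng):
        y = rng.normal(size=(5, 2, 3, 3))
        y[:, 1] = y[:, 0]
        res = rm_anova_2x3x3(_tidy(y))
        post = emm_tukey_posthoc(_tidy(y), res)
        assert np.allclose(post["p_tukey"], 1.0)

    def test_two_level_tukey_equals_studentized_range(self, rng):
        # with k = 2 estimated marginal means the Tukey adjustment is a
        # no-op: the studentized-range p equals the reported two-sided p
        y = rng.normal(size=(6, 2, 3, 3))
        res = rm_anova_2x3x3(_tidy(y))
        post = emm_tukey_posthoc(_tidy(y), res)
        for _, r in post.iterrows():
            p_range = stats.studentized_range.sf(abs(r["t"]) * np.sqrt(2.0),
                                                 2, r["df"])
            np.testing.assert_allclose(r["p_tukey"], p_range, rtol=1e-6)

    @pytest.mark.parametrize("k,df,q", [(2, 10, 2.5), (3, 12, 3.1)])
    def test_studentized_range_against_integration_oracle(self, k, df, q):
        np.testing.assert_allclose(
            stats.studentized_range.sf(q, k, df), _range_sf_oracle(q, k, df),
            rtol=1e-5,
        )

    def test_sagittal_contrasts_shape(self, rng):
        y = rng.normal(size=(5, 2, 3, 3))
        res = rm_anova_2x3x3(_tidy(y))
        post = emm_tukey_posthoc(_tidy(y), res, by="sagittal")
        assert len(post) == 3


class TestSphericityCorrection:
    def test_gg_epsilon_bounds_and_df1_invariance(self, rng):
        y = rng.normal(size=(8, 2, 3, 3))
        plain = rm_anova_2x3x3(_tidy(y))
        gg = rm_anova_2x3x3(_tidy(y), sphericity_correction="gg")
        # condition has 1 df: untouched by the correction
        assert gg.effects.loc["condition", "p"] == plain.effects.loc["condition", "p"]
        for name in ("condition:sagittal", "condition:coronal:sagittal"):
            eps = gg.effects.loc[name, "epsilon"]
            df = plain.effects.loc[name, "df"]
            assert 1.0 / df - 1e-12 <= eps <= 1.0 + 1e-12
            assert gg.effects.loc[name, "F"] == plain.effects.loc[name, "F"]

    def test_spherical_covariance_gives_epsilon_one(self, rng):
        # compound-symmetric data in the contrast space: iid cell noise
        y = rng.normal(size=(2000, 2, 3, 3))
        gg = rm_anova_2x3x3(_tidy(y), sphericity_correction="gg")
        assert gg.effects.loc["condition:sagittal", "epsilon"] > 0.95

    def test_unknown_correction_rejected(self, rng):
        with pytest.raises(ValueError, match="sphericity"):
            rm_anova_2x3x3(_tidy(rng.normal(size=(4, 2, 3, 3))),
                           sphericity_correction="hf")
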