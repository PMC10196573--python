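"""Sliding-window patch bias, epoch segmentation and panel statistics."""

import numpy as np
import pandas as pd
import pytest

from foragemod.epochs import (EpochSet, WindowBiasSeries, cumulative_pot_time,
                              food_consumption_test, panel_stats,
                              segment_epochs, sliding_window_pot_bias)


def bias_table(n_mice=16, n_windows=30, pot2_extra=None, rng=None):
    """Paired Pot2/Pot1 per-mouse window times; pot2_extra adds seconds to
    Pot2 in the given window set."""
    rng = rng or np.random.default_rng(0)
    pot2_extra = pot2_extra or {}
    rows = []
    for m in range(n_mice):
        sex = "M" if m % 2 == 0 else "F"
        for w in range(n_windows):
            base = rng.gamma(2.0, 0.5)
            rows.append({"mouse_id": m, "sex": sex, "window": w,
                         "win_start_min": float(w), "win_end_min": w + 1.0,
                         "pot": "Pot1", "time_s": base})
            extra = pot2_extra.get(w, 0.0)
            noise = rng.gamma(2.0, 0.5)
            rows.append({"mouse_id": m, "sex": sex, "window": w,
                         "win_start_min": float(w), "win_end_min": w + 1.0,
                         "pot": "Pot2", "time_s": noise + extra})
    return pd.DataFrame(rows)


def series_from(sig, alpha=0.05):
    sig = np.asarray(sig, bool)
    return WindowBiasSeries(
        windows=[(float(i), i + 1.0) for i in range(len(sig))],
        p=np.where(sig, 0.01, 0.5), coef=np.where(sig, 1.0, 0.0),
        significant=sig, per_mouse=pd.DataFrame(), alpha=alpha)


class TestSlidingWindow:
    def test_identical_pot_times_never_significant(self):
        df = bias_table()
        df = df.pivot_table(index=["mouse_id", "sex", "window",
                                   "win_start_min", "win_end_min"],
                            columns="pot", values="time_s").reset_index()
        df["Pot2"] = df["Pot1"]
        long = df.melt(id_vars=["mouse_id", "sex", "window", "win_start_min",
                                "win_end_min"], value_vars=["Pot1", "Pot2"],
                       var_name="pot", value_name="time_s")
        series = sliding_window_pot_bias(long)
        assert not series.significant.any()

    def test_thirty_windows_for_thirty_minutes(self):
        series = sliding_window_pot_bias(bias_table())
        assert series.n_windows == 30

    def test_all_zero_window_flagged_p_one(self):
        df = bias_table()
        df.loc[df["window"] == 5, "time_s"] = 0.0
        series = sliding_window_pot_bias(df)
        assert series.p[5] == 1.0 and not series.significant[5]

    def test_planted_elevation_found_in_right_windows(self):
        rng = np.random.default_rng(1)
        wave = {w: 6.0 for w in range(11, 17)}
        series = sliding_window_pot_bias(bias_table(pot2_extra=wave, rng=rng))
        assert series.significant[11:17].all()
        assert series.significant[0:10].sum() <= 1
        assert series.significant[18:].sum() <= 1


class TestSegmentEpochs:
    def test_stated_transition_example(self):
        sig = np.zeros(30, bool)
        sig[1:10] = True
        sig[12:17] = True
        sig[17:26] = True  # contiguous with previous wave: no new onset
        ep = segment_epochs(series_from(sig), trial_min=30)
        assert ep.onsets == [1, 12]
        assert ep.intervals == [(0.0, 12.0), (12.0, 30.0)]

    def test_no_significant_windows_single_epoch(self):
        ep = segment_epochs(series_from(np.zeros(30, bool)), trial_min=30)
        assert ep.intervals == [(0.0, 30.0)]

    def test_significant_from_window_zero_counts_as_onset(self):
        sig = np.zeros(30, bool)
        sig[0:8] = True
        sig[12:17] = True
        ep = segment_epochs(series_from(sig), trial_min=30)
        assert ep.onsets == [0, 12]
        assert ep.intervals == [(0.0, 12.0), (12.0, 30.0)]

    def test_deterministic_function_of_significance_vector(self):
        rng = np.random.default_rng(0)
        sig = rng.uniform(size=30) < 0.4
        a = segment_epochs(series_from(sig), trial_min=30)
        b = segment_epochs(series_from(sig.copy()), trial_min=30)
        assert a.intervals == b.intervals and a.onsets == b.onsets


class TestCumulative:
    def per_minute(self, vals_by_mouse):
        rows = []
        for m, (geno, vals) in vals_by_mouse.items():
            for minute, v in enumerate(vals):
                rows.append({"mouse_id": m, "sex": "M" if m % 2 else "F",
                             "genotype": geno, "minute": minute, "time_s": v})
        return pd.DataFrame(rows)

    def test_constant_rate_linear_curve_and_endpoint(self):
        rng = np.random.default_rng(0)
        data = {m: ("WT" if m < 4 else "KO",
                    [2.0 + 1e-6 * rng.normal() for _ in range(30)])
                for m in range(8)}
        df = self.per_minute(data)
        cum, res = cumulative_pot_time(df)
        ends = cum.groupby("mouse_id")["cum_time_s"].max()
        assert np.allclose(ends, 60.0, atol=1e-3)
        for _, g in cum.groupby("mouse_id"):
            assert np.all(np.diff(g.sort_values("minute")["cum_time_s"]) >= 0)

    def test_planted_endpoint_reduction_detected(self):
        rng = np.random.default_rng(2)
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            data = {}
            for m in range(30):
                geno = "WT" if m < 15 else "KO"
                scale = 1.0 if geno == "WT" else 0.6
                data[m] = (geno, rng.gamma(2.0, scale, 30))
            _, res = cumulative_pot_time(self.per_minute(data))
            hits += res.p_factor < 0.05
        assert hits >= 18  # >= 90%

    def test_identical_groups_calibrated(self):
        from scipy.stats import kstest
        ps = []
        for s in range(100):
            rng = np.random.default_rng(s)
            data = {m: ("WT" if m < 8 else "KO", rng.gamma(2.0, 1.0, 30))
                    for m in range(16)}
            _, res = cumulative_pot_time(self.per_minute(data))
            ps.append(res.p_factor)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestFoodConsumption:
    def consumption(self, ko_foraging_boost=0.0, rng=None, n=15):
        rng = rng or np.random.default_rng(0)
        rows = []
        mid = 0
        for geno in ("WT", "KO"):
            for sex in ("M", "F"):
                for _ in range(n):
                    mid += 1
                    for phase in ("Exploration", "Foraging"):
                        f = 0.12 + rng.normal(0, 0.02)
                        if geno == "KO" and phase == "Foraging":
                            f += ko_foraging_boost
                        rows.append({"mouse_id": mid, "sex": sex,
                                     "genotype": geno, "phase": phase,
                                     "consumed_frac": float(np.clip(f, 0, 1))})
        return pd.DataFrame(rows)

    def test_constant_consumption_no_interaction(self):
        df = self.consumption()
        df["consumed_frac"] = 0.15
        res = food_consumption_test(df)
        assert np.isnan(res.p_interaction) or res.p_interaction > 0.99

    def test_planted_interaction_detected(self):
        hits = 0
        for s in range(20):
            df = self.consumption(ko_foraging_boost=0.05,
                                  rng=np.random.default_rng(s))
            res = food_consumption_test(df)
            hits += res.p_interaction < 0.05
        assert hits >= 18

    def test_fraction_outside_unit_interval_rejected(self):
        df = self.consumption()
        df.loc[0, "consumed_frac"] = 1.5
        with pytest.raises(ValueError):
            food_consumption_test(df)


class TestPanel:
    def test_identical_latency_pairs_null(self):
        lat = pd.DataFrame({
            "mouse_id": list(range(10)) * 2,
            "phase": ["Exploration"] * 10 + ["Foraging"] * 10,
            "latency_s": [20.0] * 20})
        pot = pd.DataFrame({"mouse_id": list(range(10)) * 4,
                            "pot": np.repeat(["Pot1", "Pot2", "Pot3", "Pot4"], 10),
                            "time_s": np.random.default_rng(0).gamma(2, 1, 40)})
        rep = panel_stats(lat, pot)
        assert rep.latency_t == 0.0 and rep.latency_p == 1.0

    def test_shifted_group_flagged_only_in_its_pairs(self):
        rng = np.random.default_rng(1)
        flags = 0
        trials = 20
        for s in range(trials):
            rng = np.random.default_rng(s)
            times, pots = [], []
            for pot in ("Pot1", "Pot2", "Pot3", "Pot4"):
                mu = 8.0 if pot == "Pot4" else 5.0  # 3 sd shift (sd=1)
                times += list(rng.normal(mu, 1.0, 12))
                pots += [pot] * 12
            pot_df = pd.DataFrame({"mouse_id": range(48), "pot": pots,
                                   "time_s": times})
            lat = pd.DataFrame({"mouse_id": list(range(12)) * 2,
                                "phase": ["E"] * 12 + ["F"] * 12,
                                "latency_s": rng.gamma(3, 5, 24)})
            rep = panel_stats(lat, pot_df)
            tk = rep.tukey
            sig_pairs = tk[tk["reject"]]
            involves_p4 = sig_pairs.apply(
                lambda r: "Pot4" in (r["group1"], r["group2"]), axis=1)
            ok = (rep.anova_p < 0.05 and len(sig_pairs) > 0
                  and involves_p4.all())
            flags += ok
        assert flags >= 0.95 * trials

    def test_two_group_tukey_equals_t_test(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 15)
        b = rng.normal(1, 1, 15)
        pot = pd.DataFrame({"mouse_id": range(30),
                            "pot": ["Pot1"] * 15 + ["Pot2"] * 15,
                            "time_s": np.concatenate([a, b])})
        lat = pd.DataFrame({"mouse_id": list(range(5)) * 2,
                            "phase": ["E"] * 5 + ["F"] * 5,
                            "latency_s": rng.gamma(3, 5, 10)})
        rep = panel_stats(lat, pot)
        from scipy.stats import ttest_ind
        p_t = ttest_ind(a, b).pvalue
        p_tukey = float(rep.tukey["p-adj"].iloc[0])
        assert p_tukey == pytest.approx(p_t, abs=1e-3)
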