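"""Epoch-resolved memory-response statistics.

The memory response to a former food patch is quantified by comparing time
at the former patch (Pot2) with time at a never-baited control patch
(Pot1) in sliding 1-minute windows, with a model that absorbs sex and
tests the patch effect. Contiguous waves of significant Pot2 bias define
behavioral epochs: an epoch starts at every transition from a
non-significant to a significant window. Cumulative patch-time curves,
food-consumption contrasts and the basic panel tests (entry-latency
t-test, pot-preference ANOVA with Tukey post-tests) live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .geometry import ArenaGeometry, ZONE_CODES
from .tracking import Trajectory

__all__ = ["WindowBiasSeries", "pot_time_per_window", "sliding_window_pot_bias",
           "segment_epochs", "cumulative_pot_time", "food_consumption_test",
           "panel_stats", "PanelReport"]


@dataclass
class WindowBiasSeries:
    windows: list[tuple[float, float]]        # minute intervals
    p: np.ndarray                             # per-window patch-effect p
    coef: np.ndarray                          # Pot2-minus-Pot1 effect (s)
    significant: np.ndarray                   # p < alpha and positive bias
    per_mouse: pd.DataFrame                   # long: mouse, sex, window, pot, time
    alpha: float = 0.05

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def pot_time_per_window(trajs: list[Trajectory], pots: tuple[str, str] = ("Pot2", "Pot1"),
                        window_min: float = 1.0, step_min: float = 1.0,
                        trial_min: float = 30.0) -> pd.DataFrame:
    """Per-mouse, per-window dwell time (s) at the two pots.

    Trials must be zone-annotated. Windows tile [0, trial_min] with the
    given width and step (defaults: non-overlapping 1-min bins).
    """
    codes = [ZONE_CODES[p] for p in pots]
    starts = np.arange(0.0, trial_min - window_min + 1e-9, step_min)
    rows = []
    for traj in trajs:
        if traj.zone is None:
            raise ValueError("trajectories must be zone-annotated")
        t0 = traj.t[0]
        rel = traj.t - t0
        for w, s in enumerate(starts):
            m = (rel >= s * 60.0) & (rel < (s + window_min) * 60.0)
            z = traj.zone[m]
            for pot, code in zip(pots, codes):
                rows.append({"mouse_id": traj.mouse_id, "sex": traj.sex,
                             "genotype": traj.genotype, "window": w,
                             "win_start_min": s,
                             "win_end_min": s + window_min,
                             "pot": pot,
                             "time_s": float((z == code).sum()) / traj.frame_rate})
    return pd.DataFrame(rows)


def sliding_window_pot_bias(trajs: list[Trajectory] | pd.DataFrame,
                            window_min: float = 1.0, step_min: float = 1.0,
                            trial_min: float = 30.0,
                            pots: tuple[str, str] = ("Pot2", "Pot1"),
                            alpha: float = 0.05) -> WindowBiasSeries:
    """Windowed Gaussian GLM ``time ~ sex + pot`` over paired per-mouse rows.

    A window is flagged significant when the patch effect has p < alpha
    and the bias favors the first pot (Pot2 by default). Windows where
    every animal logs zero time are flagged with p = 1.
    """
    if isinstance(trajs, pd.DataFrame):
        per_mouse = trajs
    else:
        per_mouse = pot_time_per_window(trajs, pots, window_min, step_min,
                                        trial_min)
    n_sex = per_mouse.groupby("sex")["mouse_id"].nunique()
    if (n_sex < 2).any():
        raise ValueError("need >= 2 mice per sex for the sex-adjusted model")
    windows = sorted(per_mouse["window"].unique())
    intervals, ps, coefs = [], [], []
    for w in windows:
        sub = per_mouse[per_mouse["window"] == w]
        intervals.append((float(sub["win_start_min"].iloc[0]),
                          float(sub["win_end_min"].iloc[0])))
        if np.allclose(sub["time_s"], 0.0):
            ps.append(1.0)
            coefs.append(0.0)
            continue
        sub = sub.copy()
        sub["pot"] = pd.Categorical(sub["pot"], categories=[pots[1], pots[0]])
        fit = smf.glm("time_s ~ C(sex) + C(pot)", data=sub,
                      family=sm.families.Gaussian()).fit()
        term = f"C(pot)[T.{pots[0]}]"
        ps.append(float(fit.pvalues.get(term, 1.0)))
        coefs.append(float(fit.params.get(term, 0.0)))
    p = np.asarray(ps)
    coef = np.asarray(coefs)
    return WindowBiasSeries(windows=intervals, p=p, coef=coef,
                            significant=(p < alpha) & (coef > 0),
                            per_mouse=per_mouse, alpha=alpha)


@dataclass
class EpochSet:
    intervals: list[tuple[float, float]]  # contiguous minute intervals
    onsets: list[int] = field(default_factory=list)  # onset window indices

    @property
    def n_epochs(self) -> int:
        return len(self.intervals)


def segment_epochs(series: WindowBiasSeries, trial_min: float | None = None
                   ) -> EpochSet:
    """Epochs from non-significant -> significant transitions.

    An epoch begins at every window where the bias turns significant after
    a non-significant window (window 0, if significant, starts epoch 1);
    each epoch runs until the next onset. Epoch 1 is extended back to
    minute 0; with no significant window at all the whole trial is one
    epoch.
    """
    sig = np.asarray(series.significant, bool)
    end = trial_min if trial_min is not None else series.windows[-1][1]
    prev = np.concatenate([[False], sig[:-1]])
    onsets = list(np.flatnonzero(sig & ~prev))
    if not onsets:
        return EpochSet(intervals=[(0.0, float(end))], onsets=[])
    bounds = [series.windows[i][0] for i in onsets] + [float(end)]
    bounds[0] = 0.0  # epoch 1 extends back to the trial start
    intervals = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    return EpochSet(intervals=intervals, onsets=onsets)


def cumulative_pot_time(per_minute: pd.DataFrame, factor: str = "genotype"
                        ) -> tuple[pd.DataFrame, "GlmEndpoint"]:
    """Per-mouse cumulative patch-time curves and an endpoint GLM.

    ``per_minute``: long table with mouse_id, sex, ``factor``, window (or
    minute), time_s for one pot. Missing minutes are carried forward with
    a flag. The endpoint model is
    ``endpoint ~ sex + factor + sex:factor`` (Gaussian).
    """
    df = per_minute.copy()
    if "minute" not in df.columns:
        df["minute"] = df["window"]
    full_idx = pd.MultiIndex.from_product(
        [df["mouse_id"].unique(), sorted(df["minute"].unique())],
        names=["mouse_id", "minute"])
    wide = df.set_index(["mouse_id", "minute"])["time_s"].reindex(full_idx)
    carried = wide.isna()
    if carried.any():
        warnings.warn("missing minutes carried forward")
        wide = wide.groupby(level="mouse_id").ffill().fillna(0.0)
    cum = wide.groupby(level="mouse_id").cumsum().rename("cum_time_s").reset_index()
    meta = df.drop_duplicates("mouse_id")[["mouse_id", "sex", factor]]
    cum = cum.merge(meta, on="mouse_id")
    endpoint = cum.loc[cum.groupby("mouse_id")["minute"].idxmax()]
    fit = smf.glm(f"cum_time_s ~ C(sex) * C({factor})", data=endpoint,
                  family=sm.families.Gaussian()).fit()
    term_factor = next((k for k in fit.pvalues.index
                        if k.startswith(f"C({factor})[") and ":" not in k), None)
    term_sex = next((k for k in fit.pvalues.index
                     if k.startswith("C(sex)[") and ":" not in k), None)
    term_int = next((k for k in fit.pvalues.index if ":" in k), None)
    res = GlmEndpoint(
        p_factor=float(fit.pvalues[term_factor]) if term_factor else np.nan,
        p_sex=float(fit.pvalues[term_sex]) if term_sex else np.nan,
        p_interaction=float(fit.pvalues[term_int]) if term_int else np.nan,
        coefficients=dict(fit.params),
    )
    return cum, res


@dataclass
class GlmEndpoint:
    p_factor: float
    p_sex: float
    p_interaction: float
    coefficients: dict[str, float] = field(default_factory=dict)


def food_consumption_test(consumption: pd.DataFrame) -> GlmEndpoint:
    """Genotype x phase interaction on consumed food fraction.

    ``consumption``: mouse_id, sex, genotype, phase, consumed_frac in
    [0, 1]. Gaussian GLM ``consumed ~ sex + genotype * phase``; the
    interaction p is the headline number.
    """
    df = consumption.copy()
    frac = df["consumed_frac"].to_numpy(float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("consumed_frac must lie in [0, 1]")
    fit = smf.glm("consumed_frac ~ C(sex) + C(genotype) * C(phase)", data=df,
                  family=sm.families.Gaussian()).fit()

    def safe_p(term: str | None) -> float:
        # a perfectly constant outcome fits exactly with all effect
        # coefficients at numerical zero; there is no evidence of an effect
        if term is None:
            return np.nan
        if abs(fit.params[term]) < 1e-10 and fit.deviance < 1e-16:
            return 1.0
        return float(fit.pvalues[term])

    term_int = next((k for k in fit.pvalues.index if ":" in k), None)
    term_geno = next((k for k in fit.pvalues.index
                      if k.startswith("C(genotype)[") and ":" not in k), None)
    term_sex = next((k for k in fit.pvalues.index
                     if k.startswith("C(sex)[") and ":" not in k), None)
    return GlmEndpoint(
        p_factor=safe_p(term_geno),
        p_sex=safe_p(term_sex),
        p_interaction=safe_p(term_int),
        coefficients=dict(fit.params),
    )


@dataclass
class PanelReport:
    latency_t: float
    latency_p: float
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame


def panel_stats(latencies: pd.DataFrame, pot_times: pd.DataFrame) -> PanelReport:
    """Entry-latency paired t-test and pot-preference ANOVA with Tukey.

    ``latencies``: mouse_id, phase, latency_s with two phases per mouse
    (paired). ``pot_times``: mouse_id, pot, time_s for the four pots.
    Groups with < 2 observations are excluded with a warning.
    """
    wide = latencies.pivot(index="mouse_id", columns="phase",
                           values="latency_s").dropna()
    phases = list(wide.columns)
    if len(phases) != 2:
        raise ValueError("latency test needs exactly two phases")
    t, p = stats.ttest_rel(wide[phases[0]], wide[phases[1]])
    if np.isnan(t):  # identical pairs: zero variance of differences
        t, p = 0.0, 1.0

    groups = []
    keep_levels = []
    for pot, g in pot_times.groupby("pot"):
        if len(g) < 2:
            warnings.warn(f"pot group {pot} has < 2 observations: excluded")
            continue
        groups.append(g["time_s"].to_numpy(float))
        keep_levels.append(pot)
    f, ap = stats.f_oneway(*groups)
    sub = pot_times[pot_times["pot"].isin(keep_levels)]
    tk = pairwise_tukeyhsd(sub["time_s"], sub["pot"])
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return PanelReport(latency_t=float(t), latency_p=float(p),
                       anova_f=float(f), anova_p=float(ap), tukey=tukey)
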