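"""Module-expression statistics: count tallies and genotype tests.

Expression of a behavioral module is the number of times a mouse performs
it. The headline test is a Poisson GLM interaction contrast — does the
profile of module usage differ by genotype? — followed by per-module
post-tests, a variance pre-filter, q-value FDR control, residual-deviance
goodness-of-fit checks, and epoch-wise contingency/heatmap analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.cluster.hierarchy import leaves_list
from scipy.special import gammaln

from .excursions import parse_cimar
from .module_detection import ModuleCatalog
from .qvalue import qvalues

__all__ = ["GlmResult", "PosttestResult", "tally_module_expression",
           "interaction_glm_test", "per_module_posttests", "poisson_gof_test",
           "epoch_contingency_test", "fisher_exact_rxc"]


@dataclass
class GlmResult:
    formula: str
    lrt_stat: float
    df: int
    p: float
    coefficients: dict[str, float] = field(default_factory=dict)
    gof_stat: float | None = None
    gof_df: int | None = None
    gof_p: float | None = None
    converged: bool = True


@dataclass
class PosttestResult:
    per_module: pd.DataFrame  # module, coef, lrt_stat, p, q, gof_p
    pi0: float
    filtered_out: list[str]
    q_threshold: float = 0.05

    @property
    def significant(self) -> list[str]:
        df = self.per_module
        return list(df.loc[df["q"] < self.q_threshold, "module"])


def tally_module_expression(catalog: ModuleCatalog,
                            excursion_index: pd.DataFrame,
                            epochs: list[tuple[float, float]] | None = None,
                            include_nonmodular: bool = True) -> pd.DataFrame:
    """Count label expression per mouse x phase (x epoch).

    ``excursion_index`` needs columns cimar and start_time_s (the
    excursion-index export). An excursion counts in the epoch containing
    its start time; starts outside every epoch land in a residual bin
    with a warning. Row totals conserve each mouse's labeled excursions.
    """
    rows = []
    warned = False
    for cimar, start in zip(excursion_index["cimar"],
                            excursion_index["start_time_s"]):
        label = catalog.labels.get(cimar)
        if label is None or label == "0":
            continue
        if not include_nonmodular and not label.startswith("M"):
            continue
        key = parse_cimar(cimar)
        epoch = None
        if epochs is not None:
            minute = start / 60.0
            for e, (a, b) in enumerate(epochs, start=1):
                if a <= minute < b:
                    epoch = e
                    break
            if epoch is None:
                epoch = 0  # residual bin
                if not warned:
                    warnings.warn("excursion starts outside all epochs: "
                                  "counted in residual epoch 0")
                    warned = True
        rows.append({"mouse_id": key.mouse_number, "sex": key.sex,
                     "genotype": key.genotype, "phase": key.phase,
                     "epoch": epoch, "label": label})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no labeled excursions to tally")
    group_cols = ["mouse_id", "sex", "genotype", "phase"]
    if epochs is not None:
        group_cols.append("epoch")
    table = (df.groupby(group_cols + ["label"]).size()
               .unstack("label", fill_value=0).reset_index())
    return table


def _count_long(table: pd.DataFrame, modules: list[str] | None = None
                ) -> pd.DataFrame:
    id_cols = [c for c in ("mouse_id", "sex", "genotype", "phase", "epoch")
               if c in table.columns]
    mods = modules or [c for c in table.columns if c not in id_cols]
    long = table.melt(id_vars=id_cols, value_vars=mods,
                      var_name="module", value_name="count")
    long["count"] = long["count"].astype(int)
    return long


def interaction_glm_test(table: pd.DataFrame,
                         modules: list[str] | None = None) -> GlmResult:
    """Genotype x module interaction via nested Poisson GLMs.

    Fits ``count ~ sex + genotype + module + genotype:module`` against the
    main-effects model and reports the likelihood-ratio test for the
    interaction block.
    """
    long = _count_long(table, modules)
    mods = long["module"].unique()
    genos = long["genotype"].unique()
    if len(mods) < 2 or len(genos) < 2:
        raise ValueError("need >= 2 modules and both genotypes")
    full = smf.glm("count ~ C(sex) + C(genotype) * C(module)", data=long,
                   family=sm.families.Poisson()).fit()
    nested = smf.glm("count ~ C(sex) + C(genotype) + C(module)", data=long,
                     family=sm.families.Poisson()).fit()
    if not (full.converged and nested.converged):
        raise RuntimeError("Poisson GLM did not converge: "
                           f"full={full.converged} nested={nested.converged}")
    stat = 2.0 * (full.llf - nested.llf)
    df = int(full.df_model - nested.df_model)
    p = float(stats.chi2.sf(max(stat, 0.0), df)) if df > 0 else 1.0
    gof_stat, gof_df, gof_p = poisson_gof_test(full)
    return GlmResult(
        formula="count ~ sex + genotype + module + genotype:module",
        lrt_stat=float(max(stat, 0.0)), df=df, p=max(p, np.finfo(float).tiny),
        coefficients=dict(full.params),
        gof_stat=gof_stat, gof_df=gof_df, gof_p=gof_p,
    )


def per_module_posttests(table: pd.DataFrame, variance_quantile: float = 0.1,
                         q_threshold: float = 0.05,
                         modules: list[str] | None = None) -> PosttestResult:
    """Per-module genotype effect: ``count ~ sex + genotype``.

    Modules with expression variance at or below the ``variance_quantile``
    quantile (and all zero-variance modules) are filtered out before
    testing; q-values are computed over the survivors.
    """
    long = _count_long(table, modules)
    variances = long.groupby("module")["count"].var().fillna(0.0)
    if (variances == 0).all():
        warnings.warn("all modules have zero expression variance")
        return PosttestResult(pd.DataFrame(columns=["module", "coef",
                                                    "lrt_stat", "p", "q",
                                                    "gof_p"]),
                              pi0=1.0, filtered_out=list(variances.index),
                              q_threshold=q_threshold)
    cutoff = float(np.quantile(variances, variance_quantile))
    keep = variances.index[(variances > 0) & (variances > cutoff)]
    filtered = [m for m in variances.index if m not in set(keep)]
    recs = []
    for mod in keep:
        sub = long[long["module"] == mod]
        full = smf.glm("count ~ C(sex) + C(genotype)", data=sub,
                       family=sm.families.Poisson()).fit()
        nested = smf.glm("count ~ C(sex)", data=sub,
                         family=sm.families.Poisson()).fit()
        stat = max(0.0, 2.0 * (full.llf - nested.llf))
        p = float(stats.chi2.sf(stat, 1))
        geno_coef = next((v for k, v in full.params.items()
                          if k.startswith("C(genotype)")), np.nan)
        _, _, gof_p = poisson_gof_test(full)
        recs.append({"module": mod, "coef": float(geno_coef),
                     "lrt_stat": stat, "p": max(p, np.finfo(float).tiny),
                     "gof_p": gof_p})
    df = pd.DataFrame(recs)
    if df.empty:
        warnings.warn("variance filter removed every module")
        return PosttestResult(df.assign(q=[]), pi0=1.0,
                              filtered_out=filtered, q_threshold=q_threshold)
    q, pi0 = qvalues(df["p"].to_numpy())
    df["q"] = q
    return PosttestResult(df.sort_values("p").reset_index(drop=True),
                          pi0=pi0, filtered_out=filtered,
                          q_threshold=q_threshold)


def poisson_gof_test(fit) -> tuple[float, int, float]:
    """Chi-square test of residual deviance at residual df.

    Returns (statistic, df, p); df <= 0 yields (deviance, df, nan).
    """
    dev = float(fit.deviance)
    df = int(fit.df_resid)
    if df <= 0:
        return dev, df, float("nan")
    return dev, df, float(stats.chi2.sf(dev, df))


# -- contingency / heatmap ------------------------------------------------

def _log_table_prob(tab: np.ndarray) -> float:
    """Log conditional probability of an r x c table given its margins."""
    tab = np.asarray(tab)
    r = tab.sum(axis=1)
    c = tab.sum(axis=0)
    n = tab.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(tab + 1).sum())


def fisher_exact_rxc(table: np.ndarray, n_draws: int = 100_000,
                     seed: int = 0) -> float:
    """Exact (2x2) or Monte-Carlo exact (larger) independence p-value.

    The Monte-Carlo version samples tables with the observed margins
    (Patefield's algorithm) and scores them by conditional probability,
    with +1 smoothing.
    """
    tab = np.asarray(table, dtype=int)
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency test needs >= 2 non-empty rows and columns")
    if tab.shape == (2, 2):
        return float(stats.fisher_exact(tab)[1])
    rng = np.random.default_rng(seed)
    obs = _log_table_prob(tab)
    sampler = stats.random_table(tab.sum(axis=1), tab.sum(axis=0))
    draws = sampler.rvs(n_draws, random_state=rng)
    lp = np.array([_log_table_prob(d) for d in draws])
    return float((1 + (lp <= obs + 1e-9).sum()) / (1 + n_draws))


@dataclass
class ContingencyResult:
    scaled: pd.DataFrame          # column-scaled heatmap matrix
    column_order: list[str]       # hierarchical clustering leaf order
    linkage: np.ndarray
    p: float
    method: str                   # "chi2" | "exact" | "monte-carlo"
    statistic: float | None = None


def epoch_contingency_test(counts: pd.DataFrame, seed: int = 0
                           ) -> ContingencyResult:
    """Module x group dependence test with a column-scaled heatmap matrix.

    ``counts``: rows = modules, columns = groups (aggregated counts).
    Columns are z-scored for the heatmap and hierarchically clustered
    (Ward). Dependence uses a chi-square test, switching to an exact /
    Monte-Carlo test when more than 20% of expected cells are < 5.
    """
    tab = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    if tab.shape != counts.shape:
        warnings.warn("dropped all-zero rows/columns from contingency table")
    arr = tab.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 non-empty rows and columns")

    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0
    scaled = pd.DataFrame((arr - mu) / sd, index=tab.index, columns=tab.columns)

    from .treecut import ward_linkage
    Z = ward_linkage(scaled.to_numpy().T)
    order = [tab.columns[i] for i in leaves_list(Z)]

    stat, p, dof, expected = stats.chi2_contingency(arr)
    if (expected < 5).mean() > 0.2:
        p = fisher_exact_rxc(arr.astype(int), seed=seed)
        method = "exact" if arr.shape == (2, 2) else "monte-carlo"
        stat = None
    else:
        method = "chi2"
        stat = float(stat)
    return ContingencyResult(scaled=scaled, column_order=order, linkage=Z,
                             p=float(p), method=method, statistic=stat)
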