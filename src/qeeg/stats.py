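"""Group-comparison statistics layer.

Mirrors the analysis toolchain the study used (Prism-style conventions):

* two-group comparison with an F-ratio variance pre-test deciding
  between the pooled Student t and Welch's t;
* two-way genotype × frequency ANOVA (Type III sums of squares for
  unbalanced designs) with Sidak-adjusted per-frequency post hoc
  comparisons on the pooled residual;
* single-outlier two-sided Grubbs screening;
* bias-corrected and accelerated (BCa) bootstrap of the two-group mean
  difference with 5000 resamples by default (Gardner–Altman estimation).

Balanced ANOVA designs use a direct cell-means decomposition; unbalanced
designs are delegated to a sum-contrast OLS fit with Type III ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import InputError

__all__ = [
    "TTestResult", "AnovaResult", "PosthocRow", "EstimationResult", "GrubbsResult",
    "compare_groups_t", "two_way_anova_power", "sidak_posthoc",
    "grubbs_test", "bootstrap_mean_difference", "render_estimation_data",
    "significance_code",
]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    ci95: tuple[float, float]
    welch_used: bool
    var_pretest_p: float


@dataclass
class AnovaResult:
    F_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float
    F_frequency: float
    df_frequency: tuple[int, int]
    p_frequency: float
    F_genotype: float
    df_genotype: tuple[int, int]
    p_genotype: float
    cell_means: pd.DataFrame
    mse: float
    df_resid: int


@dataclass
class PosthocRow:
    frequency_hz: float
    mean1: float
    mean2: float
    ci95_diff: tuple[float, float]
    p_adj: float
    significance: str


@dataclass
class EstimationResult:
    mean_diff: float
    ci95_bca: tuple[float, float]
    n_boot: int
    seed: int
    bias_z0: float
    accel: float
    bootstrap_distribution: np.ndarray


@dataclass
class GrubbsResult:
    candidate_index: int
    G: float
    G_crit: float
    is_outlier: bool


def significance_code(p: float) -> str:
    """Prism-style stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups_t(a, b, alpha_var: float = 0.05) -> TTestResult:
    """Two-sided two-sample t test with an F-ratio variance pre-test.

    The pre-test compares the larger to the smaller sample variance at
    ``alpha_var`` (two-sided); if variances differ significantly,
    Welch's t with Satterthwaite df is used, otherwise the pooled
    Student t. Returns the statistic with mean(a) − mean(b) orientation
    and the 95% CI of that difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs n >= 2")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        p_var = 1.0
    else:
        hi, lo = (va, vb) if va >= vb else (vb, va)
        dfh, dfl = (len(a) - 1, len(b) - 1) if va >= vb else (len(b) - 1, len(a) - 1)
        F = np.inf if lo == 0 else hi / lo
        p_var = min(1.0, 2.0 * sst.f.sf(F, dfh, dfl))
    welch = p_var < alpha_var

    res = sst.ttest_ind(a, b, equal_var=not welch)
    diff = float(np.mean(a) - np.mean(b))
    if welch:
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
        se = float(np.sqrt(va / len(a) + vb / len(b)))
    else:
        df = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / df
        se = float(np.sqrt(sp2 * (1 / len(a) + 1 / len(b))))
    if se == 0:
        ci = (diff, diff)
    else:
        tcrit = sst.t.ppf(0.975, df)
        ci = (diff - tcrit * se, diff + tcrit * se)
    t_stat = float(res.statistic) if np.isfinite(res.statistic) else 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return TTestResult(t=t_stat, df=float(df), p=p, ci95=ci,
                       welch_used=bool(welch), var_pretest_p=float(p_var))


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"value", "genotype", "frequency"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"ANOVA table missing columns: {sorted(missing)}")
    counts = table.groupby(["genotype", "frequency"], observed=True).size()
    geno = table["genotype"].unique()
    freq = table["frequency"].unique()
    if len(geno) < 2 or len(freq) < 2:
        raise InputError("need >= 2 levels per factor")
    for g in geno:
        for f in freq:
            if (g, f) not in counts.index:
                raise InputError(f"empty cell in crossed design: "
                                 f"genotype={g!r}, frequency={f!r}")
    return table


def _f_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> tuple[float, float]:
    # degenerate data (zero residual and zero effect) reads as "no effect"
    if ss_err <= 1e-300:
        if ss_eff <= 1e-300:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_eff / df_eff) / (ss_err / df_err)
    return float(F), float(sst.f.sf(F, df_eff, df_err))


def _anova_balanced(table: pd.DataFrame) -> AnovaResult:
    piv = table.pivot_table(index="genotype", columns="frequency",
                            values="value", aggfunc="mean", observed=True)
    n = int(table.groupby(["genotype", "frequency"], observed=True).size().iloc[0])
    a, b = piv.shape
    grand = float(table["value"].mean())
    row_means = piv.mean(axis=1).to_numpy()
    col_means = piv.mean(axis=0).to_numpy()
    cells = piv.to_numpy()
    ss_a = n * b * float(np.sum((row_means - grand) ** 2))
    ss_b = n * a * float(np.sum((col_means - grand) ** 2))
    ss_ab = n * float(np.sum((cells - row_means[:, None] - col_means[None, :] + grand) ** 2))
    cell_of = table.set_index(["genotype", "frequency"]).index
    fitted = pd.Series(cells.reshape(-1),
                       index=pd.MultiIndex.from_product([piv.index, piv.columns]))
    resid = table["value"].to_numpy() - fitted.loc[cell_of].to_numpy()
    ss_e = float(np.sum(resid ** 2))
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (n - 1)
    if df_e <= 0:
        raise InputError("no residual degrees of freedom (n=1 per cell)")
    F_a, p_a = _f_p(ss_a, df_a, ss_e, df_e)
    F_b, p_b = _f_p(ss_b, df_b, ss_e, df_e)
    F_ab, p_ab = _f_p(ss_ab, df_ab, ss_e, df_e)
    return AnovaResult(
        F_interaction=F_ab, df_interaction=(df_ab, df_e), p_interaction=p_ab,
        F_frequency=F_b, df_frequency=(df_b, df_e), p_frequency=p_b,
        F_genotype=F_a, df_genotype=(df_a, df_e), p_genotype=p_a,
        cell_means=piv, mse=ss_e / df_e, df_resid=df_e)


def _anova_type3(table: pd.DataFrame) -> AnovaResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table.copy()
    data["genotype"] = data["genotype"].astype(str)
    data["frequency"] = data["frequency"].astype(str)
    model = smf.ols(
        "value ~ C(genotype, Sum) * C(frequency, Sum)", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = sm.stats.anova_lm(model, typ=3)
    piv = table.pivot_table(index="genotype", columns="frequency",
                            values="value", aggfunc="mean", observed=True)

    def row(name):
        r = tab.loc[name]
        return float(r["F"]), int(r["df"]), float(r["PR(>F)"])

    df_e = int(tab.loc["Residual", "df"])
    mse = float(tab.loc["Residual", "sum_sq"]) / df_e
    F_g, df_g, p_g = row("C(genotype, Sum)")
    F_f, df_f, p_f = row("C(frequency, Sum)")
    F_i, df_i, p_i = row("C(genotype, Sum):C(frequency, Sum)")
    return AnovaResult(
        F_interaction=F_i, df_interaction=(df_i, df_e), p_interaction=p_i,
        F_frequency=F_f, df_frequency=(df_f, df_e), p_frequency=p_f,
        F_genotype=F_g, df_genotype=(df_g, df_e), p_genotype=p_g,
        cell_means=piv, mse=mse, df_resid=df_e)


def two_way_anova_power(table: pd.DataFrame) -> AnovaResult:
    """Two-way genotype × frequency ANOVA on a long-format table.

    ``table`` has columns ``value``, ``genotype``, ``frequency``.
    Balanced designs use the classic cell-means decomposition;
    unbalanced designs use Type III sums of squares (sum-to-zero
    contrasts), matching the analysis software's convention.
    """
    table = _check_table(table)
    counts = table.groupby(["genotype", "frequency"], observed=True).size()
    if counts.nunique() == 1:
        return _anova_balanced(table)
    return _anova_type3(table)


def sidak_posthoc(table: pd.DataFrame, alpha: float = 0.05,
                  anova: AnovaResult | None = None) -> list[PosthocRow]:
    """Per-frequency genotype comparisons with Sidak adjustment.

    Each frequency level contributes one comparison of the two genotype
    means using the pooled ANOVA residual; p_adj = 1 − (1 − p_raw)^m
    over the m frequency levels, and the simultaneous 95% CI uses the
    Sidak-adjusted critical value on the residual df.
    """
    table = _check_table(table)
    anova = anova or two_way_anova_power(table)
    freqs = sorted(table["frequency"].unique())
    m = len(freqs)
    if m == 0:
        raise InputError("no frequency levels to compare")
    genos = sorted(table["genotype"].unique())
    if len(genos) != 2:
        raise InputError("post hoc comparisons require exactly 2 genotypes")
    g1, g2 = genos
    alpha_per = 1.0 - (1.0 - alpha) ** (1.0 / m)
    tcrit = sst.t.ppf(1.0 - alpha_per / 2.0, anova.df_resid)
    rows = []
    for f in freqs:
        x1 = table.loc[(table.genotype == g1) & (table.frequency == f), "value"]
        x2 = table.loc[(table.genotype == g2) & (table.frequency == f), "value"]
        diff = float(x1.mean() - x2.mean())
        se = float(np.sqrt(anova.mse * (1 / len(x1) + 1 / len(x2))))
        if se == 0:
            p_raw = 1.0 if diff == 0 else 0.0
            ci = (diff, diff)
        else:
            t = diff / se
            p_raw = float(2.0 * sst.t.sf(abs(t), anova.df_resid))
            ci = (diff - tcrit * se, diff + tcrit * se)
        p_adj = float(1.0 - (1.0 - p_raw) ** m)
        rows.append(PosthocRow(frequency_hz=float(f), mean1=float(x1.mean()),
                               mean2=float(x2.mean()), ci95_diff=ci,
                               p_adj=p_adj, significance=significance_code(p_adj)))
    return rows


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    G = max|x − x̄| / s against the t-based critical value
    ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) quantile on
    n−2 df.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise InputError("Grubbs test needs n >= 3")
    s = np.std(x, ddof=1)
    if s == 0:
        raise InputError("Grubbs test undefined for zero-variance data")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    G = float(dev[idx] / s)
    t = sst.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    G_crit = float((n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2)))
    return GrubbsResult(candidate_index=idx, G=G, G_crit=G_crit,
                        is_outlier=bool(G > G_crit))


def bootstrap_mean_difference(a, b, n_boot: int = 5000,
                              seed: int | None = 0) -> EstimationResult:
    """BCa bootstrap CI for mean(b) − mean(a) (Gardner–Altman convention).

    Groups are resampled independently with replacement; bias
    correction comes from the bootstrap CDF at the observed statistic
    and acceleration from the jackknife skewness. Identical seed gives
    identical output.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs n >= 2")
    seed = 0 if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    observed = float(np.mean(b) - np.mean(a))
    boot = (b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1)
            - a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1))

    if np.ptp(boot) == 0.0:
        warnings.warn("degenerate bootstrap distribution; returning point interval",
                      RuntimeWarning, stacklevel=2)
        return EstimationResult(mean_diff=observed, ci95_bca=(observed, observed),
                                n_boot=n_boot, seed=seed, bias_z0=0.0, accel=0.0,
                                bootstrap_distribution=boot)

    # bias correction
    prop = np.mean(boot < observed) + 0.5 * np.mean(boot == observed)
    prop = min(max(prop, 1.0 / (2 * n_boot)), 1.0 - 1.0 / (2 * n_boot))
    z0 = float(sst.norm.ppf(prop))

    # acceleration from delete-one jackknife over both groups
    jack = []
    sum_a, sum_b = a.sum(), b.sum()
    for i in range(len(a)):
        jack.append(np.mean(b) - (sum_a - a[i]) / (len(a) - 1))
    for j in range(len(b)):
        jack.append((sum_b - b[j]) / (len(b) - 1) - np.mean(a))
    jack = np.asarray(jack)
    dev = jack.mean() - jack
    denom = np.sum(dev ** 2) ** 1.5
    accel = float(np.sum(dev ** 3) / (6.0 * denom)) if denom > 0 else 0.0

    zlo, zhi = sst.norm.ppf(0.025), sst.norm.ppf(0.975)

    def adj(z):
        num = z0 + z
        return float(sst.norm.cdf(z0 + num / (1.0 - accel * num)))

    lo = float(np.quantile(boot, adj(zlo), method="linear"))
    hi = float(np.quantile(boot, adj(zhi), method="linear"))
    return EstimationResult(mean_diff=observed, ci95_bca=(lo, hi),
                            n_boot=n_boot, seed=seed, bias_z0=z0, accel=accel,
                            bootstrap_distribution=boot)


def render_estimation_data(res: EstimationResult, a, b) -> dict:
    """Serializable payload for a Gardner–Altman estimation plot."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    qs = np.linspace(0.0, 1.0, 101)
    return {
        "group1": {"values": a.tolist(), "mean": float(a.mean()), "n": len(a)},
        "group2": {"values": b.tolist(), "mean": float(b.mean()), "n": len(b)},
        "mean_diff": res.mean_diff,
        "ci95_bca": list(res.ci95_bca),
        "n_boot": res.n_boot,
        "seed": res.seed,
        "bootstrap_quantiles": {f"{q:.2f}": float(np.quantile(res.bootstrap_distribution, q))
                                for q in qs},
    }
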