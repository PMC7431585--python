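"""Statistical toolbox and the two scripted analyses.

Provides the tests used by the behavioral and lateralization analyses:
paired/one-sample t-tests with Hedges g / g1, Wilcoxon signed-rank,
one-way repeated-measures ANOVA with Mauchly's sphericity test and
Greenhouse-Geisser correction, Friedman's ANOVA, a Lilliefors normality
gate, uncapped Benjamini-Hochberg FDR, and default-prior JZS Bayes factors.

Conventions follow the study: all t-family tests are two-tailed; adjusted
p-values are deliberately *not* capped at 1; parametric tests are used only
when the Lilliefors test does not reject normality (p > .05), otherwise the
rank-based alternative is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sp_stats

from .containers import condition_of
from .simulate import MIN_RT_MS, RESPONSE_LIMIT_MS

__all__ = [
    "TestResult",
    "paired_t",
    "one_sample_t",
    "wilcoxon_signed_rank",
    "rm_anova_1way",
    "friedman",
    "hedges_g",
    "hedges_g1",
    "fdr_bh",
    "bf_ttest",
    "lilliefors",
    "behavioral_analysis",
    "ali_followup",
]

JZS_DEFAULT_SCALE = math.sqrt(2.0) / 2.0


@dataclass
class TestResult:
    """One inferential test: statistic, p, effect size, Bayes factor."""

    name: str
    statistic: float
    df: float | tuple
    p: float
    p_adj: float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    bf: float | None = None
    tails: str = "two"
    family: str | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p": self.p,
            "p_adj": self.p_adj,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "bf": self.bf,
            "tails": self.tails,
            "family": self.family,
        }
        d.update(self.extra)
        return d


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def _small_sample_j(df: float) -> float:
    """Hedges' small-sample correction J = 1 - 3/(4 df - 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(x, y) -> float:
    """Paired-design Hedges g: mean difference over SD of differences, J-corrected."""
    d = np.asarray(x, float) - np.asarray(y, float)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(d.mean() / sd * _small_sample_j(d.size - 1))


def hedges_g1(x, mu0: float = 0.0) -> float:
    """One-sample Hedges g1: (mean - mu0) / SD, J-corrected."""
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((x.mean() - mu0) / sd * _small_sample_j(x.size - 1))


# ---------------------------------------------------------------------------
# t-family
# ---------------------------------------------------------------------------

def paired_t(x, y, name: str = "paired_t", family: str | None = None,
             with_bf: bool = True) -> TestResult:
    """Two-tailed paired t-test with Hedges g and JZS Bayes factor."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x, y must be equal-length 1-D with n >= 2")
    d = x - y
    n = x.size
    if d.std(ddof=1) == 0:
        if d.mean() != 0:
            raise ValueError("zero variance of differences")
        t, p = 0.0, 1.0
    else:
        res = sp_stats.ttest_rel(x, y)
        t, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        name=name, statistic=t, df=n - 1, p=p,
        effect_size=hedges_g(x, y), effect_size_name="g",
        bf=bf_ttest(t, n) if with_bf else None, family=family,
    )


def one_sample_t(x, mu0: float = 0.0, name: str = "one_sample_t",
                 family: str | None = None, with_bf: bool = True) -> TestResult:
    """Two-tailed one-sample t-test against mu0 with Hedges g1 and BF."""
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be 1-D with n >= 2")
    if x.std(ddof=1) == 0:
        if x.mean() != mu0:
            raise ValueError("zero variance")
        t, p = 0.0, 1.0
    else:
        res = sp_stats.ttest_1samp(x, mu0)
        t, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        name=name, statistic=t, df=x.size - 1, p=p,
        effect_size=hedges_g1(x, mu0), effect_size_name="g1",
        bf=bf_ttest(t, x.size) if with_bf else None, family=family,
    )


def wilcoxon_signed_rank(x, y=None, name: str = "wilcoxon",
                         family: str | None = None) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test.

    Uses the exact null distribution for n <= 25 without ties, otherwise the
    normal approximation with tie and continuity corrections.  Zero
    differences are dropped.
    """
    x = np.asarray(x, float)
    d = x if y is None else x - np.asarray(y, float)
    d = d[d != 0]
    if d.size < 2:
        raise ValueError("need >= 2 nonzero differences")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sp_stats.wilcoxon(d, alternative="two-sided", method=method,
                            correction=(method == "approx"))
    g = hedges_g1(d) if y is None else 0.0
    return TestResult(
        name=name, statistic=float(res.statistic), df=d.size, p=float(res.pvalue),
        effect_size=g if y is None else hedges_g(x, np.asarray(y, float)),
        effect_size_name="g" if y is not None else "g1",
        family=family, extra={"method": method},
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA and Friedman
# ---------------------------------------------------------------------------

def rm_anova_1way(data: np.ndarray, name: str = "rm_anova",
                  family: str | None = None) -> TestResult:
    """One-way repeated-measures ANOVA on a complete subject x level matrix.

    Reports F with (k-1, (k-1)(n-1)) df and partial eta-squared; Mauchly's
    sphericity test is run and, when it rejects (p < .05), both df are
    multiplied by the Greenhouse-Geisser epsilon.  For k = 2 sphericity
    holds trivially and epsilon is exactly 1.
    """
    import pingouin as pg

    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[1] < 2 or data.shape[0] < 3:
        raise ValueError("need a subject x level matrix, >=3 subjects, >=2 levels")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    n, k = data.shape
    # degenerate case: no between-level variation at all -> F is exactly 0
    if np.allclose(n * np.sum((data.mean(axis=0) - data.mean()) ** 2), 0.0):
        return TestResult(
            name=name, statistic=0.0, df=(k - 1.0, (k - 1.0) * (n - 1.0)), p=1.0,
            effect_size=0.0, effect_size_name="eta_p2", family=family,
            extra={"mauchly_p": 1.0, "gg_epsilon": 1.0, "gg_applied": False},
        )
    wide = pd.DataFrame(data, columns=[f"l{j}" for j in range(k)])
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="level", value_name="y"
    )
    aov = pg.rm_anova(data=long, dv="y", within="level", subject="subject",
                      detailed=True, correction=True, effsize="np2")
    row = aov.iloc[0]
    spher = pg.sphericity(data=long, dv="y", within="level", subject="subject")
    eps = float(pg.epsilon(wide, correction="gg")) if k > 2 else 1.0
    mauchly_p = float(spher.pval) if k > 2 else 1.0
    corrected = k > 2 and mauchly_p < 0.05
    df1, df2 = float(row["DF"]), float(aov.iloc[1]["DF"])
    if corrected:
        df1, df2 = df1 * eps, df2 * eps
        p = float(row["p_GG_corr"])
    else:
        p = float(row["p_unc"])
    return TestResult(
        name=name, statistic=float(row["F"]), df=(df1, df2), p=p,
        effect_size=float(row["np2"]), effect_size_name="eta_p2",
        family=family,
        extra={"mauchly_p": mauchly_p, "gg_epsilon": eps, "gg_applied": corrected},
    )


def friedman(data: np.ndarray, name: str = "friedman",
             family: str | None = None) -> TestResult:
    """Friedman's rank-based ANOVA (chi-square with k-1 df, mid-ranks for ties)."""
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError("need a subject x level matrix, >=2 subjects, >=2 levels")
    if np.allclose(data, data[:, :1]):
        # constant rows: chi-square is exactly 0 (scipy refuses all-tied input)
        return TestResult(name=name, statistic=0.0, df=data.shape[1] - 1, p=1.0,
                          family=family)
    res = sp_stats.friedmanchisquare(*[data[:, j] for j in range(data.shape[1])])
    return TestResult(
        name=name, statistic=float(res.statistic), df=data.shape[1] - 1,
        p=float(res.pvalue), family=family,
    )


# ---------------------------------------------------------------------------
# normality gate, FDR, Bayes factors
# ---------------------------------------------------------------------------

def lilliefors(x, name: str = "lilliefors") -> TestResult:
    """Lilliefors (KS with estimated mean/SD) test of normality."""
    from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

    x = np.asarray(x, float)
    if x.size < 4:
        raise ValueError("Lilliefors test needs n >= 4")
    stat, p = sm_lilliefors(x, dist="norm")
    return TestResult(name=name, statistic=float(stat), df=x.size, p=float(p))


def fdr_bh(p_values, method: str = "indep") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, uncapped.

    ``method='indep'`` is the classic BH procedure; ``method='dep'`` applies
    the Benjamini-Yekutieli correction factor for arbitrary dependence,
    under which adjusted values above 1 arise naturally (they are reported
    as-is rather than clipped).
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    cm = np.sum(1.0 / np.arange(1, m + 1)) if method == "dep" else 1.0
    if method not in ("indep", "dep"):
        raise ValueError("method must be 'indep' or 'dep'")
    raw = ranked * m * cm / np.arange(1, m + 1)
    adj = np.minimum.accumulate(raw[::-1])[::-1]   # enforce monotone step-up
    out = np.empty(m)
    out[order] = adj
    return out


def _jzs_integrand_delta(delta: np.ndarray, t: float, n: int, scale: float) -> np.ndarray:
    nu = n - 1
    like = sp_stats.nct.pdf(t, nu, delta * math.sqrt(n))
    prior = sp_stats.cauchy.pdf(delta, loc=0.0, scale=scale)
    return like * prior


def bf_ttest(t: float, n: int, scale: float = JZS_DEFAULT_SCALE) -> float:
    """JZS (Cauchy-prior) Bayes factor BF10 for a one-sample/paired t statistic.

    Marginal likelihood under H1 integrates the noncentral-t likelihood over
    a Cauchy(0, scale) prior on the standardized effect size (default scale
    sqrt(2)/2); H0 is the central t density.  Computed by adaptive
    quadrature.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    nu = n - 1
    h0 = sp_stats.t.pdf(t, nu)
    h1, err = integrate.quad(
        _jzs_integrand_delta, -np.inf, np.inf, args=(float(t), int(n), float(scale)),
        limit=200, epsabs=0.0, epsrel=1e-10,
    )
    if not np.isfinite(h1) or h1 <= 0 or err > 1e-6 * max(h1, 1e-300):
        raise RuntimeError(f"JZS integration failed (value={h1}, err={err})")
    return float(h1 / h0)


# ---------------------------------------------------------------------------
# scripted analyses
# ---------------------------------------------------------------------------

def mark_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag late (> response deadline), premature (< 200 ms) and missing
    responses as erroneous; returns a copy with ``correct`` updated."""
    t = trials.copy()
    missing = t["response"] == "none"
    late = t["rt_ms"] > RESPONSE_LIMIT_MS   # NaN compares False
    premature = t["rt_ms"] < MIN_RT_MS
    t.loc[missing | late | premature, "correct"] = False
    return t


def _gated_paired(x, y, name, family) -> TestResult:
    """Paired t if the difference scores pass the Lilliefors gate, else Wilcoxon."""
    d = np.asarray(x, float) - np.asarray(y, float)
    use_parametric = True
    if d.size >= 4:
        use_parametric = lilliefors(d).p > 0.05
    if use_parametric:
        return paired_t(x, y, name=name, family=family)
    res = wilcoxon_signed_rank(x, y, name=name, family=family)
    res.bf = None
    return res


def _subject_cells(trials: pd.DataFrame) -> dict:
    """Per-subject condition means used by the two behavioral analyses."""
    t = mark_errors(trials)
    t = t[~t["rejected"]]
    t = t.assign(condition=t["retrocue"].map(condition_of))
    # cue-type contrast excludes non-cued probes (absent for neutral cues)
    bal = t[t["probe"] != "noncued"]
    sel, neu = bal[bal["condition"] != "neutral"], bal[bal["condition"] == "neutral"]
    out = {
        "rt_selective": sel.loc[sel["correct"], "rt_ms"].mean(),
        "rt_neutral": neu.loc[neu["correct"], "rt_ms"].mean(),
        "acc_selective": sel["correct"].mean(),
        "acc_neutral": neu["correct"].mean(),
    }
    sel_all = t[t["condition"] != "neutral"]
    for probe in ("cued", "noncued", "new"):
        cell = sel_all[sel_all["probe"] == probe]
        if len(cell) == 0:
            raise ValueError(f"subject lacks trials in selective/{probe} cell")
        out[f"rt_{probe}"] = cell.loc[cell["correct"], "rt_ms"].mean()
        out[f"acc_{probe}"] = cell["correct"].mean()
    if np.isnan(list(out.values())).any():
        empty = [k for k, v in out.items() if np.isnan(v)]
        raise ValueError(f"subject has empty analysis cells: {empty}")
    return out


def behavioral_analysis(subject_tables: list[pd.DataFrame]) -> dict[str, TestResult]:
    """Group-level behavioral analysis over per-subject trial tables.

    Analysis 1 contrasts selective vs. neutral retro-cues (paired t or
    Wilcoxon via the Lilliefors gate) on response time and accuracy,
    excluding non-cued-probe trials.  Analysis 2 tests probe type within the
    selective conditions: repeated-measures ANOVA on RT, Friedman on
    accuracy, with FDR-corrected post-hoc pairwise tests.  The two analyses
    form one FDR family per measure; adjusted p-values are uncapped.
    """
    if len(subject_tables) < 2:
        raise ValueError("need at least 2 subjects")
    cells = pd.DataFrame([_subject_cells(t) for t in subject_tables])

    results: dict[str, TestResult] = {}
    results["rt_cue_type"] = _gated_paired(
        cells["rt_selective"], cells["rt_neutral"], "rt_cue_type", family="rt"
    )
    results["acc_cue_type"] = _gated_paired(
        cells["acc_selective"], cells["acc_neutral"], "acc_cue_type", family="acc"
    )
    rt_mat = cells[["rt_cued", "rt_noncued", "rt_new"]].to_numpy()
    acc_mat = cells[["acc_cued", "acc_noncued", "acc_new"]].to_numpy()
    results["rt_probe_type"] = rm_anova_1way(rt_mat, "rt_probe_type", family="rt")
    results["acc_probe_type"] = friedman(acc_mat, "acc_probe_type", family="acc")

    for fam in ("rt", "acc"):
        keys = [k for k, r in results.items() if r.family == fam]
        adj = fdr_bh([results[k].p for k in keys])
        for k, a in zip(keys, adj):
            results[k].p_adj = float(a)

    # post-hoc pairwise probe-type contrasts, own FDR family per measure
    pairs = (("cued", "noncued"), ("cued", "new"), ("noncued", "new"))
    for measure, mat_cols in (("rt", ["rt_cued", "rt_noncued", "rt_new"]),
                              ("acc", ["acc_cued", "acc_noncued", "acc_new"])):
        keys = []
        for a_lbl, b_lbl in pairs:
            key = f"{measure}_posthoc_{a_lbl}_vs_{b_lbl}"
            results[key] = _gated_paired(
                cells[f"{measure}_{a_lbl}"], cells[f"{measure}_{b_lbl}"],
                key, family=f"{measure}_posthoc",
            )
            keys.append(key)
        adj = fdr_bh([results[k].p for k in keys])
        for k, a in zip(keys, adj):
            results[k].p_adj = float(a)
    return results


def ali_followup(window_means: pd.DataFrame) -> dict[str, TestResult]:
    """Follow-up window statistics on per-subject ALI window means.

    ``window_means`` has one row per subject and columns ``target_lateral``,
    ``distractor_lateral``, ``neutral``.  Runs the five post-hoc tests (two
    paired contrasts against neutral, three one-sample tests against zero)
    in a single FDR family, with Hedges g/g1 and JZS Bayes factors attached.
    """
    need = {"target_lateral", "distractor_lateral", "neutral"}
    if not need.issubset(window_means.columns):
        raise ValueError(f"window_means must have columns {sorted(need)}")
    if len(window_means) < 2:
        raise ValueError("need at least 2 subjects")
    wm = window_means
    results = {
        "neutral_vs_target_lateral": paired_t(
            wm["neutral"], wm["target_lateral"], "neutral_vs_target_lateral", family="ali"
        ),
        "neutral_vs_distractor_lateral": paired_t(
            wm["neutral"], wm["distractor_lateral"], "neutral_vs_distractor_lateral",
            family="ali",
        ),
    }
    for cond in ("target_lateral", "distractor_lateral", "neutral"):
        results[f"{cond}_vs_zero"] = one_sample_t(
            wm[cond], 0.0, f"{cond}_vs_zero", family="ali"
        )
    keys = list(results)
    adj = fdr_bh([results[k].p for k in keys])
    for k, a in zip(keys, adj):
        results[k].p_adj = float(a)
    return results
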