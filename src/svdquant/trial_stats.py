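"""Trial-level statistics: baseline tables, treatment effects, biomarkers.

Baseline comparisons follow the conventional rules for randomized-trial
"Table 1"s: two-sample t-tests for continuous traits, chi-squared tests
for binary traits (Fisher's exact test when any observed cell count is
below five), and median (quantile) regression for ordinal traits.

Treatment effects on imaging outcomes are ratio-scale: ordinary least
squares of log(follow-up) on an arm indicator and log(baseline), optionally
adjusted for age; the exponentiated arm coefficient is reported as an RR
with a Wald 95% CI.  Zeros are handled by adding half the smallest positive
observed value (recorded in the result) before taking logs.  Populations:
intention-to-treat (all randomized subjects with available data, missing
follow-up dropped pairwise) and per-protocol (treatment completers only).

The 92-protein panel is analysed per protein with Bonferroni correction
(0.05/m), and by PCA on the z-scored panel with per-component treatment
effects on the difference scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "baseline_comparison",
    "TreatmentEffect",
    "EffectEstimate",
    "treatment_effect",
    "biomarker_analysis",
    "pca_treatment",
    "PCAResult",
    "qalb",
    "qalb_validation",
    "power_n_per_arm",
    "pooled_mean",
    "adverse_event_summary",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# baseline comparisons

def _compare_binary(x_by_arm: list[np.ndarray]) -> tuple[float, float, str]:
    table = np.array([[np.sum(v), np.sum(~v)] for v in x_by_arm]).T  # 2 x n_arms
    if np.any(table < 5):
        stat, p = stats.fisher_exact(table)
        return float(stat), float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), "chi2"


def _compare_ordinal(values: np.ndarray, arm_ind: np.ndarray,
                     seed: int = 0) -> tuple[float, float, str]:
    """Median (tau=0.5) regression of the trait on the arm indicator."""
    import warnings

    X = sm.add_constant(arm_ind.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.QuantReg(values.astype(float), X).fit(q=0.5)
            return float(res.params[1]), float(res.pvalues[1]), "median-regression"
        except Exception:
            pass
    # bootstrap fallback on the median difference
    rng = np.random.default_rng(seed)
    a, b = values[arm_ind == 1], values[arm_ind == 0]
    obs = np.median(a) - np.median(b)
    pooled = np.concatenate([a, b])
    null = np.empty(1000)
    for i in range(1000):
        perm = rng.permutation(pooled)
        null[i] = np.median(perm[: a.size]) - np.median(perm[a.size:])
    p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
    return float(obs), p, "median-bootstrap"


def baseline_comparison(cohort: pd.DataFrame,
                        variables: dict[str, str] | None = None,
                        arm_col: str = "arm") -> pd.DataFrame:
    """Per-variable between-arm comparison with the test actually used.

    ``variables`` maps column name -> type in {"continuous", "binary",
    "ordinal"}; defaults cover the standard cohort columns.
    """
    arms = sorted(cohort[arm_col].unique())
    if len(arms) != 2:
        raise ValueError("exactly two arms required")
    if variables is None:
        variables = {
            "age_years": "continuous", "bmi": "continuous",
            "time_since_stroke_months": "continuous", "wmh_volume_cc": "continuous",
            "male": "binary", "white_british": "binary", "hypertension": "binary",
            "hyperlipidemia": "binary", "ihd": "binary", "diabetes": "binary",
            "smoker": "binary", "fazekas": "ordinal",
        }
    out = []
    arm_ind = (cohort[arm_col] == arms[0]).to_numpy().astype(int)
    for col, kind in variables.items():
        x = cohort[col].to_numpy()
        if np.all(x == x.flat[0]):
            out.append({"variable": col, "statistic": np.nan, "p": np.nan,
                        "test_used": "none-constant"})
            continue
        if kind == "continuous":
            g = [x[cohort[arm_col] == a].astype(float) for a in arms]
            stat, p = stats.ttest_ind(g[0], g[1], equal_var=True)
            name = "t-test"
        elif kind == "binary":
            g = [x[cohort[arm_col] == a].astype(bool) for a in arms]
            stat, p, name = _compare_binary(g)
        elif kind == "ordinal":
            stat, p, name = _compare_ordinal(x, arm_ind)
        else:
            raise ValueError(f"unknown variable type {kind!r}")
        out.append({"variable": col, "statistic": float(stat), "p": float(p),
                    "test_used": name})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# treatment effects

@dataclass(frozen=True)
class EffectEstimate:
    """Ratio-scale treatment effect with Wald 95% CI."""

    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted_for_age: bool
    population: str
    n_used: int
    epsilon: float = 0.0          # log-offset actually applied (0 = none)
    scale: str = "ratio"

    def summary(self) -> str:
        return (f"RR {self.rr:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f}), "
                f"p={self.p_value:.3g}, n={self.n_used}, "
                f"{'age-adjusted' if self.adjusted_for_age else 'unadjusted'}, "
                f"{self.population}")


class TreatmentEffect:
    """Log-outcome regression model for a pre/post imaging endpoint.

    Built from a long table with one row per subject carrying
    ``baseline_value``, ``followup_value``, ``arm``, ``age`` and
    ``completed_treatment``.
    """

    def __init__(self, outcomes: pd.DataFrame, active_arm: str = "minocycline"):
        self.outcomes = outcomes
        self.active_arm = active_arm

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "TreatmentEffect":
        return cls(df, **kw)

    def fit(self, adjust_age: bool = False, population: str = "ITT") -> EffectEstimate:
        df = self.outcomes
        if population == "per-protocol":
            df = df[df["completed_treatment"].astype(bool)]
        elif population != "ITT":
            raise ValueError("population must be 'ITT' or 'per-protocol'")
        df = df.dropna(subset=["baseline_value", "followup_value"])
        y0 = df["baseline_value"].to_numpy(dtype=float)
        y1 = df["followup_value"].to_numpy(dtype=float)
        eps = 0.0
        if np.any(y0 <= 0) or np.any(y1 <= 0):
            pos = np.concatenate([y0[y0 > 0], y1[y1 > 0]])
            if pos.size == 0:
                raise ValueError("no positive outcome values; ratio scale undefined")
            eps = 0.5 * pos.min()
        # values still non-positive after the zero offset (true negatives)
        # have no ratio-scale representation and drop pairwise
        ok = (y0 + eps > 0) & (y1 + eps > 0)
        df, y0, y1 = df[ok], y0[ok], y1[ok]
        arm_ind = (df["arm"] == self.active_arm).to_numpy().astype(float)
        for v in (0.0, 1.0):
            if np.sum(arm_ind == v) < 3:
                raise ValueError("need >= 3 subjects per arm with both timepoints")
        ly0, ly1 = np.log(y0 + eps), np.log(y1 + eps)

        cols = [arm_ind, ly0]
        names = ["arm", "log_baseline"]
        if adjust_age:
            cols.append(df["age_years"].to_numpy(dtype=float))
            names.append("age")
        X = sm.add_constant(np.column_stack(cols))
        res = sm.OLS(ly1, X).fit()
        beta, se = res.params[1], res.bse[1]
        return EffectEstimate(
            rr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959963984540054 * se)),
            ci_high=float(np.exp(beta + 1.959963984540054 * se)),
            p_value=float(res.pvalues[1]),
            adjusted_for_age=adjust_age,
            population=population,
            n_used=int(len(df)),
            epsilon=float(eps),
        )

    def fit_ratio_of_changes(self, population: str = "ITT") -> EffectEstimate:
        """Alternative estimator: ratio of geometric-mean follow-up/baseline
        ratios between arms, CI by t-interval on the log ratios."""
        df = self.outcomes
        if population == "per-protocol":
            df = df[df["completed_treatment"].astype(bool)]
        df = df.dropna(subset=["baseline_value", "followup_value"])
        y0, y1 = df["baseline_value"].to_numpy(float), df["followup_value"].to_numpy(float)
        eps = 0.0
        if np.any(y0 <= 0) or np.any(y1 <= 0):
            pos = np.concatenate([y0[y0 > 0], y1[y1 > 0]])
            eps = 0.5 * pos.min()
        lr = np.log(y1 + eps) - np.log(y0 + eps)
        act = (df["arm"] == self.active_arm).to_numpy()
        t = stats.ttest_ind(lr[act], lr[~act], equal_var=True)
        diff = lr[act].mean() - lr[~act].mean()
        se = diff / t.statistic if t.statistic != 0 else np.nan
        return EffectEstimate(
            rr=float(np.exp(diff)),
            ci_low=float(np.exp(diff - 1.959963984540054 * se)),
            ci_high=float(np.exp(diff + 1.959963984540054 * se)),
            p_value=float(t.pvalue), adjusted_for_age=False,
            population=population, n_used=int(len(df)), epsilon=float(eps),
            scale="ratio-of-changes",
        )


def treatment_effect(outcomes: pd.DataFrame, adjust_age: bool = False,
                     population: str = "ITT",
                     active_arm: str = "minocycline") -> EffectEstimate:
    """Functional wrapper around :class:`TreatmentEffect`."""
    return TreatmentEffect(outcomes, active_arm).fit(adjust_age, population)


# ---------------------------------------------------------------------------
# biomarker panel

def biomarker_analysis(baseline: pd.DataFrame, followup: pd.DataFrame,
                       cohort: pd.DataFrame, m: int | None = None,
                       protein_cols: list[str] | None = None,
                       active_arm: str = "minocycline") -> pd.DataFrame:
    """Per-protein treatment effects with Bonferroni significance flags."""
    if protein_cols is None:
        protein_cols = [c for c in baseline.columns
                        if c not in ("subject_id", "timepoint")]
    m = len(protein_cols) if m is None else m
    if m <= 0:
        raise ValueError("m must be positive")
    thresh = ALPHA / m
    rows = []
    for col in protein_cols:
        df = pd.DataFrame({
            "arm": cohort["arm"].to_numpy(),
            "age_years": cohort["age_years"].to_numpy(),
            "completed_treatment": cohort["completed_treatment"].to_numpy(),
            "baseline_value": baseline[col].to_numpy(),
            "followup_value": followup[col].to_numpy(),
        })
        est = TreatmentEffect(df, active_arm).fit()
        rows.append({"protein": col, "rr": est.rr, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "p": est.p_value,
                     "bonferroni_significant": est.p_value < thresh})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = thresh
    return out


@dataclass(frozen=True)
class PCAResult:
    """SVD-based PCA of the z-scored panel."""

    loadings: np.ndarray          # (m, k), orthonormal columns
    scores: np.ndarray            # (n, k)
    variance_share: np.ndarray    # (k,)


def pca_treatment(baseline: pd.DataFrame, followup: pd.DataFrame,
                  cohort: pd.DataFrame, k: int = 3,
                  protein_cols: list[str] | None = None,
                  active_arm: str = "minocycline"
                  ) -> tuple[PCAResult, pd.DataFrame]:
    """PCA of the baseline panel plus per-component treatment effects.

    Scores at both timepoints are projections onto the baseline loadings;
    per-component effects are difference-scale OLS of follow-up score on
    arm and baseline score.
    """
    if protein_cols is None:
        protein_cols = [c for c in baseline.columns
                        if c.startswith("P") and c != "timepoint"]
    X = baseline[protein_cols].to_numpy(dtype=float)
    n, m_p = X.shape
    if k > min(n, m_p):
        raise ValueError("k exceeds the rank of the panel")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # sign convention: largest-|loading| element positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var_share = S**2 / np.sum(S**2)
    loadings = Vt[:k].T
    scores0 = Z @ loadings
    Z1 = (followup[protein_cols].to_numpy(dtype=float) - mu) / sd
    scores1 = Z1 @ loadings

    arm_ind = (cohort["arm"] == active_arm).to_numpy().astype(float)
    age = cohort["age_years"].to_numpy(dtype=float)
    rows = []
    for j in range(k):
        X_reg = sm.add_constant(np.column_stack([arm_ind, scores0[:, j]]))
        res = sm.OLS(scores1[:, j], X_reg).fit()
        rows.append({"component": j + 1, "effect": float(res.params[1]),
                     "ci_low": float(res.params[1] - 1.96 * res.bse[1]),
                     "ci_high": float(res.params[1] + 1.96 * res.bse[1]),
                     "p": float(res.pvalues[1]), "scale": "difference",
                     "variance_share": float(var_share[j])})
    pca = PCAResult(loadings=loadings, scores=scores0,
                    variance_share=var_share[:k])
    return pca, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# albumin validation, power, table helpers

def qalb(csf_albumin_mg_L, serum_albumin_g_L):
    """CSF/serum albumin ratio in mg/g."""
    csf = np.asarray(csf_albumin_mg_L, dtype=float)
    serum = np.asarray(serum_albumin_g_L, dtype=float)
    if np.any(csf <= 0) or np.any(serum <= 0):
        raise ValueError("albumin values must be positive")
    return csf / serum


def qalb_validation(qalb_values, imaging_summary) -> dict:
    """Pearson correlation of Qalb with an imaging permeability summary."""
    q = np.asarray(qalb_values, dtype=float)
    x = np.asarray(imaging_summary, dtype=float)
    keep = np.isfinite(q) & np.isfinite(x)
    q, x = q[keep], x[keep]
    if q.size < 3:
        raise ValueError("need >= 3 paired records")
    if np.std(q) == 0 or np.std(x) == 0:
        raise ValueError("zero variance in one variable")
    r, p = stats.pearsonr(q, x)
    return {"pearson_r": float(r), "p": float(p), "n": int(q.size)}


def power_n_per_arm(effect_fraction: float, mean: float, sd: float,
                    alpha: float = 0.05, power: float = 0.80,
                    n_max: int = 10000) -> int:
    """Smallest per-arm n giving the target power for a two-sample t-test.

    The detectable difference is ``effect_fraction * mean``; power is
    evaluated exactly via the noncentral t distribution.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    delta = abs(effect_fraction * mean)
    if delta == 0:
        raise ValueError("null effect has no finite sample size")
    d = delta / sd
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        ncp = d * np.sqrt(n / 2.0)
        achieved = (1 - stats.nct.cdf(tcrit, df, ncp)
                    + stats.nct.cdf(-tcrit, df, ncp))
        if achieved >= power:
            return n
    raise RuntimeError("no n below n_max reaches the target power")


def pooled_mean(group_means, group_ns) -> float:
    """Sample-size-weighted mean across groups."""
    m = np.asarray(group_means, dtype=float)
    n = np.asarray(group_ns, dtype=float)
    if m.size == 0 or m.size != n.size:
        raise ValueError("means and ns must be non-empty and equal length")
    if np.any(n <= 0):
        raise ValueError("group sizes must be positive")
    return float(np.sum(m * n) / np.sum(n))


def adverse_event_summary(cohort: pd.DataFrame, arm_col: str = "arm",
                          event_col: str = "adverse_event") -> pd.DataFrame:
    """Per-arm adverse-event counts/percentages plus a comparison p-value."""
    arms = sorted(cohort[arm_col].unique())
    rows = []
    by_arm = []
    for arm in arms:
        ev = cohort.loc[cohort[arm_col] == arm, event_col].to_numpy().astype(bool)
        by_arm.append(ev)
        rows.append({"arm": arm, "n": ev.size, "events": int(ev.sum()),
                     "pct": round(100.0 * ev.sum() / ev.size, 1)})
    total_events = sum(int(v.sum()) for v in by_arm)
    if total_events == 0:
        p, test = np.nan, "skipped-no-events"
    else:
        _, p, test = _compare_binary(by_arm)
    out = pd.DataFrame(rows)
    out.attrs["p"] = p
    out.attrs["test_used"] = test
    return out
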