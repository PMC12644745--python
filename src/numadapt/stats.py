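"""Group-level inference over map examples.

Slopes and slope differences are tested per visual field map with two-sided
Wilcoxon signed-rank tests across map examples (hemispheres), with
Benjamini-Hochberg FDR correction over the family of maps.  The strength of
adaptation (proportional slope reduction) is compared between maps with a
two-factor ANOVA (visual field map + participant) followed by Tukey's HSD,
and cross-region relationships are quantified with Pearson correlations
whose residuals are screened for normality with an Anderson-Darling test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "signed_rank_test",
    "fdr_adjust",
    "per_map_signed_rank",
    "map_effect_anova",
    "region_correlations",
    "tuned_effect_summaries",
]


@dataclass
class TestResult:
    """One hypothesis test: statistic, two-sided p, optional adjusted p."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    p_adjusted: float | None = None
    labels: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "p_adjusted": self.p_adjusted,
        }
        d.update(self.labels)
        return d


EXACT_MAX_N = 25


def signed_rank_test(values, mu: float = 0.0, **labels) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of median ``mu``.

    Zeros are discarded (Wilcoxon's rule).  The exact null distribution is
    used for n <= 25 when there are no tied absolute values; otherwise the
    normal approximation with tie correction.  Degenerate input (all values
    equal to ``mu``) returns p = 1 with a warning.
    """
    import warnings

    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all differences zero; signed-rank p set to 1",
                      RuntimeWarning, stacklevel=2)
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, 0, labels=labels)
    if n < 5:
        warnings.warn(f"signed-rank test with n={n} < 5 has little power",
                      RuntimeWarning, stacklevel=2)
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= EXACT_MAX_N and not ties) else "approx"
    stat, p = scipy.stats.wilcoxon(d, method=method, correction=False)
    return TestResult("wilcoxon_signed_rank", float(stat), float(p), n,
                      labels=labels)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_map_signed_rank(
    examples: pd.DataFrame,
    value: str,
    mu: float = 0.0,
    by: str = "map_label",
) -> pd.DataFrame:
    """Signed-rank test of ``value`` per map, FDR-corrected across maps."""
    results = [
        signed_rank_test(grp[value].to_numpy(), mu=mu, **{by: label})
        for label, grp in examples.groupby(by, observed=True, sort=True)
    ]
    adj = fdr_adjust([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return pd.DataFrame([r.as_dict() for r in results])


def map_effect_anova(
    reductions: pd.DataFrame,
    value: str = "proportional_reduction",
    map_col: str = "map_label",
    participant_col: str = "participant",
) -> dict:
    """Two-factor ANOVA (map + participant) on proportional reductions.

    Visual field map is the effect of interest; participant enters as an
    additive blocking factor.  Unbalanced tables are allowed (type-II sums
    of squares).  Pairwise map differences are assessed with Tukey's HSD on
    participant-demeaned values, approximating comparisons of the map
    marginal means under the additive model.

    Returns a dict with F, df, p for the map effect, the full ANOVA table,
    and the Tukey pairwise table.
    """
    df = reductions[[value, map_col, participant_col]].dropna().copy()
    df.columns = ["y", "map", "participant"]
    if df["map"].nunique() < 2:
        raise ValueError("ANOVA needs at least two visual field maps")
    if df["participant"].nunique() < 2:
        raise ValueError("ANOVA needs at least two participants")
    model = smf.ols("y ~ C(map) + C(participant)", data=df).fit()
    table = anova_lm(model, typ=2)
    f = float(table.loc["C(map)", "F"])
    p = float(table.loc["C(map)", "PR(>F)"])
    ss_total = float(np.sum((df["y"] - df["y"].mean()) ** 2))
    if float(table.loc["C(map)", "sum_sq"]) <= 1e-12 * max(ss_total, 1.0):
        f, p = 0.0, 1.0  # no between-map variation at all (0/0 guard)
    df_map = int(table.loc["C(map)", "df"])
    df_resid = int(table.loc["Residual", "df"])

    # Tukey HSD on participant-demeaned values (additive blocking removed)
    demeaned = df["y"] - df.groupby("participant")["y"].transform("mean") + df["y"].mean()
    tukey = pairwise_tukeyhsd(endog=demeaned.to_numpy(), groups=df["map"].to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {
        "F": f,
        "df": (df_map, df_resid),
        "p": p,
        "anova_table": table,
        "tukey": tukey_df,
    }


def region_correlations(metric_a, metric_b, **labels) -> dict:
    """Pearson correlation between two per-hemisphere metrics.

    Pairs with a missing value in either metric are dropped.  Residuals of
    the b-on-a linear fit are screened with an Anderson-Darling normality
    test; ``normality_ok`` is False when that test rejects at 0.05.
    Degenerate input (fewer than 4 complete pairs, or zero variance) yields
    NaN correlation, reported as such.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    out = {"n": n, "r": float("nan"), "p": float("nan"),
           "ad_p": float("nan"), "normality_ok": None}
    out.update(labels)
    if n < 4 or np.std(a) == 0 or np.std(b) == 0:
        return out
    r, p = scipy.stats.pearsonr(a, b)
    slope, intercept = np.polyfit(a, b, 1)
    resid = b - (slope * a + intercept)
    ad_stat, ad_p = normal_ad(resid)
    out.update(r=float(r), p=float(p), ad_p=float(ad_p),
               normality_ok=bool(ad_p >= 0.05))
    return out


def tuned_effect_summaries(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-hemisphere summaries of adaptation effects on tuned responses.

    For the tuned-class voxels of each participant x hemisphere x map:

    * ``delta_r2`` — mean difference in tuned-model variance explained
      between the low and high adaptor conditions (consistently lower R^2
      under the high adaptor indicates stronger response suppression);
    * ``pref_change_slope`` — slope of the linear relationship between the
      per-voxel signed preference change (pref_low - pref_high, log units)
      and the voxel's preferred log numerosity in the changing-adaptor
      condition.

    These are the two tuned-response quantities correlated with the
    monotonic proportional slope reduction across hemispheres.
    """
    tuned = fits.loc[fits["model_class"] == "tuned"]
    need = {"low", "high", "changing"}
    rows = []
    for (part, hemi, map_label), grp in tuned.groupby(
        ["participant", "hemisphere", "map_label"], observed=True, sort=True
    ):
        wide_r2 = grp.pivot(index="voxel_id", columns="condition",
                            values="tuned_r2")
        wide_pref = grp.pivot(index="voxel_id", columns="condition",
                              values="pref_log")
        if not need.issubset(wide_r2.columns):
            continue
        complete = wide_r2[list(need)].notna().all(axis=1)
        wide_r2, wide_pref = wide_r2[complete], wide_pref[complete]
        if len(wide_r2) == 0:
            continue
        delta_r2 = float((wide_r2["low"] - wide_r2["high"]).mean())
        if len(wide_pref) >= 2 and wide_pref["changing"].std() > 0:
            slope = float(np.polyfit(
                wide_pref["changing"], wide_pref["low"] - wide_pref["high"], 1
            )[0])
        else:
            slope = float("nan")
        rows.append({
            "participant": part,
            "hemisphere": hemi,
            "map_label": map_label,
            "n_voxels": int(len(wide_r2)),
            "delta_r2": delta_r2,
            "pref_change_slope": slope,
        })
    return pd.DataFrame(rows)
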