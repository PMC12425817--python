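"""SBS-based TNBC subtyping and downstream group/survival statistics.

The classifier combines the clock-like (aging) activity SBS1 + SBS5 with
the HRD-related activity SBS3.  Each activity is cut into cohort tertiles,
collapsed to low (T1/T2) versus high (T3), and the two binary levels
define four subtypes:

=========  ======  ====
subtype    aging   HRD
=========  ======  ====
1          low     high
2          low     low
3          high    low
4          high    high
=========  ======  ====

Downstream statistics are the ones used throughout this kind of cohort
analysis: two-sided Wilcoxon rank-sum comparisons between subtypes,
logistic regression for age/BMI odds, Kaplan-Meier curves with log-rank
tests, and Cox proportional-hazards models with Efron tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
import statsmodels.api as sm

SUBTYPE_MAP = {
    ("low", "high"): 1,
    ("low", "low"): 2,
    ("high", "low"): 3,
    ("high", "high"): 4,
}


@dataclass
class SubtypeAssignment:
    sample_id: str
    aging_activity: float
    hrd_activity: float
    aging_tertile: str
    hrd_tertile: str
    aging_level: str
    hrd_level: str
    subtype: int


def _tertiles(values: pd.Series) -> pd.Series:
    """T1/T2/T3 labels at the 33.33/66.67 empirical percentiles.

    Values exactly equal to a cut point go to the lower tertile.
    """
    q1, q2 = np.percentile(values, [100 / 3, 200 / 3])
    if q1 == q2:
        raise ValueError(
            "degenerate tertiles: more than a third of the cohort is tied; "
            "consider switching exposure mode or jittering upstream"
        )
    labels = pd.Series("T3", index=values.index)
    labels[values <= q2] = "T2"
    labels[values <= q1] = "T1"
    return labels


def assign_sbs_subtype(exposures: pd.DataFrame, mode: str = "counts") -> pd.DataFrame:
    """Assign the four SBS subtypes from signature exposures.

    ``exposures`` must contain SBS1, SBS5 and SBS3 columns in mutation-
    count units; ``mode='proportions'`` first normalizes each sample's
    exposures to sum to one.  Tertile cut points are computed on this
    cohort, so assignments are relative to the analyzed samples.
    """
    required = {"SBS1", "SBS5", "SBS3"}
    if not required.issubset(exposures.columns):
        raise ValueError(f"exposures must contain columns {sorted(required)}")
    if len(exposures) < 3:
        raise ValueError("need at least 3 samples to form tertiles")
    expo = exposures.copy()
    if mode == "proportions":
        totals = expo.sum(axis=1).replace(0, np.nan)
        expo = expo.div(totals, axis=0).fillna(0.0)
    elif mode != "counts":
        raise ValueError("mode must be 'counts' or 'proportions'")
    aging = expo["SBS1"] + expo["SBS5"]
    hrd = expo["SBS3"]
    aging_t = _tertiles(aging)
    hrd_t = _tertiles(hrd)
    aging_level = aging_t.map(lambda t: "high" if t == "T3" else "low")
    hrd_level = hrd_t.map(lambda t: "high" if t == "T3" else "low")
    subtype = [
        SUBTYPE_MAP[(a, h)] for a, h in zip(aging_level, hrd_level)
    ]
    return pd.DataFrame(
        {
            "sample_id": exposures.index,
            "aging_activity": aging.to_numpy(),
            "hrd_activity": hrd.to_numpy(),
            "aging_tertile": aging_t.to_numpy(),
            "hrd_tertile": hrd_t.to_numpy(),
            "aging_level": aging_level.to_numpy(),
            "hrd_level": hrd_level.to_numpy(),
            "subtype": subtype,
        }
    ).set_index("sample_id")


def compare_features(group_a, group_b, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p between two feature vectors.

    Exact enumeration for combined n <= ``exact_max_n`` without ties,
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def subtype_odds(
    clinical: pd.DataFrame,
    outcome_subtype: int = 1,
    reference_subtype: int = 3,
    age_increment: float = 10.0,
    bmi_increment: float = 5.0,
    covariates: tuple = ("age", "bmi"),
) -> pd.DataFrame:
    """Logistic odds of one subtype versus another per covariate increment.

    ``clinical`` needs columns ``subtype``, ``age`` and ``bmi``.  Returns
    odds ratios (with Wald 95% CI and p) scaled to the requested
    increments, e.g. per +10 years of age and per +5 kg/m2 of BMI.  On
    complete separation the model is refit with a light L2 penalty and
    flagged.
    """
    sub = clinical[clinical["subtype"].isin([outcome_subtype, reference_subtype])]
    if sub["subtype"].nunique() < 2:
        raise ValueError("both subtype groups must be non-empty")
    y = (sub["subtype"] == outcome_subtype).astype(float)
    X = sm.add_constant(sub[list(covariates)].astype(float))
    flagged = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        if not np.isfinite(fit.bse).all() or (fit.bse[1:] > 1e3).any():
            raise ValueError("unstable fit")
    except Exception:
        flagged = True
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=0.1, L1_wt=0.0
        )
    params = np.asarray(fit.params, dtype=float)
    try:
        bse = np.asarray(fit.bse, dtype=float)
        pvals = np.asarray(fit.pvalues, dtype=float)
    except Exception:
        bse = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
    increments = {"age": age_increment, "bmi": bmi_increment}
    rows = []
    for name in covariates:
        increment = increments.get(name, 1.0)
        i = list(X.columns).index(name)
        beta = params[i] * increment
        se = bse[i] * increment
        rows.append(
            {
                "covariate": name,
                "increment": increment,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.96 * se)),
                "ci_high": float(np.exp(beta + 1.96 * se)),
                "p": float(pvals[i]),
                "penalized": flagged,
            }
        )
    return pd.DataFrame(rows)


def km_logrank(records: pd.DataFrame, group_col: str = "group") -> dict:
    """Kaplan-Meier curves per group plus the log-rank test across groups.

    ``records`` needs columns ``time`` (months), ``event`` (0/1) and the
    grouping column.  With no events the log-rank p is undefined (None).
    """
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    curves = {}
    for name, sub in records.groupby(group_col):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(name))
        curves[name] = kmf
    if records["event"].sum() == 0 or records[group_col].nunique() < 2:
        return {"curves": curves, "statistic": None, "p": None}
    res = multivariate_logrank_test(
        records["time"], records[group_col], records["event"]
    )
    return {"curves": curves, "statistic": float(res.test_statistic), "p": float(res.p_value)}


def cox_hr(
    records: pd.DataFrame,
    group_col: str = "group",
    covariates: list[str] | None = None,
) -> dict:
    """Cox proportional-hazards HR for ``group_col`` (Efron tie handling).

    ``records`` needs ``time``, ``event``, a binary/numeric group column
    and optional covariate columns (categorical covariates are dummy-
    coded).  Returns the group HR with Wald 95% CI and p, plus the
    fitted model.
    """
    covariates = covariates or []
    cols = ["time", "event", group_col] + covariates
    df = records[cols].copy()
    cat_cols = [c for c in covariates if df[c].dtype == object or df[c].dtype.name == "category"]
    if cat_cols:
        df = pd.get_dummies(df, columns=cat_cols, drop_first=True, dtype=float)
    n_params = df.shape[1] - 2
    if df["event"].sum() < n_params:
        raise ValueError("fewer events than model parameters")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event", show_progress=False)
    hr = float(np.exp(cph.params_[group_col]))
    ci = cph.confidence_intervals_.loc[group_col]
    return {
        "hr": hr,
        "ci_low": float(np.exp(ci.iloc[0])),
        "ci_high": float(np.exp(ci.iloc[1])),
        "p": float(cph.summary.loc[group_col, "p"]),
        "model": cph,
    }
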