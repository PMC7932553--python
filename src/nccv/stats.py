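"""Group statistics on per-subject nCCV and clinical covariates.

Covers the analysis layer applied to pipeline outputs: per-slice
patient/control comparison with Sidak familywise control, Welch t-test on
nCCV, ROC discrimination with bootstrap CI, Pearson/Spearman correlation,
regression associations of standardized nCCV with clinical outcomes,
repeat-acquisition coefficient of variation, and two clinical unit
helpers (leukocyte-to-granulocyte cystine conversion, bedside Schwartz
eGFR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .quantify import AreaProfile

#: Leukocyte -> granulocyte cystine conversion factor.
GRANULOCYTE_FACTOR = 1.95
#: Bedside Schwartz constant (mL/min/1.73 m^2 per cm/(mg/dL)).
SCHWARTZ_K = 0.413


# --------------------------------------------------------------------------
# subject records
# --------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One subject's nCCV plus clinical covariates (optional fields None)."""

    subject_id: str
    group: str  # "patient" | "control"
    nccv_um3: float
    age_years: Optional[float] = None
    sex: Optional[str] = None
    ckd_stage: Optional[int] = None
    hypothyroidism: Optional[bool] = None
    fanconi: Optional[bool] = None
    polydipsia: Optional[bool] = None
    bmi: Optional[float] = None
    serum_sodium_mmol_l: Optional[float] = None
    platelet_count: Optional[float] = None
    egfr_ml_min: Optional[float] = None
    leukocyte_cystine: Optional[float] = None
    cysteamine_dose_mg: Optional[float] = None
    kidney_transplant: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.nccv_um3 < 0:
            raise ValueError("nccv_um3 must be >= 0")
        if self.ckd_stage is not None and self.ckd_stage not in range(5):
            raise ValueError("ckd_stage must be in 0..4")


def records_to_dataframe(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# --------------------------------------------------------------------------
# per-slice group comparison
# --------------------------------------------------------------------------

def sidak_level(alpha: float, m: int) -> float:
    """Sidak-adjusted per-comparison level: ``1 - (1 - alpha)^(1/m)``."""
    if not 0 < alpha < 1 or m < 1:
        raise ValueError("need 0 < alpha < 1 and m >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def per_slice_comparison(
    profiles_patients: Sequence[AreaProfile],
    profiles_controls: Sequence[AreaProfile],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Patient/control mean comparison of normalized crystal area per slice.

    Runs a two-sample Welch test at every slice and flags slices whose
    p-value falls below the Sidak-adjusted level ``1 - (1-alpha)^(1/m)``,
    controlling the familywise error over the ``m`` slices.

    Returns a DataFrame with columns ``slice_index, mean_patients,
    mean_controls, mean_difference, p_value, significant``.
    """
    if len(profiles_patients) < 2 or len(profiles_controls) < 2:
        raise ValueError("need at least 2 profiles per group")
    m = len(profiles_patients[0])
    for p in list(profiles_patients) + list(profiles_controls):
        if len(p) != m:
            raise ValueError("all profiles must share the same slice count")
    pat = np.vstack([p.normalized for p in profiles_patients])
    ctl = np.vstack([p.normalized for p in profiles_controls])
    level = sidak_level(alpha, m)
    rows = []
    for j in range(m):
        a, b = pat[:, j], ctl[:, j]
        diff = a.mean() - b.mean()
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            p_val = 1.0 if diff == 0 else 0.0
        else:
            p_val = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "slice_index": j + 1,
                "mean_patients": a.mean(),
                "mean_controls": b.mean(),
                "mean_difference": diff,
                "p_value": p_val,
                "significant": p_val < level,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["sidak_level"] = level
    return out


# --------------------------------------------------------------------------
# group comparison and discrimination
# --------------------------------------------------------------------------

def group_t_test(x_patients, x_controls, equal_var: bool = False) -> dict:
    """Two-sided t-test between groups (Welch by default).

    The Welch form is the default because patient and control nCCV
    spreads differ severalfold, where pooled variance is inappropriate.
    Returns t, df, p plus per-group descriptives.
    """
    a = np.asarray(x_patients, dtype=float)
    b = np.asarray(x_controls, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    out = {
        "mean_patients": float(a.mean()),
        "mean_controls": float(b.mean()),
        "sd_patients": float(a.std(ddof=1)),
        "sd_controls": float(b.std(ddof=1)),
        "n_patients": int(a.size),
        "n_controls": int(b.size),
    }
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: no within-group variability
        equal_means = a.mean() == b.mean()
        out.update(t=0.0 if equal_means else np.inf, df=float(a.size + b.size - 2),
                   p=1.0 if equal_means else 0.0, degenerate=True)
        return out
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    out.update(t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
               degenerate=False)
    return out


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic over n1*n0, ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """ROC AUC of a score for a binary label, with bootstrap CI.

    AUC is computed as the Mann-Whitney U statistic divided by ``n1*n0``
    (tied pairs count 1/2); the CI is a seeded stratified bootstrap
    percentile interval (classes resampled separately).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    auc = auc_mann_whitney(s, y)
    pos, neg = s[y], s[~y]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        boots[i] = auc_mann_whitney(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(bp.size, bool), np.zeros(bn.size, bool)]),
        )
    lo, hi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return {"auc": auc, "ci_low": float(lo), "ci_high": float(hi), "n_boot": n_boot}


# --------------------------------------------------------------------------
# regression associations
# --------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Effect of a 1-SD increase in nCCV on one clinical outcome."""

    outcome: str
    kind: str  # "binary" | "continuous"
    effect: float  # odds ratio (binary) or slope (continuous) per 1 SD nCCV
    ci_low: float
    ci_high: float
    wald_chi_square: float
    p_value: float
    covariates: List[str] = field(default_factory=list)
    n: int = 0
    separation_flag: bool = False

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "kind": self.kind,
            "effect": self.effect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "wald_chi_square": self.wald_chi_square,
            "p_value": self.p_value,
            "covariates": "+".join(self.covariates) if self.covariates else "",
            "n": self.n,
            "separation": self.separation_flag,
        }


#: Pre-specified clinical models: outcome -> (kind, covariates, restriction).
#: CKD stage is modeled linear-in-stage (continuous) adjusted for age and
#: eGFR among transplant-free subjects; hypothyroidism adjusted for sex
#: among subjects aged >= 9.
CLINICAL_MODELS = {
    "ckd_stage": (
        "continuous",
        ["age_years", "egfr_ml_min"],
        lambda df: df["kidney_transplant"] != True,  # noqa: E712
    ),
    "hypothyroidism": ("binary", ["sex"], lambda df: df["age_years"] >= 9),
    "fanconi": ("binary", [], None),
    "polydipsia": ("binary", [], None),
    "bmi": ("continuous", ["age_years", "sex"], None),
    "serum_sodium_mmol_l": ("continuous", ["age_years"], None),
    "platelet_count": ("continuous", [], None),
}


def _design_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["nccv_z"] = df["nccv_z"]
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category":
            codes, _ = pd.factorize(col)
            X[cov] = codes
        else:
            X[cov] = pd.to_numeric(col)
    return sm.add_constant(X, has_constant="add")


def association(
    records,
    outcome: str,
    kind: str,
    covariates: Sequence[str] = (),
    restrict: Optional[Callable[[pd.DataFrame], pd.Series]] = None,
) -> AssociationResult:
    """Association between standardized nCCV and one clinical outcome.

    Fits a maximum-likelihood logistic model (binary outcome) or OLS
    (continuous outcome) with z-scored nCCV as the main predictor plus
    ``covariates``.  The effect is reported per 1 SD of nCCV: an odds
    ratio with Wald 95% CI for binary outcomes, a slope for continuous
    ones.  Rows failing ``restrict`` or missing the outcome/covariates are
    dropped listwise; nCCV is standardized within the analyzed subset.
    Complete separation is flagged, not raised.
    """
    if kind not in ("binary", "continuous"):
        raise ValueError("kind must be 'binary' or 'continuous'")
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    if outcome not in df.columns:
        raise KeyError(f"unknown outcome field {outcome!r}")
    if restrict is not None:
        df = df[restrict(df).fillna(False)]
    cols = [outcome, "nccv_um3", *covariates]
    df = df.dropna(subset=cols)
    n = len(df)
    if n < 10:
        raise ValueError(f"only {n} usable records for {outcome}; need >= 10")
    df = df.copy()
    sd = df["nccv_um3"].std(ddof=1)
    if sd == 0:
        raise ValueError("nCCV has zero variance in the analyzed subset")
    df["nccv_z"] = (df["nccv_um3"] - df["nccv_um3"].mean()) / sd
    X = _design_matrix(df, covariates)

    separation = False
    if kind == "binary":
        y = df[outcome].astype(float)
        if y.nunique() < 2:
            return AssociationResult(
                outcome=outcome, kind=kind, effect=np.nan, ci_low=np.nan,
                ci_high=np.nan, wald_chi_square=np.nan, p_value=np.nan,
                covariates=list(covariates), n=n, separation_flag=True,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            except (np.linalg.LinAlgError, PerfectSeparationError):
                fit = None
        # (quasi-)separation shows up as a failed fit or an exploding SE
        if fit is None or not np.isfinite(fit.bse["nccv_z"]) or fit.bse["nccv_z"] > 50:
            beta = np.nan if fit is None else float(fit.params["nccv_z"])
            return AssociationResult(
                outcome=outcome, kind=kind,
                effect=float(np.exp(beta)) if np.isfinite(beta) else np.nan,
                ci_low=np.nan, ci_high=np.nan, wald_chi_square=np.nan,
                p_value=np.nan, covariates=list(covariates), n=n,
                separation_flag=True,
            )
        beta = float(fit.params["nccv_z"])
        se = float(fit.bse["nccv_z"])
        effect = float(np.exp(beta))
        lo, hi = np.exp(beta - 1.959964 * se), np.exp(beta + 1.959964 * se)
    else:
        y = pd.to_numeric(df[outcome])
        fit = sm.OLS(y, X).fit()
        beta = float(fit.params["nccv_z"])
        se = float(fit.bse["nccv_z"])
        effect = beta
        lo, hi = beta - 1.959964 * se, beta + 1.959964 * se
    wald = (beta / se) ** 2
    p = float(sps.chi2.sf(wald, df=1))
    return AssociationResult(
        outcome=outcome, kind=kind, effect=effect, ci_low=float(lo),
        ci_high=float(hi), wald_chi_square=float(wald), p_value=p,
        covariates=list(covariates), n=n, separation_flag=separation,
    )


# --------------------------------------------------------------------------
# correlation, repeatability, clinical conversions
# --------------------------------------------------------------------------

def correlation(x, y, method: str = "pearson") -> dict:
    """Pearson product-moment or Spearman rank correlation with 2-sided p."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(a, b)
    elif method == "spearman":
        r, p = sps.spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return {"r": float(r), "p": float(p), "method": method, "n": int(a.size)}


def repeatability_cv(repeats) -> float:
    """Coefficient of variation (%) of repeat acquisitions: 100 * SD / mean.

    Sample SD (n-1 denominator); the mean must be positive.
    """
    v = np.asarray(repeats, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 repeat measurements")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def granulocyte_from_leukocyte(leukocyte_level: float) -> float:
    """Granulocyte cystine level from a leukocyte cystine level.

    Granulocyte levels are ``1.95 x`` the leukocyte level (both in
    nmol/mg protein 1/2 cystine).
    """
    if leukocyte_level < 0:
        raise ValueError("cystine level must be >= 0")
    return GRANULOCYTE_FACTOR * leukocyte_level


def egfr_schwartz(height_cm: float, serum_creatinine_mg_dl: float) -> float:
    """Bedside Schwartz eGFR (mL/min/1.73 m^2): ``0.413 * height / creatinine``."""
    if height_cm <= 0 or serum_creatinine_mg_dl <= 0:
        raise ValueError("height and creatinine must be > 0")
    return SCHWARTZ_K * height_cm / serum_creatinine_mg_dl
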