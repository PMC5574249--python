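"""Evaluation of a dichotomous biomarker in a two-arm neoadjuvant trial.

Given a per-patient table (arm, biomarker class, hormone-receptor status,
tumor-size category, binary pCR outcome) the module computes:

* per-arm biomarker-response 2x2 tables, sample odds ratios
  (Haldane-Anscombe corrected when a cell is zero) and two-sided Fisher
  exact p-values;
* the biomarker x treatment interaction via a likelihood-ratio test on
  nested logistic models, optionally adjusted for HR status and tumor size
  (complete-case when tumor size is in the model);
* baseline-characteristics chi-squared tests by biomarker class
  (continuity-corrected for 2x2 tables);
* confusion-matrix metrics for the discovery-set signature-vs-copy-number
  comparison;
* the treatment odds ratio within the combined subset
  TN u (HR+ n biomarker-positive) and its prevalence gain over TN alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .matrix import ValidationError

__all__ = [
    "ConfusionMatrix",
    "confusion_metrics",
    "validate_trial_table",
    "arm_association",
    "interaction_test",
    "characteristics_table",
    "combined_subset_or",
    "evaluate_trial",
]

ARMS = ("control", "experimental")
BIOMARKER = ("negative", "positive")
HR_LEVELS = ("HR+", "TN")
SIZE_LEVELS = ("0-1", ">1-2", ">2-5", ">5")


@dataclass
class ConfusionMatrix:
    """Reference = copy-number label, prediction = signature call."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as fractions."""
    if cm.tp + cm.fn == 0 or cm.fp + cm.tn == 0:
        raise ValidationError("confusion matrix has an empty reference margin")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    return sens, spec, acc


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-patient table; arm/biomarker/pcr must be complete,
    tumor_size_cat may be missing."""
    required = {"arm", "biomarker", "hr_status", "pcr"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"trial table missing columns: {sorted(missing)}")
    for col in ("arm", "biomarker", "pcr"):
        if table[col].isna().any():
            raise ValidationError(f"column {col!r} has missing values")
    if not set(table["arm"].unique()) <= set(ARMS):
        raise ValidationError(f"arm must be one of {ARMS}")
    if not set(table["biomarker"].unique()) <= set(BIOMARKER):
        raise ValidationError(f"biomarker must be one of {BIOMARKER}")
    if not set(table["pcr"].unique()) <= {0, 1}:
        raise ValidationError("pcr must be binary 0/1")
    return table


def _two_by_two(sub: pd.DataFrame) -> np.ndarray:
    """Rows: biomarker positive, negative; columns: pCR, no pCR."""
    a = ((sub.biomarker == "positive") & (sub.pcr == 1)).sum()
    b = ((sub.biomarker == "positive") & (sub.pcr == 0)).sum()
    c = ((sub.biomarker == "negative") & (sub.pcr == 1)).sum()
    d = ((sub.biomarker == "negative") & (sub.pcr == 0)).sum()
    return np.array([[a, b], [c, d]], dtype=float)


def _cross_product_or(t: np.ndarray) -> float:
    """Sample odds ratio with Haldane-Anscombe +0.5 applied iff any cell is 0."""
    if (t == 0).any():
        t = t + 0.5
    return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))


def arm_association(table: pd.DataFrame, arm: str) -> tuple[float, float, np.ndarray]:
    """Biomarker-response association within one arm.

    Returns (odds ratio, two-sided Fisher exact p, 2x2 counts). The odds
    ratio compares the odds of pCR in biomarker-positive versus
    biomarker-negative patients.
    """
    validate_trial_table(table)
    sub = table[table.arm == arm]
    if len(sub) == 0:
        raise ValidationError(f"arm {arm!r} absent from trial table")
    t = _two_by_two(sub)
    orr = _cross_product_or(t)
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return orr, float(p), t


def _design(table: pd.DataFrame, covariates: tuple[str, ...], interaction: bool) -> tuple[pd.DataFrame, pd.Series]:
    df = table
    if "tumor_size_cat" in covariates:
        df = df[df.tumor_size_cat.notna()]
    y = df.pcr.astype(float)
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["arm"] = (df.arm == "experimental").astype(float)
    X["biomarker"] = (df.biomarker == "positive").astype(float)
    if interaction:
        X["arm_x_biomarker"] = X["arm"] * X["biomarker"]
    if "hr_status" in covariates:
        X["hr_tn"] = (df.hr_status == "TN").astype(float)
    if "tumor_size_cat" in covariates:
        present = [lev for lev in SIZE_LEVELS if (df.tumor_size_cat == lev).any()]
        for lev in present[1:]:  # first present level is the reference
            X[f"size_{lev}"] = (df.tumor_size_cat == lev).astype(float)
    return X, y


def _fit_logit(y: pd.Series, X: pd.DataFrame):
    """Newton ML fit with a BFGS fallback for near-degenerate tables (a zero
    cell sends the saturated interaction coefficient toward infinity; BFGS
    still reaches the limiting log-likelihood)."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10, maxiter=100)
            if res.mle_retvals.get("converged", True) and np.isfinite(res.llf):
                return res
        except Exception:
            pass
        res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500, gtol=1e-8)
        if not np.isfinite(res.llf):
            raise ValidationError("log-likelihood did not converge")
        return res


def interaction_test(
    table: pd.DataFrame, covariates: tuple[str, ...] = ()
) -> tuple[float, float, pd.Series]:
    """Likelihood-ratio test of the biomarker x treatment interaction.

    Fits logistic regressions pcr ~ arm + biomarker (+ covariates) with and
    without the arm:biomarker term; LR = 2(loglik_full - loglik_reduced),
    p from chi-squared with 1 df. Patients with missing tumor size are
    dropped only when that covariate is included.
    """
    validate_trial_table(table)
    bad = set(covariates) - {"hr_status", "tumor_size_cat"}
    if bad:
        raise ValidationError(f"unknown covariates: {sorted(bad)}")
    if table.pcr.sum() == 0 or (1 - table.pcr).sum() == 0:
        raise ValidationError("outcome has no events or no non-events")
    X_full, y = _design(table, tuple(covariates), interaction=True)
    X_red, _ = _design(table, tuple(covariates), interaction=False)

    rank = np.linalg.matrix_rank(X_full.to_numpy())
    if rank < X_full.shape[1]:
        raise ValidationError("design matrix is rank deficient (aliased columns)")
    try:
        full = _fit_logit(y, X_full)
        red = _fit_logit(y, X_red)
    except Exception as exc:  # perfect separation or non-convergence
        raise ValidationError(
            "logistic fit failed (possible separation); consider the "
            f"corrected odds-ratio path: {exc}"
        ) from exc
    lr = 2.0 * (full.llf - red.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return float(lr), p, full.params


def characteristics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics tests of each variable against biomarker class.

    2x2 tables use the continuity-corrected chi-squared statistic; r x 2
    tables use the uncorrected Pearson statistic after dropping all-zero
    rows. Variables with a single observed level get p = NaN.
    """
    validate_trial_table(table)
    rows = []
    for var in ("arm", "hr_status", "tumor_size_cat"):
        sub = table[[var, "biomarker"]].dropna()
        ct = pd.crosstab(sub[var], sub["biomarker"])
        ct = ct.loc[(ct.sum(axis=1) > 0)]
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            rows.append((var, np.nan, np.nan, np.nan))
            continue
        correction = ct.shape == (2, 2)
        res = stats.chi2_contingency(ct.to_numpy(), correction=correction)
        rows.append((var, float(res.statistic), int(res.dof), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["variable", "statistic", "df", "p"]).set_index("variable")


def combined_subset_or(table: pd.DataFrame) -> tuple[float, float]:
    """Treatment odds ratio within TN u (HR+ n biomarker-positive).

    Returns (odds ratio of pCR for experimental vs control within the
    subset, gain in rule-positive prevalence over the TN-only rule, as a
    fraction of all patients).
    """
    validate_trial_table(table)
    rule = (table.hr_status == "TN") | (
        (table.hr_status == "HR+") & (table.biomarker == "positive")
    )
    sub = table[rule]
    for arm in ARMS:
        if (sub.arm == arm).sum() == 0:
            raise ValidationError(f"combined subset is empty in arm {arm!r}")
    t = np.array(
        [
            [((sub.arm == "experimental") & (sub.pcr == 1)).sum(),
             ((sub.arm == "experimental") & (sub.pcr == 0)).sum()],
            [((sub.arm == "control") & (sub.pcr == 1)).sum(),
             ((sub.arm == "control") & (sub.pcr == 0)).sum()],
        ],
        dtype=float,
    )
    orr = _cross_product_or(t)
    gain = (rule.sum() - (table.hr_status == "TN").sum()) / len(table)
    return orr, float(gain)


def tn_subset_or(table: pd.DataFrame) -> float:
    """Treatment odds ratio within the TN-only subset."""
    sub = table[table.hr_status == "TN"]
    t = np.array(
        [
            [((sub.arm == "experimental") & (sub.pcr == 1)).sum(),
             ((sub.arm == "experimental") & (sub.pcr == 0)).sum()],
            [((sub.arm == "control") & (sub.pcr == 1)).sum(),
             ((sub.arm == "control") & (sub.pcr == 0)).sum()],
        ],
        dtype=float,
    )
    return _cross_product_or(t)


def evaluate_trial(table: pd.DataFrame) -> dict:
    """Full evaluation report: per-arm tests, interaction tests (unadjusted,
    HR-adjusted, HR+size-adjusted), and the baseline-characteristics table."""
    validate_trial_table(table)
    report: dict = {"arms": {}}
    for arm in ARMS:
        orr, p, counts = arm_association(table, arm)
        report["arms"][arm] = {
            "odds_ratio": orr,
            "fisher_p": p,
            "counts": counts.astype(int).tolist(),
        }
    report["interaction"] = {}
    for name, covs in (
        ("unadjusted", ()),
        ("hr_adjusted", ("hr_status",)),
        ("hr_size_adjusted", ("hr_status", "tumor_size_cat")),
    ):
        try:
            lr, p, params = interaction_test(table, covs)
            report["interaction"][name] = {
                "lr_stat": lr,
                "p": p,
                "coefficients": {k: float(v) for k, v in params.items()},
            }
        except ValidationError as exc:
            report["interaction"][name] = {"error": str(exc)}
    chars = characteristics_table(table)
    report["characteristics"] = {
        var: {
            "statistic": None if np.isnan(row.statistic) else row.statistic,
            "df": None if np.isnan(row.df) else int(row.df),
            "p": None if np.isnan(row.p) else row.p,
        }
        for var, row in chars.iterrows()
    }
    return report
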