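"""Clinical statistics for attenuation-based hepatic steatosis grading.

Implements the validation machinery used around attenuation measurements:
steatosis grading from MRI-PDFF or from a modality cutoff triple,
Spearman/Pearson correlation with ordinary-least-squares regression,
ROC analysis with Youden-optimal operating points, intraclass correlation
(two-way random effects, absolute agreement, single and mean rating), and a
Gaussian-copula synthetic cohort generator for end-to-end testing when no
patient data is available.

Reference cutoffs: PDFF 5 / 16.3 / 21.6 % for steatosis grades >=1, >=2 and
3; QUS attenuation 0.36 / 0.46 / 0.53 dB/cm/MHz for the same grades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
import statsmodels.api as sm

from .errors import ConfigurationError, DegenerateInputError, InputError

__all__ = [
    "GradeCutoffs",
    "RatingTable",
    "PDFF_CUTOFFS",
    "QUS_AC_CUTOFFS",
    "grade_from_pdff",
    "grade_from_measure",
    "icc_two_way_random",
    "roc_analysis",
    "correlation_regression",
    "synth_cohort",
    "COHORT_MARGINALS",
]


@dataclass
class GradeCutoffs:
    """Ordered thresholds for steatosis grades >=1, >=2 and 3 (inclusive)."""

    modality: str
    thresholds: tuple[float, float, float]

    def __post_init__(self):
        t = self.thresholds
        if not (t[0] <= t[1] <= t[2]):
            raise ConfigurationError(f"cutoffs must be nondecreasing, got {t}")


PDFF_CUTOFFS = GradeCutoffs("MRI-PDFF", (5.0, 16.3, 21.6))  # percent
QUS_AC_CUTOFFS = GradeCutoffs("QUS-AC", (0.36, 0.46, 0.53))  # dB/cm/MHz
ATI_CUTOFFS = GradeCutoffs("ATI", (0.63, 0.71, 0.81))  # dB/cm/MHz
UAP_CUTOFFS = GradeCutoffs("UAP", (222.0, 280.0, 281.0))  # dB/m


@dataclass
class RatingTable:
    """Subjects x raters measurements (complete cases only)."""

    values: np.ndarray
    subject_ids: list = field(default_factory=list)
    rater_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise InputError("rating table needs >=2 subjects and >=2 raters")
        if not np.all(np.isfinite(self.values)):
            raise InputError("rating table has missing/non-finite cells; "
                             "apply listwise deletion upstream")
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(self.values.shape[0])]
        if not self.rater_ids:
            self.rater_ids = [f"r{j}" for j in range(self.values.shape[1])]

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        df = pd.read_csv(path)
        id_col = df.columns[0]
        df = df.dropna()
        return cls(df.iloc[:, 1:].to_numpy(dtype=float),
                   subject_ids=list(df[id_col]),
                   rater_ids=list(df.columns[1:]))


def grade_from_measure(value: float, cutoffs: GradeCutoffs) -> int:
    """Steatosis grade 0-3: the number of (inclusive) thresholds reached."""
    return int(np.count_nonzero(np.asarray(cutoffs.thresholds) <= value))


def grade_from_pdff(pdff_percent: float) -> int:
    """Grade from an MRI-PDFF value using the 5 / 16.3 / 21.6 % cutoffs."""
    if pdff_percent < 0:
        raise InputError(f"PDFF must be nonnegative, got {pdff_percent}")
    return grade_from_measure(pdff_percent, PDFF_CUTOFFS)


def icc_two_way_random(table: RatingTable) -> dict:
    """ICC(2,1) and ICC(2,k): two-way random effects, absolute agreement.

    Computed from the two-way ANOVA mean squares; 95% confidence intervals
    follow the F-based construction of McGraw & Wong.  Values are <= 1; a
    table with zero total variance is degenerate.
    """
    x = table.values
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise DegenerateInputError("zero total variance in rating table")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # between-subjects
    msc = ss_cols / (k - 1)  # between-raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual

    icc_single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc_mean = (msr - mse) / (msr + (msc - mse) / n)

    if mse == 0.0:  # perfect agreement: the interval collapses
        return {
            "icc_single": float(icc_single), "icc_mean": float(icc_mean),
            "ci95_single": (float(icc_single), float(icc_single)),
            "ci95_mean": (float(icc_mean), float(icc_mean)),
            "n_subjects": n, "n_raters": k,
            "mean_squares": {"msr": float(msr), "msc": float(msc), "mse": 0.0,
                             "f": np.inf},
        }

    # F-based CI for ICC(2,1)/(2,k), McGraw & Wong (1996).
    alpha = 0.05
    a = k * icc_single / (n * (1 - icc_single))
    b = 1 + k * icc_single * (n - 1) / (n * (1 - icc_single))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_star = msr / mse if mse > 0 else np.inf
    fl = sps.f.ppf(1 - alpha / 2, n - 1, v)
    fu = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo_s = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi_s = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    lo_m = lo_s * k / (1 + lo_s * (k - 1))
    hi_m = hi_s * k / (1 + hi_s * (k - 1))
    return {
        "icc_single": float(icc_single),
        "icc_mean": float(icc_mean),
        "ci95_single": (float(lo_s), float(hi_s)),
        "ci95_mean": (float(lo_m), float(hi_m)),
        "n_subjects": n,
        "n_raters": k,
        "mean_squares": {"msr": float(msr), "msc": float(msc), "mse": float(mse),
                         "f": float(f_star)},
    }


def roc_analysis(scores, labels, n_boot: int = 2000, seed: int = 0) -> dict:
    """AUROC with bootstrap CI and Youden-optimal operating-point metrics.

    The cutoff maximizes Youden's J = sensitivity + specificity - 1; a score
    at or above the cutoff calls the positive class.  Likelihood ratios and
    predictive values come from the contingency table at that cutoff.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be equal-length 1-D")
    if len(np.unique(y)) < 2:
        raise InputError("both classes must be present")

    auroc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    cutoff = float(thr[np.argmax(j)])

    pos = s >= cutoff
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    tn = int(np.sum(~pos & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    lr_pos = sens / (1 - spec) if spec < 1 else np.inf
    lr_neg = (1 - sens) / spec if spec > 0 else np.inf

    # Stratified bootstrap over subjects.
    rng = np.random.default_rng(seed)
    idx_pos, idx_neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    boots = []
    for _ in range(n_boot):
        bi = np.concatenate([rng.choice(idx_pos, len(idx_pos)),
                             rng.choice(idx_neg, len(idx_neg))])
        boots.append(roc_auc_score(y[bi], s[bi]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "auroc": auroc, "ci95": (float(lo), float(hi)), "cutoff": cutoff,
        "sens": float(sens), "spec": float(spec), "ppv": float(ppv),
        "npv": float(npv), "lr_pos": float(lr_pos), "lr_neg": float(lr_neg),
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def operating_point_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Contingency arithmetic for a fixed operating point."""
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "sens": sens, "spec": spec,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
        "lr_pos": sens / (1 - spec) if spec < 1 else np.inf,
        "lr_neg": (1 - sens) / spec if spec > 0 else np.inf,
    }


def correlation_regression(x, y) -> dict:
    """Spearman + Pearson correlation and OLS y ~ x with slope CI.

    ``r_squared_pct`` is the coefficient of determination in percent, the
    convention used when reporting attenuation-vs-PDFF regressions.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise InputError("need equal-length inputs with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateInputError("constant input")
    rho, rho_p = sps.spearmanr(x, y)
    r, r_p = sps.pearsonr(x, y)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    ci = ols.conf_int(alpha=0.05)
    return {
        "spearman_rho": float(rho), "spearman_p": float(rho_p),
        "pearson_r": float(r), "pearson_p": float(r_p),
        "slope": float(ols.params[1]), "intercept": float(ols.params[0]),
        "r_squared_pct": float(100.0 * ols.rsquared),
        "ci95_slope": (float(ci[1][0]), float(ci[1][1])),
    }


# Cohort template: marginal means/SDs of the study population this module is
# exercised against (PDFF in %, attenuations in their modality units).
COHORT_MARGINALS: dict[str, dict] = {
    "pdff": {"mean": 11.16, "sd": 7.24, "clip": (0.0, 60.0)},
    "qus_ac": {"mean": 0.44, "sd": 0.09, "clip": (0.0, 1.2)},
    "ati": {"mean": 0.71, "sd": 0.09, "clip": (0.0, 1.5)},
    "uap": {"mean": 262.54, "sd": 46.66, "clip": (100.0, 400.0)},
    "age": {"mean": 52.3, "sd": 14.5, "clip": (18.0, 95.0)},
    "bmi": {"mean": 28.7, "sd": 5.1, "clip": (15.0, 55.0)},
}
_MALE_FRACTION = 0.6


def synth_cohort(n: int, marginals: dict | None = None,
                 rho_ac_pdff: float = 0.9, seed: int = 0) -> pd.DataFrame:
    """Gaussian-copula synthetic cohort with a controllable AC-PDFF link.

    Latent normals for (pdff, qus_ac) share correlation ``rho_ac_pdff``; the
    comparator modalities (ati, uap) track pdff with fixed weaker latent
    correlations (0.7, 0.5), and demographics are independent.  Normal
    marginals with the template means/SDs are clipped to physical ranges.
    The rank (Spearman) correlation implied by a latent correlation rho is
    6/pi * asin(rho/2).
    """
    if not -1.0 < rho_ac_pdff < 1.0:
        raise ConfigurationError(f"rho_ac_pdff must be in (-1, 1), got {rho_ac_pdff}")
    marg = {**COHORT_MARGINALS, **(marginals or {})}
    cols = ["pdff", "qus_ac", "ati", "uap"]
    corr = np.eye(4)
    corr[0, 1] = corr[1, 0] = rho_ac_pdff
    corr[0, 2] = corr[2, 0] = 0.7
    corr[0, 3] = corr[3, 0] = 0.5
    corr[1, 2] = corr[2, 1] = rho_ac_pdff * 0.7
    corr[1, 3] = corr[3, 1] = rho_ac_pdff * 0.5
    corr[2, 3] = corr[3, 2] = 0.35
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin <= 1e-10:
        raise ConfigurationError("infeasible latent correlation matrix")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(4), corr, size=n, method="cholesky")
    data = {}
    for i, c in enumerate(cols):
        m = marg[c]
        data[c] = np.clip(m["mean"] + m["sd"] * z[:, i], *m["clip"])
    for c in ("age", "bmi"):
        m = marg[c]
        data[c] = np.clip(m["mean"] + m["sd"] * rng.standard_normal(n), *m["clip"])
    data["sex"] = np.where(rng.random(n) < _MALE_FRACTION, "M", "F")
    df = pd.DataFrame(data, columns=["pdff", "qus_ac", "ati", "uap", "age", "sex", "bmi"])
    df.index.name = "subject"
    return df
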