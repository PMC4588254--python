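"""Inter-rater reliability statistics: ICC, multi-rater kappa, Landis-Koch.

Continuous measurements (subjects x raters) are assessed with the two-way
random-effects intraclass correlation coefficient for absolute agreement —
ICC(2,1) for single measures by default, ICC(2,k) for rater averages — with
95% confidence intervals from the Shrout-Fleiss F-based interval.

Categorical outcomes are assessed with Fleiss' multi-rater kappa (default)
or the mean of pairwise Cohen's kappas, with a large-sample one-sided
z-test of the no-agreement null.  Estimates are given a verbal Landis-Koch
label: <0 poor, then slight / fair / moderate / substantial / almost
perfect in steps of 0.2 up to 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coords import ValidationError

PARAMETERS = ("vertical", "ap", "transverse", "sagittal", "inlet", "outlet")
ROTATION_PLANES = ("sagittal", "inlet", "outlet")


class DegenerateStatisticError(ValueError):
    """The agreement statistic is undefined for this ratings matrix."""


@dataclass(frozen=True)
class AgreementEstimate:
    statistic: str  # "icc" or "kappa"
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None

    @property
    def landis_koch_label(self) -> str:
        return landis_koch(self.value)


def landis_koch(value: float) -> str:
    """Verbal strength-of-agreement label for a kappa/ICC value.

    The conventional scale bands at 0.2/0.4/0.6/0.8; published band edges
    (0.20, 0.21, 0.40, 0.41, ...) are honoured by cutting each band 0.005
    below the next printed lower bound, so 0.20 is slight and 0.21 is fair.
    Values below 0 are "poor"; values above 1 are invalid.
    """
    if not np.isfinite(value):
        raise ValidationError(f"agreement value must be finite, got {value}")
    if value > 1:
        raise ValidationError(f"agreement value cannot exceed 1, got {value}")
    if value < 0:
        return "poor"
    for cut, label in ((0.205, "slight"), (0.405, "fair"),
                       (0.605, "moderate"), (0.805, "substantial")):
        if value < cut:
            return label
    return "almost perfect"


def _check_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError(
            f"ratings matrix must be (subjects >= 2) x (raters >= 2), got shape {m.shape}"
        )
    return m


def _anova_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares of a subjects x raters matrix:
    (rows/subjects MSR, columns/raters MSC, residual MSE)."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse


def icc_two_way_random(
    m: np.ndarray, form: str = "single", alpha: float = 0.05
) -> AgreementEstimate:
    """ICC under the two-way random-effects, absolute-agreement model.

    ``form="single"`` gives ICC(2,1) (reliability of one rater's
    measurement), ``form="average"`` gives ICC(2,k).  The confidence
    interval is the Shrout-Fleiss F-based interval at level ``1 - alpha``.

    Raises :class:`DegenerateStatisticError` when there is no
    between-subject variability, in which case agreement is undefined.
    """
    if form not in ("single", "average"):
        raise ValidationError(f"form must be 'single' or 'average', got {form!r}")
    m = _check_matrix(np.asarray(m, dtype=float))
    if not np.all(np.isfinite(m)):
        raise ValidationError("ratings matrix contains non-finite values")
    if np.all(m == m[0]) or np.ptp(m) == 0:
        raise DegenerateStatisticError(
            "no between-subject variability: ICC is undefined"
        )
    n, k = m.shape
    msr, msc, mse = _anova_mean_squares(m)

    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom_single <= 0:
        raise DegenerateStatisticError("zero total variance: ICC is undefined")
    icc_single = (msr - mse) / denom_single
    lo, hi = _icc2_ci(msr, msc, mse, n, k, icc_single, alpha)

    if form == "single":
        value, ci = icc_single, (lo, hi)
    else:
        denom_avg = msr + (msc - mse) / n
        if denom_avg <= 0:
            raise DegenerateStatisticError("zero total variance: ICC is undefined")
        value = (msr - mse) / denom_avg
        sl = lambda r: r * k / (1 + (k - 1) * r)  # single -> average (Spearman-Brown)
        ci = (sl(lo), sl(hi))
    return AgreementEstimate("icc", float(value), float(min(ci[0], value)),
                             float(max(ci[1], value)))


def _icc2_ci(msr, msc, mse, n, k, icc, alpha):
    """Confidence bounds for ICC(2,1) via the Satterthwaite F* construction
    (Shrout & Fleiss 1979 / McGraw & Wong 1996)."""
    if mse == 0 or icc >= 1:
        return 1.0, 1.0
    fj = msc / mse
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = (a * fj + b) ** 2 / (
        (a * fj) ** 2 / (k - 1) + b**2 / ((n - 1) * (k - 1))
    )
    f_star1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_star1 * mse)) / (
        f_star1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = (n * (f_star2 * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_star2 * msr
    )
    return float(lower), float(upper)


def _category_table(m: np.ndarray) -> tuple[np.ndarray, list]:
    """Subjects x categories count table from a subjects x raters label matrix."""
    cats = sorted({x for row in m for x in row}, key=str)
    idx = {c: j for j, c in enumerate(cats)}
    table = np.zeros((m.shape[0], len(cats)), dtype=float)
    for i, row in enumerate(m):
        for x in row:
            table[i, idx[x]] += 1
    return table, cats


def _fleiss_kappa_with_p(table: np.ndarray) -> tuple[float, float]:
    """Fleiss' kappa and its large-sample one-sided p-value (H1: kappa > 0)."""
    n_sub, _ = table.shape
    n_rat = int(table[0].sum())
    p_j = table.sum(axis=0) / (n_sub * n_rat)
    p_bar = ((table**2).sum() - n_sub * n_rat) / (n_sub * n_rat * (n_rat - 1))
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0:
        raise DegenerateStatisticError("all ratings fall in one category: kappa undefined")
    kappa = (p_bar - p_e) / (1 - p_e)
    q_j = 1 - p_j
    s = float(np.sum(p_j * q_j))
    var0 = 2.0 / (n_sub * n_rat * (n_rat - 1)) * (
        s**2 - float(np.sum(p_j * q_j * (q_j - p_j)))
    ) / s**2
    z = kappa / np.sqrt(var0)
    return float(kappa), float(stats.norm.sf(z))


def cohen_kappa(r1: np.ndarray, r2: np.ndarray) -> tuple[float, float]:
    """Cohen's kappa for two raters and its one-sided z-test p-value."""
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    cats = sorted(set(r1) | set(r2), key=str)
    idx = {c: j for j, c in enumerate(cats)}
    n = len(r1)
    tab = np.zeros((len(cats), len(cats)))
    for a, b in zip(r1, r2):
        tab[idx[a], idx[b]] += 1
    tab /= n
    p_o = float(np.trace(tab))
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    p_e = float(rows @ cols)
    if p_e >= 1.0:
        raise DegenerateStatisticError("all ratings fall in one category: kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    var0 = (p_e + p_e**2 - float(np.sum(rows * cols * (rows + cols)))) / (n * (1 - p_e) ** 2)
    z = kappa / np.sqrt(var0)
    return float(kappa), float(stats.norm.sf(z))


def kappa_categorical(m: np.ndarray, mode: str = "fleiss") -> AgreementEstimate:
    """Chance-corrected categorical agreement across raters.

    ``mode="fleiss"`` (default) is Fleiss' multi-rater kappa with the
    large-sample one-sided z-test; ``mode="pairwise_cohen_mean"`` averages
    Cohen's kappa over rater pairs (p-value reported only for 2 raters,
    where the mean reduces to a single Cohen's kappa).
    """
    m = _check_matrix(np.asarray(m, dtype=object))
    if len({x for row in m for x in row}) < 2:
        raise DegenerateStatisticError("all ratings fall in one category: kappa undefined")
    if mode == "fleiss":
        table, _ = _category_table(m)
        kappa, p = _fleiss_kappa_with_p(table)
        return AgreementEstimate("kappa", kappa, p_value=p)
    if mode == "pairwise_cohen_mean":
        pairs = list(itertools.combinations(range(m.shape[1]), 2))
        kappas, ps = zip(*(cohen_kappa(m[:, i], m[:, j]) for i, j in pairs))
        p = ps[0] if len(pairs) == 1 else None
        return AgreementEstimate("kappa", float(np.mean(kappas)), p_value=p)
    raise ValidationError(f"unknown kappa mode {mode!r}")


@dataclass(frozen=True)
class ReliabilityReport:
    """ICC per continuous parameter and kappa per rotational plane."""

    icc: dict[str, AgreementEstimate]
    kappa: dict[str, AgreementEstimate]
    n_subjects: int
    n_raters: int
    icc_form: str = "single"
    kappa_mode: str = "fleiss"


def _report_value(report, parameter: str):
    t, r = report.translation, report.rotation
    return {
        "vertical": t.vertical_mm, "ap": t.ap_mm, "transverse": t.transverse_mm,
        "sagittal": r.sagittal_mm, "inlet": r.inlet_mm, "outlet": r.outlet_mm,
    }[parameter]


def _report_class(report, plane: str) -> str:
    r = report.rotation
    return {"sagittal": r.sagittal_class, "inlet": r.inlet_class,
            "outlet": r.outlet_class}[plane]


def reliability_report(
    reports_by_rater: dict[str, dict[str, "DisplacementReport"]],
    icc_form: str = "single",
    kappa_mode: str = "fleiss",
) -> ReliabilityReport:
    """Inter-rater reliability over a rater -> subject -> report grid.

    Every rater must have measured every subject; missing cells are listed
    in the error.  Returns ICC (with CI) for the six continuous parameters
    and kappa (with p-value) for the three rotational class outcomes.
    """
    raters = sorted(reports_by_rater)
    if len(raters) < 2:
        raise ValidationError("need at least 2 raters")
    subjects = sorted({s for r in raters for s in reports_by_rater[r]})
    missing = [(r, s) for r in raters for s in subjects if s not in reports_by_rater[r]]
    if missing:
        cells = ", ".join(f"rater {r}/subject {s}" for r, s in missing)
        raise ValidationError(f"unbalanced rater x subject grid; missing cells: {cells}")
    if len(subjects) < 2:
        raise ValidationError("need at least 2 subjects")

    icc = {}
    for param in PARAMETERS:
        m = np.array([[ _report_value(reports_by_rater[r][s], param) for r in raters]
                      for s in subjects], dtype=float)
        icc[param] = icc_two_way_random(m, form=icc_form)
    kappa = {}
    for plane in ROTATION_PLANES:
        m = np.array([[_report_class(reports_by_rater[r][s], plane) for r in raters]
                      for s in subjects], dtype=object)
        kappa[plane] = kappa_categorical(m, mode=kappa_mode)
    return ReliabilityReport(icc, kappa, len(subjects), len(raters), icc_form, kappa_mode)
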