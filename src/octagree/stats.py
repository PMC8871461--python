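"""Agreement statistics for paired EDI/conventional quantifications.

Workflow per biomarker and subgroup: a Lilliefors-corrected Kolmogorov–
Smirnov normality gate on the paired differences chooses between the paired
t-test (normal branch) and the Wilcoxon signed-rank test (non-normal
branch); the intraclass correlation coefficient — two-way, absolute
agreement, single measures, ICC(A,1) — quantifies interchangeability of the
two modes; and Bland–Altman limits of agreement are parametric
(mean ± 1.96 SD) on the normal branch or non-parametric (median centre,
Harrell–Davis 2.5/97.5% quantiles) otherwise.

The signed-rank test is implemented with its exact, tie-aware null
distribution (all 2^n equiprobable sign assignments, mid-ranks for tied
absolute differences) for n ≤ 25 and a continuity-corrected normal
approximation with tie correction beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.mstats import hdquantiles
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "PairedSample", "NormalityResult", "TestResult", "ICCResult",
    "BlandAltmanResult", "AgreementSummary", "normality_gate", "paired_test",
    "wilcoxon_signed_rank", "icc_agreement", "bland_altman", "summarize",
]


@dataclass
class PairedSample:
    """Per-eye paired measurements (one eye per subject)."""

    values_without_edi: np.ndarray
    values_with_edi: np.ndarray
    labels: pd.DataFrame | None = None  # per-eye metadata (diagnosis, edema, ids)

    def __post_init__(self) -> None:
        self.values_without_edi = np.asarray(self.values_without_edi, dtype=float)
        self.values_with_edi = np.asarray(self.values_with_edi, dtype=float)
        if self.values_without_edi.shape != self.values_with_edi.shape:
            raise ValueError("paired vectors must have equal length")
        if len(self.values_without_edi) < 3:
            raise ValueError("need at least 3 pairs")
        if self.labels is not None:
            if len(self.labels) != len(self.values_without_edi):
                raise ValueError("labels must have one row per pair")
            if "eye_id" in self.labels and self.labels["eye_id"].duplicated().any():
                raise ValueError("duplicated subject ids (one eye per subject)")

    @property
    def differences(self) -> np.ndarray:
        """with-EDI minus without-EDI."""
        return self.values_with_edi - self.values_without_edi

    @property
    def n(self) -> int:
        return len(self.values_without_edi)

    def subset(self, mask: np.ndarray) -> "PairedSample":
        mask = np.asarray(mask, dtype=bool)
        return PairedSample(
            self.values_without_edi[mask],
            self.values_with_edi[mask],
            self.labels.loc[mask].reset_index(drop=True) if self.labels is not None else None,
        )


@dataclass(frozen=True)
class NormalityResult:
    branch: str  # "normal" | "non-normal"
    statistic: float
    p_value: float
    flags: tuple[str, ...] = ()


def normality_gate(differences: np.ndarray, alpha: float = 0.05) -> NormalityResult:
    """Lilliefors-corrected one-sample KS test against a normal with the
    sample's mean and SD.  Zero-variance input is non-normal with a flag."""
    d = np.asarray(differences, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 differences")
    if np.std(d) == 0:
        return NormalityResult("non-normal", float("nan"), 0.0, ("degenerate: zero variance",))
    if len(d) < 4:
        # below the Lilliefors table: stay on the distribution-free branch
        return NormalityResult("non-normal", float("nan"), float("nan"),
                               ("n < 4: normality not assessable",))
    stat, p = lilliefors(d, dist="norm", pvalmethod="table")
    branch = "normal" if p > alpha else "non-normal"
    return NormalityResult(branch, float(stat), float(p))


@dataclass(frozen=True)
class TestResult:
    p_value: float
    test_used: str  # "paired-t" | "wilcoxon"
    statistic: float
    flags: tuple[str, ...] = ()


def _signed_rank_exact_p(w2: float, ranks2: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic.

    ``ranks2`` are doubled mid-ranks (integers); ``w2`` the doubled observed
    positive-rank sum.  Counts subset sums of the symmetric null by dynamic
    programming over all 2^n sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    n_assign = counts.sum()  # == 2**n
    lo = min(w2, total - w2)
    hi = total - lo
    p = (counts[: int(lo) + 1].sum() + counts[int(np.ceil(hi)):].sum()) / n_assign
    return float(min(p, 1.0))


def wilcoxon_signed_rank(differences: np.ndarray, exact_threshold: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's convention), tied absolute
    differences receive mid-ranks.  The null distribution is exact (full
    enumeration by DP) for n ≤ ``exact_threshold`` and a tie-corrected normal
    approximation with continuity correction beyond.
    """
    d = np.asarray(differences, dtype=float)
    nonzero = d[d != 0]
    flags: tuple[str, ...] = ()
    n_zero = len(d) - len(nonzero)
    if n_zero:
        flags += (f"{n_zero} zero differences dropped",)
    n = len(nonzero)
    if n == 0:
        return TestResult(1.0, "wilcoxon", 0.0, flags + ("degenerate: all differences zero",))
    ranks = sps.rankdata(np.abs(nonzero))
    w_pos = float(ranks[nonzero > 0].sum())
    if n <= exact_threshold:
        ranks2 = np.rint(2 * ranks).astype(int)
        p = _signed_rank_exact_p(2 * w_pos, ranks2)
        return TestResult(p, "wilcoxon", w_pos, flags)
    mu = n * (n + 1) / 4.0
    _vals, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return TestResult(1.0, "wilcoxon", w_pos, flags + ("degenerate: zero variance",))
    delta = w_pos - mu
    z = (delta - 0.5 * np.sign(delta)) / sigma
    p = float(min(2 * sps.norm.sf(abs(z)), 1.0))
    return TestResult(p, "wilcoxon", w_pos, flags)


def paired_test(sample: PairedSample, branch: str) -> TestResult:
    """Paired t-test (normal branch) or Wilcoxon signed-rank (non-normal)."""
    d = sample.differences
    if np.all(d == 0):
        return TestResult(1.0, "paired-t" if branch == "normal" else "wilcoxon",
                          0.0, ("degenerate: all differences zero",))
    if branch == "normal":
        if np.std(d, ddof=1) == 0:
            return TestResult(float("nan"), "paired-t", float("nan"),
                              ("degenerate: zero variance, t undefined",))
        t, p = sps.ttest_rel(sample.values_with_edi, sample.values_without_edi)
        return TestResult(float(p), "paired-t", float(t))
    if branch != "non-normal":
        raise ValueError("branch must be 'normal' or 'non-normal'")
    return wilcoxon_signed_rank(d)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    form: str  # "agreement" (ICC(A,1)) | "consistency" (ICC(C,1))
    flags: tuple[str, ...] = ()


def _two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way (subject × rater) ANOVA."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = table - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_agreement(
    sample: PairedSample | np.ndarray,
    form: str = "agreement",
    confidence: float = 0.95,
) -> ICCResult:
    """Single-measures ICC between the two modes with a 95% CI.

    ``form="agreement"`` gives the two-way, absolute-agreement ICC(A,1) from
    the ANOVA mean squares,

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

    with the F-distribution confidence interval of McGraw & Wong;
    ``form="consistency"`` gives ICC(C,1) = (MSR − MSE)/(MSR + (k−1)·MSE).
    """
    if isinstance(sample, PairedSample):
        table = np.column_stack([sample.values_without_edi, sample.values_with_edi])
    else:
        table = np.asarray(sample, dtype=float)
    n, k = table.shape
    if n < 5:
        raise ValueError("need at least 5 subjects for the ICC")
    msr, msc, mse = _two_way_mean_squares(table)
    alpha = 1 - confidence
    flags: tuple[str, ...] = ()
    if np.ptp(table) == 0 or (msr == 0 and mse == 0):
        return ICCResult(0.0, float("nan"), float("nan"), form,
                         ("degenerate: zero between-subject variance",))
    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            return ICCResult(icc, icc, icc, form, ("degenerate: zero residual variance",))
        fobs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fobs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = fobs * sps.f.ppf(1 - alpha / 2, df2, df1)
        return ICCResult(float(icc), float((fl - 1) / (fl + k - 1)),
                         float((fu - 1) / (fu + k - 1)), form, flags)
    if form != "agreement":
        raise ValueError("form must be 'agreement' or 'consistency'")
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        # duplicated columns: perfect agreement, CI collapses
        return ICCResult(float(icc), float(icc), float(icc), form,
                         ("degenerate: zero residual variance",))
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return ICCResult(float(icc), float(icc), float(icc), form,
                         ("degenerate: icc at upper bound",))
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return ICCResult(float(icc), float(lower), float(upper), form, flags)


@dataclass(frozen=True)
class BlandAltmanResult:
    center: float
    lower: float
    upper: float
    method: str  # "parametric" | "quantile"
    n_outside: int
    flags: tuple[str, ...] = ()


def bland_altman(
    differences: np.ndarray,
    branch: str,
    quantile_estimator: str = "harrell-davis",
) -> BlandAltmanResult:
    """Bland–Altman limits of agreement on paired differences.

    Normal branch: centre = mean, LoA = mean ± 1.96·SD.  Non-normal branch:
    centre = median, LoA = 2.5th/97.5th empirical quantiles (Harrell–Davis
    estimator by default, plain order-statistic interpolation as option).
    ``n_outside`` counts differences strictly outside [lower, upper].
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 differences")
    flags: tuple[str, ...] = ()
    if branch == "normal":
        center = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        lower, upper = center - 1.96 * sd, center + 1.96 * sd
        method = "parametric"
        if sd == 0:
            flags = ("degenerate: zero variance",)
    elif branch == "non-normal":
        center = float(np.median(d))
        if np.std(d) == 0:
            lower = upper = center
            flags = ("degenerate: zero variance",)
        elif quantile_estimator == "harrell-davis":
            q = hdquantiles(d, prob=[0.025, 0.975])
            lower, upper = float(q[0]), float(q[1])
        elif quantile_estimator == "order-statistic":
            lower, upper = (float(v) for v in np.quantile(d, [0.025, 0.975]))
        else:
            raise ValueError("quantile_estimator must be 'harrell-davis' or 'order-statistic'")
        method = "quantile"
    else:
        raise ValueError("branch must be 'normal' or 'non-normal'")
    n_outside = int(np.sum((d < lower) | (d > upper)))
    return BlandAltmanResult(center, float(lower), float(upper), method, n_outside, flags)


@dataclass
class AgreementSummary:
    """One biomarker × subgroup row of the agreement table."""

    biomarker: str
    subgroup: str
    n: int
    mean_sd_without: tuple[float, float]
    mean_sd_with: tuple[float, float]
    mean_difference: float
    p_value: float
    test_used: str
    icc: ICCResult | None
    loa: BlandAltmanResult
    flags: tuple[str, ...] = ()


def summarize(
    sample: PairedSample,
    biomarker: str = "",
    subgroup: str = "Overall",
    subgroup_mask: np.ndarray | None = None,
    icc_form: str = "agreement",
    quantile_estimator: str = "harrell-davis",
) -> AgreementSummary:
    """Compose the full agreement analysis for one biomarker/subgroup."""
    sub = sample.subset(subgroup_mask) if subgroup_mask is not None else sample
    if sub.n == 0:
        raise ValueError("empty subgroup")
    d = sub.differences
    gate = normality_gate(d)
    test = paired_test(sub, gate.branch)
    flags = gate.flags + test.flags
    icc: ICCResult | None = None
    if sub.n >= 5:
        icc = icc_agreement(sub, form=icc_form)
    else:
        flags += ("ICC omitted: subgroup n < 5",)
    loa = bland_altman(d, gate.branch, quantile_estimator)
    w = sub.values_without_edi
    e = sub.values_with_edi
    sd_w = float(np.std(w, ddof=1)) if sub.n > 1 else 0.0
    sd_e = float(np.std(e, ddof=1)) if sub.n > 1 else 0.0
    return AgreementSummary(
        biomarker=biomarker,
        subgroup=subgroup,
        n=sub.n,
        mean_sd_without=(float(np.mean(w)), sd_w),
        mean_sd_with=(float(np.mean(e)), sd_e),
        mean_difference=float(np.mean(d)),
        p_value=test.p_value,
        test_used=test.test_used,
        icc=icc,
        loa=loa,
        flags=flags,
    )
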