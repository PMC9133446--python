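"""Statistical battery of the pre/post two-group vigilance study.

Paired and two-sample t-tests with Cohen's d / dz, a 2×2 mixed-design
ANOVA (between: group; within: time), Wilcoxon signed-rank with effect
size r, chi-square crosstabs with Cohen's w, Pearson correlation, and
the noncentral-t machinery used for design sensitivity: the minimal
detectable effect size (MDE) of a t-test at given n/alpha/power, and an
equivalence check that compares a noncentral-t pivot confidence interval
for Cohen's d against a smallest effect size of interest (SESOI).

Standard tests are delegated to scipy/pingouin; the noncentral-t
root-finding, the d confidence interval and the effect-size attachments
are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """One inferential result: statistic, df, p, effect size, CI."""

    __test__ = False  # not a pytest collection target

    name: str
    statistic: float
    df: float
    p_value: float
    effect_size: float | None = None
    effect_size_name: str = ""
    ci: tuple[float, float] | None = None
    n: int | tuple[int, int] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class PowerSpec:
    """Design of a prospective two-tailed t-test."""

    family: str  # "paired" or "two-sample"
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    alpha: float = 0.05
    power: float = 0.8

    def validate(self) -> None:
        if self.family not in ("paired", "two-sample"):
            raise ValueError("family must be 'paired' or 'two-sample'")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.family == "paired":
            if self.n is None or self.n < 2:
                raise ValueError("paired design needs n >= 2 pairs")
        else:
            if self.n1 is None or self.n2 is None or min(self.n1, self.n2) < 2:
                raise ValueError("two-sample design needs n1, n2 >= 2")


# ---------------------------------------------------------------------------
# t-tests and effect sizes
# ---------------------------------------------------------------------------

def cohens_d_paired(differences) -> float:
    """dz = mean / SD of the paired differences (SD with n−1 denominator)."""
    d = np.asarray(differences, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in differences")
    return float(d.mean() / sd)


def paired_t(differences, name: str = "paired t") -> TestResult:
    """Two-tailed paired t-test on pre−post differences, with dz attached."""
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 non-missing pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return TestResult(
        name=name,
        statistic=float(t),
        df=n - 1,
        p_value=float(p),
        effect_size=float(d.mean() / sd),
        effect_size_name="dz",
        n=n,
    )


def t_from_summary(mean_diff: float, sd_diff: float, n: int) -> tuple[float, float]:
    """(t, dz) recomputed from a printed difference mean/SD and pair count."""
    if sd_diff <= 0:
        raise ValueError("SD must be positive")
    dz = mean_diff / sd_diff
    return dz * np.sqrt(n), dz


def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    return float(
        np.sqrt(
            ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        )
    )


def cohens_d_two_sample(a, b) -> float:
    """Pooled-SD standardized mean difference."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    sp = pooled_sd(a, b)
    if sp == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / sp)


def two_sample_t(
    group_a, group_b, variance_mode: str = "pooled", name: str = "two-sample t"
) -> TestResult:
    """Two-tailed independent-samples t-test with pooled Cohen's d attached."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs n >= 2")
    equal_var = variance_mode == "pooled"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return TestResult(
        name=name,
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        effect_size=cohens_d_two_sample(a, b),
        effect_size_name="d",
        n=(len(a), len(b)),
    )


# ---------------------------------------------------------------------------
# noncentral-t power machinery
# ---------------------------------------------------------------------------

def _power_from_delta(delta: float, df: float, alpha: float) -> float:
    """Exact two-tailed power of a t-test at noncentrality ``delta``."""
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = 1.0 - stats.nct.cdf(tcrit, df, delta)
    lower = stats.nct.cdf(-tcrit, df, delta)
    if np.isnan(lower):  # lower tail underflows for large noncentrality
        lower = 0.0
    if np.isnan(upper):
        upper = 1.0 - float(stats.nct.sf(-tcrit, df, delta))
    return float(upper + lower)


def power_t(spec: PowerSpec, effect_size: float) -> float:
    """Power of the two-tailed t-test described by ``spec`` at a given d/dz."""
    spec.validate()
    if spec.family == "paired":
        df = spec.n - 1
        delta = effect_size * np.sqrt(spec.n)
    else:
        df = spec.n1 + spec.n2 - 2
        delta = effect_size * np.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    return _power_from_delta(delta, df, spec.alpha)


def mde_t(spec: PowerSpec, tol: float = 1e-6) -> float:
    """Minimal detectable effect size by noncentral-t root finding.

    The smallest Cohen's d (two-sample) or dz (paired) at which the
    two-tailed test reaches the target power, solved on the exact
    noncentral t distribution to ``tol`` in d.
    """
    spec.validate()

    def gap(d: float) -> float:
        return power_t(spec, d) - spec.power

    hi = 0.5
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e3:
            raise ValueError("target power unreachable at this design")
    return float(optimize.brentq(gap, 1e-12, hi, xtol=tol))


def cohens_d_ci(
    group_a, group_b, confidence: float = 0.95
) -> tuple[float, float]:
    """Noncentral-t pivot confidence interval for pooled Cohen's d."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    sp = pooled_sd(a, b)
    if sp == 0:
        raise ValueError("degenerate (zero) pooled variance")
    t_obs = (a.mean() - b.mean()) / (sp * np.sqrt(1 / n1 + 1 / n2))
    alpha = 1 - confidence

    def solve(prob: float) -> float:
        lo, hi = t_obs - 50, t_obs + 50
        return optimize.brentq(
            lambda nc: np.nan_to_num(stats.nct.cdf(t_obs, df, nc) - prob, nan=-prob),
            lo,
            hi,
            xtol=1e-8,
        )

    nc_lo = solve(1 - alpha / 2)
    nc_hi = solve(alpha / 2)
    return nc_lo / scale, nc_hi / scale


def equivalence_verdict(ci: tuple[float, float], sesoi: float) -> bool:
    """True iff both CI bounds for d lie strictly inside (−sesoi, +sesoi)."""
    lo, hi = ci
    return -sesoi < lo and hi < sesoi


def equivalence_check(
    group_a, group_b, sesoi: float, confidence: float = 0.95
) -> TestResult:
    """Baseline-equivalence check against a smallest effect size of interest.

    The groups are equivalent if the noncentral-t pivot CI for pooled
    Cohen's d lies strictly inside (−sesoi, +sesoi).
    """
    ci = cohens_d_ci(group_a, group_b, confidence)
    d = cohens_d_two_sample(group_a, group_b)
    equivalent = equivalence_verdict(ci, sesoi)
    base = two_sample_t(group_a, group_b)
    return TestResult(
        name="equivalence",
        statistic=base.statistic,
        df=base.df,
        p_value=base.p_value,
        effect_size=d,
        effect_size_name="d",
        ci=ci,
        n=(len(group_a), len(group_b)),
        extra={"sesoi": sesoi, "equivalent": equivalent},
    )


# ---------------------------------------------------------------------------
# mixed ANOVA, Wilcoxon, chi-square, Pearson
# ---------------------------------------------------------------------------

def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "id",
    between: str = "group",
    within: str = "time",
) -> dict[str, TestResult]:
    """2×2 mixed-design ANOVA: within factor time, between factor group.

    Returns TestResults for ``"time"`` and ``"interaction"``.  The effect
    size is reported as Cohen's d via the d = 2f conversion with
    f = sqrt(η²p / (1 − η²p)).  Incomplete cases raise with the offending
    subjects listed.
    """
    import pingouin as pg

    counts = data.groupby(subject)[within].nunique()
    bad = counts[counts < 2].index.tolist()
    if bad:
        raise ValueError(f"subjects missing a timepoint: {bad}")
    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, subject=subject, between=between
    )
    out = {}
    for source, key in ((within, "time"), ("Interaction", "interaction")):
        row = aov.loc[aov["Source"].str.lower() == source.lower()]
        if row.empty:
            raise RuntimeError(f"ANOVA source {source!r} not found")
        row = row.iloc[0]
        np2 = float(row["np2"])
        f = np.sqrt(np2 / (1 - np2)) if np2 < 1 else np.inf
        pcol = "p_unc" if "p_unc" in row.index else "p-unc"
        out[key] = TestResult(
            name=f"mixed ANOVA {key}",
            statistic=float(row["F"]),
            df=float(row["DF1"]),
            p_value=float(row[pcol]),
            effect_size=float(2 * f),
            effect_size_name="d (=2f)",
            extra={"df_den": float(row["DF2"]), "np2": np2},
        )
    return out


def wilcoxon_signed_rank(differences, method: str = "auto") -> TestResult:
    """Wilcoxon signed-rank test with continuity-corrected Z and r = |Z|/√n.

    Zero differences are dropped (Wilcoxon's convention); ``method`` is
    ``"exact"`` (full null enumeration, no ties/zeros), ``"approx"``
    (normal approximation with continuity correction) or ``"auto"``.
    """
    d = np.asarray(differences, dtype=float)
    n_total = len(d)
    d = d[d != 0]
    n = len(d)
    if n < 1:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    ties = np.unique(np.abs(d), return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24 - (ties**3 - ties).sum() / 48
    sigma = np.sqrt(sigma2)
    # continuity-corrected z
    diff = w_plus - mu
    if sigma > 0:
        z = (diff - 0.5 * np.sign(diff)) / sigma if diff != 0 else 0.0
    else:
        z = 0.0

    use_exact = method == "exact" or (
        method == "auto" and n <= 25 and len(ties) == n
    )
    if use_exact:
        p = float(stats.wilcoxon(d, method="exact").pvalue)
    else:
        if n < 5:
            raise ValueError("need >= 5 non-zero differences for the "
                             "normal approximation")
        p = float(2 * stats.norm.sf(abs(z)))
    return TestResult(
        name="Wilcoxon signed-rank",
        statistic=float(z),
        df=np.nan,
        p_value=min(p, 1.0),
        effect_size=float(abs(z) / np.sqrt(n_total)),
        effect_size_name="r",
        n=n_total,
        extra={"W_plus": float(w_plus), "n_nonzero": n},
    )


def chi_square_crosstab(table) -> TestResult:
    """Pearson chi-square on a contingency table, with Cohen's w = √(χ²/N)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need at least a 2×2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    n = obs.sum()
    return TestResult(
        name="chi-square",
        statistic=float(chi2),
        df=float(dof),
        p_value=float(p),
        effect_size=float(np.sqrt(chi2 / n)),
        effect_size_name="w",
        n=int(n),
    )


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        name="Pearson r",
        statistic=float(r),
        df=len(x) - 2,
        p_value=float(p),
        effect_size=float(r),
        effect_size_name="r",
        n=len(x),
    )
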