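"""Single-marker association for common variants.

Covers the conventional battery for a candidate-gene case-control study:
Hardy-Weinberg checks in controls, allelic 2x2 Pearson chi-square with odds
ratio and Woolf confidence interval, label-permutation empirical p-values,
and covariate-adjusted logistic regression (sex, age, ancestry proportion,
plus BMI for substance-dependence outcomes or SD status for BMI contrasts).

BMI is analysed as three contrasts against the normal-weight stratum:
overweight, obese, and overweight+obese; underweight subjects sit outside all
three.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BmiClass, CohortStudy, MISSING, Population, SubjectRecord

__all__ = [
    "Allelic2x2Result",
    "LogisticAssocResult",
    "BmiContrast",
    "hwe_test",
    "allelic_chi2",
    "permutation_empirical_p",
    "logistic_assoc",
    "run_bmi_contrasts",
    "run_sd_assoc",
    "ConvergenceFailure",
]


class BmiContrast(enum.Enum):
    """Conditioned stratum vs. the normal-weight comparison stratum."""

    OVERWEIGHT_VS_NORMAL = "overweight"
    OBESE_VS_NORMAL = "obese"
    OVERWEIGHT_OBESE_VS_NORMAL = "overweight+obese"

    @property
    def conditioned_classes(self) -> tuple[BmiClass, ...]:
        return {
            BmiContrast.OVERWEIGHT_VS_NORMAL: (BmiClass.OVERWEIGHT,),
            BmiContrast.OBESE_VS_NORMAL: (BmiClass.OBESE,),
            BmiContrast.OVERWEIGHT_OBESE_VS_NORMAL: (
                BmiClass.OVERWEIGHT,
                BmiClass.OBESE,
            ),
        }[self]


@dataclass(frozen=True)
class Allelic2x2Result:
    chi2: float
    p_obs: float
    or_: float
    ci95: tuple[float, float]
    counts: tuple[int, int, int, int]
    p_emp: float | None = None
    freq_conditioned: float | None = None
    freq_comparison: float | None = None


@dataclass(frozen=True)
class LogisticAssocResult:
    beta: float
    stat: float
    p_adj: float
    or_adj: float
    ci95: tuple[float, float]
    covariates: tuple[str, ...]
    n: int


class ConvergenceFailure(RuntimeError):
    """Logistic fit failed (separation or non-convergence); no p-value exists."""


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "exact") -> float:
    """Hardy-Weinberg test from genotype counts (AA, Aa, aa).

    ``exact`` sums, over all heterozygote counts compatible with the observed
    allele totals, the conditional probabilities no larger than the observed
    configuration's.  ``chi2`` is the 1-df Pearson goodness-of-fit test against
    expected p^2 : 2pq : q^2.  Monomorphic samples return p = 1.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped subjects")
    n_a = n_Aa + 2 * n_aa  # minor-allele count
    n_A = 2 * n - n_a
    if n_a == 0 or n_A == 0:
        return 1.0
    if method == "chi2":
        p = n_A / (2 * n)
        q = 1.0 - p
        expected = np.array([p * p, 2 * p * q, q * q]) * n
        observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        return float(stats.chi2.sf(chi2, df=1))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    # Exact: P(het = h | allele counts) over h with h = n_a (mod 2).
    rare = min(n_a, n_A)
    hets = np.arange(rare % 2, rare + 1, 2)
    logs = np.array([_log_het_prob(int(h), n, n_a) for h in hets])
    m = logs.max()
    probs = np.exp(logs - m)
    probs /= probs.sum()
    obs_idx = int(np.where(hets == n_Aa)[0][0])
    p = float(probs[probs <= probs[obs_idx] * (1 + 1e-12)].sum())
    return min(1.0, p)


def _log_het_prob(h: int, n: int, n_minor: int) -> float:
    """log P(n_Aa = h | n subjects, n_minor minor alleles), Levene's formula."""
    n_major = 2 * n - n_minor
    if (n_minor - h) % 2 or h > min(n_minor, n_major):
        return -math.inf
    hom_minor = (n_minor - h) // 2
    hom_major = n - h - hom_minor
    if hom_major < 0:
        return -math.inf
    return (
        math.lgamma(n + 1)
        - math.lgamma(hom_major + 1)
        - math.lgamma(h + 1)
        - math.lgamma(hom_minor + 1)
        + h * math.log(2)
        + math.lgamma(n_minor + 1)
        + math.lgamma(n_major + 1)
        - math.lgamma(2 * n + 1)
    )


def allelic_chi2(a: int, b: int, c: int, d: int) -> Allelic2x2Result:
    """Pearson 2x2 chi-square (1 df, no continuity correction) with OR and CI.

    Table layout: rows are strata (conditioned, comparison), columns are
    (minor, major) allele counts — [[a, b], [c, d]].  OR = ad/bc, with a 0.5
    Haldane-Anscombe increment to every cell only when some cell is zero; the
    95% CI is Woolf's log interval.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate 2x2 table: a margin is zero")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (or_ * math.exp(-1.959963984540054 * se), or_ * math.exp(1.959963984540054 * se))
    return Allelic2x2Result(
        chi2=float(chi2),
        p_obs=p,
        or_=float(or_),
        ci95=ci,
        counts=(a, b, c, d),
        freq_conditioned=a / r1,
        freq_comparison=c / r2,
    )


def _allelic_chi2_stat(minor1: int, total1: int, minor2: int, total2: int) -> float:
    a, b = minor1, total1 - minor1
    c, d = minor2, total2 - minor2
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    n = r1 + r2
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def permutation_empirical_p(
    dosages: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator,
) -> float:
    """Label-permutation empirical p for the allelic chi-square.

    Subjects' dosages stay fixed; binary group labels are permuted.  The
    estimator is (1 + #{permuted chi2 >= observed}) / (1 + n_perm), which can
    never report zero.  Missing dosages are excluded.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dosages = np.asarray(dosages)
    labels = np.asarray(labels, dtype=bool)
    if dosages.shape != labels.shape:
        raise ValueError("dosages and labels differ in length")
    keep = dosages != MISSING
    dosages, labels = dosages[keep].astype(np.int64), labels[keep]
    n1 = int(labels.sum())
    if n1 < 2 or (labels.size - n1) < 2:
        raise ValueError("need at least two subjects per label")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    total1, total2 = 2 * n1, 2 * (labels.size - n1)
    grand_minor = int(dosages.sum())
    obs = _allelic_chi2_stat(int(dosages[labels].sum()), total1, grand_minor - int(dosages[labels].sum()), total2)
    exceed = 0
    # vectorised permutations in blocks to bound memory
    block = max(1, min(n_perm, 4096))
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        # each row: a fresh permutation of subject indices; take the first n1
        order = np.argsort(rng.random((m, labels.size)), axis=1)[:, :n1]
        minor1 = dosages[order].sum(axis=1)
        stats_perm = _vector_chi2(minor1, total1, grand_minor - minor1, total2)
        exceed += int(np.count_nonzero(stats_perm >= obs - 1e-12))
        done += m
    return (1 + exceed) / (1 + n_perm)


def _vector_chi2(
    minor1: np.ndarray, total1: int, minor2: np.ndarray, total2: int
) -> np.ndarray:
    a = minor1.astype(float)
    b = total1 - a
    c = minor2.astype(float)
    d = total2 - c
    r1, r2 = total1, total2
    c1, c2 = a + c, b + d
    n = r1 + r2
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n * (a * d - b * c) ** 2 / denom
    out[denom == 0] = 0.0
    return out


def logistic_assoc(
    outcome: np.ndarray,
    dosage: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> LogisticAssocResult:
    """Additive-coding logistic regression of a binary outcome on dosage.

    Maximum-likelihood fit via statsmodels; the reported statistic and p-value
    are the Wald z and its two-sided p for the dosage coefficient.  Rows with
    a missing dosage are dropped.  Separation or non-convergence raises
    :class:`ConvergenceFailure` rather than fabricating a p-value.
    """
    import statsmodels.api as sm

    outcome = np.asarray(outcome, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    keep = dosage != MISSING
    outcome, dosage = outcome[keep], dosage[keep]
    cov_names: tuple[str, ...] = ()
    X = pd.DataFrame({"dosage": dosage})
    if covariates is not None:
        cov = covariates.loc[keep].reset_index(drop=True) if len(covariates) == len(keep) else covariates.reset_index(drop=True)
        for col in cov.columns:
            if cov[col].nunique() <= 1:
                raise ValueError(f"covariate {col!r} is constant")
        X = pd.concat([X, cov.astype(float)], axis=1)
        cov_names = tuple(cov.columns)
    if len(set(outcome)) < 2:
        raise ValueError("outcome must contain both classes")
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter("ignore", category=FutureWarning)
        try:
            fit = sm.Logit(outcome, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # noqa: BLE001 - any failure means "no fit"
            raise ConvergenceFailure(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceFailure("logistic fit did not converge")
    if abs(fit.params["dosage"]) > 15:
        raise ConvergenceFailure("quasi-separation: dosage effect unbounded")
    beta = float(fit.params["dosage"])
    se = float(fit.bse["dosage"])
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    ci = (math.exp(beta - 1.959963984540054 * se), math.exp(beta + 1.959963984540054 * se))
    return LogisticAssocResult(
        beta=beta,
        stat=float(z),
        p_adj=p,
        or_adj=math.exp(beta),
        ci95=ci,
        covariates=cov_names,
        n=int(len(outcome)),
    )


# ---------------------------------------------------------------------------
# study-level drivers
# ---------------------------------------------------------------------------


def _require_subject_level(study: CohortStudy) -> None:
    if study.genotypes is None:
        raise ValueError(
            "subject-level genotypes required; a count-only table cannot "
            "support stratified or covariate-adjusted analysis"
        )


def _covariate_frame(subjects: list[SubjectRecord], extra: str) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sex": [1.0 if s.sex.value == "M" else 0.0 for s in subjects],
            "age": [s.age for s in subjects],
            "ancestry": [s.ancestry_prop for s in subjects],
        }
    )
    if extra == "sd":
        df["sd"] = [1.0 if s.sd_case else 0.0 for s in subjects]
    elif extra == "bmi":
        df["bmi"] = [s.bmi for s in subjects]
    # drop covariates that are constant within the stratum (e.g. ancestry in a
    # single-population analysis) rather than failing the fit
    return df.loc[:, df.nunique() > 1]


def run_bmi_contrasts(
    study: CohortStudy,
    site_id: str,
    contrast: BmiContrast,
    population: Population | None = None,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[Allelic2x2Result, LogisticAssocResult]:
    """One BMI contrast at one site: allelic test + adjusted logistic model.

    Cases and controls are pooled; SD status enters the logistic model as a
    covariate.  Underweight subjects are excluded from every contrast.  The
    conditioned stratum is coded 1, normal weight 0.
    """
    _require_subject_level(study)
    g = study.genotypes
    j = g.site_index(site_id)
    cond = contrast.conditioned_classes
    subjects, outcome, dosage = [], [], []
    for i, s in enumerate(g.subjects):
        if s.excluded or s.bmi_class is BmiClass.UNDERWEIGHT:
            continue
        if population is not None and s.population is not population:
            continue
        if s.bmi_class in cond:
            y = 1
        elif s.bmi_class is BmiClass.NORMAL:
            y = 0
        else:
            continue
        subjects.append(s)
        outcome.append(y)
        dosage.append(int(g.calls[i, j]))
    outcome_arr = np.array(outcome)
    dosage_arr = np.array(dosage)
    called = dosage_arr != MISSING
    if not (outcome_arr[called] == 1).any() or not (outcome_arr[called] == 0).any():
        raise ValueError(f"empty stratum for {contrast.value}: contrast untestable")
    a = int(dosage_arr[called & (outcome_arr == 1)].sum())
    n1 = int(2 * np.count_nonzero(called & (outcome_arr == 1)))
    c = int(dosage_arr[called & (outcome_arr == 0)].sum())
    n0 = int(2 * np.count_nonzero(called & (outcome_arr == 0)))
    allelic = allelic_chi2(a, n1 - a, c, n0 - c)
    p_emp = permutation_empirical_p(dosage_arr, outcome_arr == 1, n_perm, seed)
    allelic = Allelic2x2Result(
        chi2=allelic.chi2,
        p_obs=allelic.p_obs,
        or_=allelic.or_,
        ci95=allelic.ci95,
        counts=allelic.counts,
        p_emp=p_emp,
        freq_conditioned=allelic.freq_conditioned,
        freq_comparison=allelic.freq_comparison,
    )
    cov = _covariate_frame(subjects, extra="sd")
    logistic = logistic_assoc(outcome_arr, dosage_arr, cov)
    return allelic, logistic


def run_sd_assoc(
    study: CohortStudy,
    site_id: str,
    trait: str = "sd",
    population: Population | None = None,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[Allelic2x2Result, LogisticAssocResult]:
    """Case-control association of a common site with an SD trait.

    ``trait`` is one of sd/ad/cd/od/mjd; cases carry the trait, the comparison
    group is the screened controls, and BMI joins the covariates.
    """
    _require_subject_level(study)
    if trait not in ("sd", "ad", "cd", "od", "mjd"):
        raise ValueError(f"unknown trait {trait!r}")
    g = study.genotypes
    j = g.site_index(site_id)
    subjects, outcome, dosage = [], [], []
    for i, s in enumerate(g.subjects):
        if s.excluded:
            continue
        if population is not None and s.population is not population:
            continue
        has = s.sd_case if trait == "sd" else getattr(s, trait)
        if has:
            y = 1
        elif s.screened_control:
            y = 0
        else:
            continue
        subjects.append(s)
        outcome.append(y)
        dosage.append(int(g.calls[i, j]))
    outcome_arr = np.array(outcome)
    dosage_arr = np.array(dosage)
    called = dosage_arr != MISSING
    if not (outcome_arr[called] == 1).any() or not (outcome_arr[called] == 0).any():
        raise ValueError(f"no callable subjects on one side of trait {trait!r}")
    a = int(dosage_arr[called & (outcome_arr == 1)].sum())
    n1 = int(2 * np.count_nonzero(called & (outcome_arr == 1)))
    c = int(dosage_arr[called & (outcome_arr == 0)].sum())
    n0 = int(2 * np.count_nonzero(called & (outcome_arr == 0)))
    allelic = allelic_chi2(a, n1 - a, c, n0 - c)
    p_emp = permutation_empirical_p(dosage_arr, outcome_arr == 1, n_perm, seed)
    allelic = Allelic2x2Result(
        chi2=allelic.chi2,
        p_obs=allelic.p_obs,
        or_=allelic.or_,
        ci95=allelic.ci95,
        counts=allelic.counts,
        p_emp=p_emp,
        freq_conditioned=allelic.freq_conditioned,
        freq_comparison=allelic.freq_comparison,
    )
    cov = _covariate_frame(subjects, extra="bmi")
    logistic = logistic_assoc(outcome_arr, dosage_arr, cov)
    return allelic, logistic
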