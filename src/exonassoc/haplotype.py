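"""Two-locus haplotype phasing by EM, LD statistics, and haplotype association.

With unphased genotypes at two biallelic loci the only phase ambiguity is the
double heterozygote, which may be AB/ab or Ab/aB.  The EM algorithm splits
each double heterozygote's two haplotypes between the cis and trans
configurations in proportion to their current estimated probabilities
(f_AB*f_ab vs f_Ab*f_aB) and re-estimates the four haplotype frequencies from
the expected counts, iterating to convergence.  Allele margins are fixed by
the observed dosages, so the likelihood has a single free parameter and is
well behaved in practice.

Labels: "A"/"a" are the major/minor alleles at locus 1, "B"/"b" at locus 2,
so haplotype "AB" carries the major allele at both loci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CohortStudy, MISSING
from .common import BmiContrast, _allelic_chi2_stat
from .cohort import BmiClass

__all__ = [
    "HaplotypeTable",
    "LDStats",
    "HaplotypeAssocResult",
    "em_haplotype_freqs",
    "ld_stats",
    "haplotype_assoc",
    "HAPLOTYPE_ORDER",
]

HAPLOTYPE_ORDER = ("AB", "Ab", "aB", "ab")


@dataclass(frozen=True)
class HaplotypeTable:
    """Estimated haplotype frequencies f(AB), f(Ab), f(aB), f(ab)."""

    freqs: tuple[float, float, float, float]
    loglik: float
    n_iter: int
    converged: bool
    n_subjects: int

    def freq(self, hap: str) -> float:
        return self.freqs[HAPLOTYPE_ORDER.index(hap)]


@dataclass(frozen=True)
class LDStats:
    d: float
    d_prime: float
    r2: float | None  # None when undefined (an allele frequency is zero)


@dataclass(frozen=True)
class HaplotypeAssocResult:
    haplotype: str
    freq_conditioned: float
    freq_comparison: float
    chi2: float
    p_obs: float
    p_emp: float | None
    reliable: bool


def _genotype_class_counts(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """3x3 table of joint dosage counts over subjects complete at both loci."""
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    if d1.shape != d2.shape:
        raise ValueError("dosage vectors differ in length")
    keep = (d1 != MISSING) & (d2 != MISSING)
    d1, d2 = d1[keep], d2[keep]
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (d1.astype(int), d2.astype(int)), 1)
    return counts


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 dosage table given hap freqs."""
    fAB, fAb, faB, fab = f
    # P(genotype class) under random union of gametes
    p = np.empty((3, 3))
    p[0, 0] = fAB * fAB
    p[0, 1] = 2 * fAB * fAb
    p[0, 2] = fAb * fAb
    p[1, 0] = 2 * fAB * faB
    p[1, 1] = 2 * (fAB * fab + fAb * faB)
    p[1, 2] = 2 * fAb * fab
    p[2, 0] = faB * faB
    p[2, 1] = 2 * faB * fab
    p[2, 2] = fab * fab
    with np.errstate(divide="ignore"):
        lp = np.log(p)
    mask = counts > 0
    if np.any(np.isneginf(lp[mask])):
        return -math.inf
    return float((counts[mask] * lp[mask]).sum())


def em_haplotype_freqs(
    d1: np.ndarray,
    d2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> HaplotypeTable:
    """EM estimate of two-locus haplotype frequencies from unphased dosages.

    Subjects missing either call are dropped.  Initialisation is the
    linkage-equilibrium point (product of observed allele frequencies); the
    iteration stops when no frequency moves by more than ``tol``.  The
    log-likelihood is checked to be non-decreasing at every step.
    """
    counts = _genotype_class_counts(d1, d2)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no subject has complete calls at both sites")
    # fixed allele-dosage margins (minor-allele frequencies)
    p1 = float((counts.sum(axis=1) * np.array([0, 1, 2])).sum()) / (2 * n)
    p2 = float((counts.sum(axis=0) * np.array([0, 1, 2])).sum()) / (2 * n)
    pA, pa, pB, pb = 1 - p1, p1, 1 - p2, p2
    f = np.array([pA * pB, pA * pb, pa * pB, pa * pb], dtype=float)
    n_dh = int(counts[1, 1])  # double heterozygotes
    # known haplotype contributions from all unambiguous genotype classes
    base = np.zeros(4)
    base[0] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]  # AB
    base[1] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]  # Ab
    base[2] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]  # aB
    base[3] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]  # ab
    prev_ll = _loglik(counts, f)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        denom = cis + trans
        w = 0.5 if denom == 0 else cis / denom
        expected = base.copy()
        expected[0] += n_dh * w
        expected[3] += n_dh * w
        expected[1] += n_dh * (1 - w)
        expected[2] += n_dh * (1 - w)
        new = expected / (2 * n)
        ll = _loglik(counts, new)
        if ll < prev_ll - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll}) at iteration {it}"
            )
        delta = float(np.max(np.abs(new - f)))
        f, prev_ll = new, ll
        if delta < tol:
            converged = True
            break
        if n_dh == 0:
            converged = True  # closed form: nothing left to iterate
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)
    f = np.clip(f, 0.0, None)
    f = f / f.sum()
    return HaplotypeTable(
        freqs=tuple(float(x) for x in f),
        loglik=prev_ll,
        n_iter=it,
        converged=converged,
        n_subjects=n,
    )


def ld_stats(table: HaplotypeTable) -> LDStats:
    """D, D' = |D|/D_max and r^2 from a haplotype frequency table.

    r^2 is undefined (None) when any allele frequency is zero; a monomorphic
    locus is rejected outright because D' is undefined too.
    """
    fAB, fAb, faB, fab = table.freqs
    pA, pa = fAB + fAb, faB + fab
    pB, pb = fAB + faB, fAb + fab
    if min(pA, pa) <= 0 or min(pB, pb) <= 0:
        raise ValueError("monomorphic locus: LD undefined")
    d = fAB - pA * pB
    if d >= 0:
        d_max = min(pA * pb, pa * pB)
    else:
        d_max = min(pA * pB, pa * pb)
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    r2 = d * d / (pA * pa * pB * pb)
    return LDStats(d=float(d), d_prime=float(min(1.0, d_prime)), r2=float(min(1.0, r2)))


def _posterior_hap_counts(
    d1: np.ndarray, d2: np.ndarray, table: HaplotypeTable
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject expected haplotype counts (n x 4) under the pooled EM fit.

    Returns (counts, complete_mask); rows for incomplete subjects are zero.
    """
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    keep = (d1 != MISSING) & (d2 != MISSING)
    out = np.zeros((d1.size, 4))
    fAB, fAb, faB, fab = table.freqs
    cis, trans = fAB * fab, fAb * faB
    w = 0.5 if cis + trans == 0 else cis / (cis + trans)
    contrib = {
        (0, 0): (2, 0, 0, 0),
        (0, 1): (1, 1, 0, 0),
        (0, 2): (0, 2, 0, 0),
        (1, 0): (1, 0, 1, 0),
        (1, 2): (0, 1, 0, 1),
        (2, 0): (0, 0, 2, 0),
        (2, 1): (0, 0, 1, 1),
        (2, 2): (0, 0, 0, 2),
    }
    for i in np.flatnonzero(keep):
        key = (int(d1[i]), int(d2[i]))
        if key == (1, 1):
            out[i] = (w, 1 - w, 1 - w, w)
        else:
            out[i] = contrib[key]
    return out, keep


def haplotype_assoc(
    study: CohortStudy,
    site1: str,
    site2: str,
    contrast: BmiContrast | str,
    population=None,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[HaplotypeTable, list[HaplotypeAssocResult]]:
    """Per-haplotype association between two strata at a pair of common sites.

    Phase is estimated once in the pooled sample; each subject contributes
    fixed posterior fractional haplotype counts, and each haplotype is tested
    with a 1-df chi-square of its expected count against all others, between
    the conditioned and comparison strata.  The empirical p permutes stratum
    labels while re-using the fixed posterior assignment.  Haplotypes with an
    expected count below 1 in either stratum are flagged unreliable.

    ``contrast`` is a :class:`BmiContrast` for BMI strata or one of
    ``"sd"/"ad"/"cd"/"od"/"mjd"`` for case-control strata.
    """
    if study.genotypes is None:
        raise ValueError("haplotype association requires subject-level genotypes")
    g = study.genotypes
    j1, j2 = g.site_index(site1), g.site_index(site2)
    d1 = g.calls[:, j1].copy()
    d2 = g.calls[:, j2].copy()
    y = np.full(len(g.subjects), -1)
    for i, s in enumerate(g.subjects):
        if s.excluded:
            continue
        if population is not None and s.population is not population:
            continue
        if isinstance(contrast, BmiContrast):
            if s.bmi_class in contrast.conditioned_classes:
                y[i] = 1
            elif s.bmi_class is BmiClass.NORMAL:
                y[i] = 0
        else:
            has = s.sd_case if contrast == "sd" else getattr(s, contrast)
            y[i] = 1 if has else 0
    sel = y >= 0
    d1, d2, y = d1[sel], d2[sel], y[sel]
    table = em_haplotype_freqs(d1, d2)
    if not table.converged:
        raise RuntimeError("pooled-sample EM did not converge")
    hap_counts, complete = _posterior_hap_counts(d1, d2, table)
    labels = y == 1
    if not (labels & complete).any() or not (~labels & complete).any():
        raise ValueError("a stratum has no subjects with complete calls")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    results = []
    tot1 = 2.0 * np.count_nonzero(labels & complete)
    tot0 = 2.0 * np.count_nonzero(~labels & complete)
    for h, hap in enumerate(HAPLOTYPE_ORDER):
        c1 = float(hap_counts[labels, h].sum())
        c0 = float(hap_counts[~labels, h].sum())
        chi2 = _fractional_chi2(c1, tot1, c0, tot0)
        p_obs = float(stats.chi2.sf(chi2, df=1))
        p_emp = None
        if n_perm >= 1:
            p_emp = _permute_hap(hap_counts[:, h], labels, complete, tot1, tot0, chi2, n_perm, rng)
        results.append(
            HaplotypeAssocResult(
                haplotype=hap,
                freq_conditioned=c1 / tot1,
                freq_comparison=c0 / tot0,
                chi2=chi2,
                p_obs=p_obs,
                p_emp=p_emp,
                reliable=min(c1, c0) >= 1.0,
            )
        )
    return table, results


def _fractional_chi2(a: float, n1: float, c: float, n0: float) -> float:
    b, d = n1 - a, n0 - c
    r1, r2, col1, col2 = a + b, c + d, a + c, b + d
    if min(r1, r2, col1, col2) <= 0:
        return 0.0
    n = r1 + r2
    return n * (a * d - b * c) ** 2 / (r1 * r2 * col1 * col2)


def _permute_hap(
    counts: np.ndarray,
    labels: np.ndarray,
    complete: np.ndarray,
    tot1: float,
    tot0: float,
    obs: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    idx = np.flatnonzero(complete)
    vals = counts[idx]
    n1 = int(np.count_nonzero(labels & complete))
    grand = float(vals.sum())
    exceed = 0
    block = max(1, min(n_perm, 2048))
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        order = np.argsort(rng.random((m, idx.size)), axis=1)[:, :n1]
        c1 = vals[order].sum(axis=1)
        c0 = grand - c1
        stats_perm = np.array(
            [_fractional_chi2(x1, tot1, x0, tot0) for x1, x0 in zip(c1, c0)]
        )
        exceed += int(np.count_nonzero(stats_perm >= obs - 1e-12))
        done += m
    return (1 + exceed) / (1 + n_perm)
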