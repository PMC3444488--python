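"""Synthetic case-control cohorts with the structure the analysis assumes.

The generator emulates a two-population (AA/EA) candidate-gene resequencing
study: two common variants simulated as a two-locus haplotype pair under
Hardy-Weinberg with controllable D', a panel of rare sites with independent
per-population carrier frequencies, amplicon-segment sequencing dropout that
produces the variable per-variant chromosome denominators seen in real Sanger
data, a logistic substance-dependence liability driven by the rare-allele
burden, and WHO BMI categories whose odds respond to the 3'UTR common variant
in EA subjects only.

Case/control quotas are met by rejection resampling: phenotypes are drawn for
an oversized pool and the first ``n`` qualifying subjects per group are kept.
This is exact under the null and approximate (slightly shrinking covariate
effects) under strong effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort import (
    BmiClass,
    CohortStudy,
    GenotypeMatrix,
    MISSING,
    SubjectRecord,
    Sex,
    VariantSite,
    build_count_table,
    load_count_fixture,
)

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "pomc_study_preset",
]

_POPS = ("AA", "EA")


@dataclass(frozen=True)
class EffectSpec:
    """Effect sizes and baseline covariate model for the liability draws."""

    burden_or_sd: float = 1.0  # odds of SD per rare minor allele carried
    common_or_bmi: float = 1.0  # odds of overweight/obese per minor allele (EA)
    sd_intercept: float = 0.2
    beta_sex_male: float = 0.2
    beta_age_decade: float = 0.1
    beta_ancestry: float = 0.3
    bmi_high_intercept: float = 0.95  # baseline logit of overweight+obese
    p_underweight: float = 0.005
    p_obese_given_high: float = 0.46

    def __post_init__(self) -> None:
        if self.burden_or_sd <= 0 or self.common_or_bmi <= 0:
            raise ValueError("odds ratios must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    n_aa_case: int
    n_aa_ctrl: int
    n_ea_case: int
    n_ea_ctrl: int
    sites: tuple[VariantSite, ...]
    segment_of_site: tuple[int, ...]  # amplicon segment index per site
    common_site_ids: tuple[str, str]
    #: per-population minor-allele frequencies of the two common sites
    common_maf: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"AA": (0.28, 0.14), "EA": (0.05, 0.21)}
    )
    #: signed D' between the two common sites: positive couples the two minor
    #: alleles, negative puts them in repulsion (minor with major).  Repulsion
    #: at high |D'| yields the tight-LD / low-r2 pattern typical of a rare
    #: allele arising on a common background.
    common_d_prime: float = -0.9
    #: per-population allele frequencies of the rare sites, fixture order
    rare_freqs: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    #: amplicon dropout: group_id -> per-segment missing probability
    exon_dropout: Mapping[str, tuple[float, ...]] | float = 0.0
    effects: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0
    bmi_common_site: int = 1  # index into common_site_ids driving BMI odds

    def __post_init__(self) -> None:
        for n in (self.n_aa_case, self.n_aa_ctrl, self.n_ea_case, self.n_ea_ctrl):
            if n < 0:
                raise ValueError("group sizes must be non-negative")
        if len(self.segment_of_site) != len(self.sites):
            raise ValueError("segment_of_site must align with sites")
        for pop in _POPS:
            p1, p2 = self.common_maf[pop]
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise ValueError("common MAFs must lie in [0, 1]")
            for f in self.rare_freqs.get(pop, ()):
                if not 0 <= f <= 1:
                    raise ValueError("rare frequencies must lie in [0, 1]")
        if not -1 <= self.common_d_prime <= 1:
            raise ValueError("D' must lie in [-1, 1]")
        if isinstance(self.exon_dropout, (int, float)):
            if not 0 <= float(self.exon_dropout) < 1:
                raise ValueError("dropout must lie in [0, 1)")
        else:
            for probs in self.exon_dropout.values():
                if any(not 0 <= q < 1 for q in probs):
                    raise ValueError("dropout must lie in [0, 1)")

    @property
    def rare_site_ids(self) -> tuple[str, ...]:
        return tuple(
            s.site_id for s in self.sites if s.site_id not in self.common_site_ids
        )

    @property
    def n_segments(self) -> int:
        return max(self.segment_of_site) + 1

    def group_sizes(self) -> dict[str, int]:
        return {
            "AA_case": self.n_aa_case,
            "AA_ctrl": self.n_aa_ctrl,
            "EA_case": self.n_ea_case,
            "EA_ctrl": self.n_ea_ctrl,
        }


def _haplotype_freqs(p1: float, p2: float, d_prime: float) -> np.ndarray:
    """Four haplotype freqs (mm, mM, Mm, MM on minor/major coding) at the
    requested signed D' (positive = minor alleles in coupling)."""
    if d_prime >= 0:
        d = d_prime * min(p1 * (1 - p2), (1 - p1) * p2)
    else:
        d = d_prime * min(p1 * p2, (1 - p1) * (1 - p2))
    f = np.array(
        [
            p1 * p2 + d,  # minor-minor
            p1 * (1 - p2) - d,  # minor-major
            (1 - p1) * p2 - d,  # major-minor
            (1 - p1) * (1 - p2) + d,  # major-major
        ]
    )
    if (f < -1e-12).any():
        raise ValueError("infeasible haplotype table for the requested D'")
    return np.clip(f, 0.0, None) / f.sum()


def _draw_common_dosages(
    n: int, p1: float, p2: float, d_prime: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two dosage vectors from random union of two-locus haplotypes."""
    f = _haplotype_freqs(p1, p2, d_prime)
    haps = rng.choice(4, size=(n, 2), p=f)
    carries1 = np.isin(haps, (0, 1))  # minor at locus 1
    carries2 = np.isin(haps, (0, 2))  # minor at locus 2
    return carries1.sum(axis=1), carries2.sum(axis=1)


def simulate_genotypes(
    config: SimulationConfig,
    population: str,
    n_subjects: int,
    rng: np.random.Generator,
    apply_dropout: bool = True,
) -> np.ndarray:
    """Raw dosage matrix (n_subjects x n_sites) for one population.

    Common sites come from two-locus haplotypes under HWE at the configured
    MAFs; rare sites are independent binomial(2, f) draws so heterozygous
    carriers appear at roughly 2f and homozygotes at f^2.  When the configured
    dropout is population-level (a scalar or a per-segment vector rather than
    per-group), a dropped segment sets every call in it to MISSING here;
    per-group dropout is applied later, once group membership exists.
    """
    n_sites = len(config.sites)
    calls = np.zeros((n_subjects, n_sites), dtype=np.int16)
    site_index = {s.site_id: j for j, s in enumerate(config.sites)}
    j1 = site_index[config.common_site_ids[0]]
    j2 = site_index[config.common_site_ids[1]]
    p1, p2 = config.common_maf[population]
    d1, d2 = _draw_common_dosages(n_subjects, p1, p2, config.common_d_prime, rng)
    calls[:, j1] = d1
    calls[:, j2] = d2
    rare_ids = config.rare_site_ids
    freqs = np.asarray(
        config.rare_freqs.get(population, np.zeros(len(rare_ids))), dtype=float
    )
    if freqs.size != len(rare_ids):
        raise ValueError("rare_freqs must align with the rare sites")
    for k, sid in enumerate(rare_ids):
        calls[:, site_index[sid]] = rng.binomial(2, freqs[k], size=n_subjects)
    if apply_dropout and isinstance(config.exon_dropout, (int, float)):
        q = float(config.exon_dropout)
        if q > 0:
            _apply_dropout(calls, config, np.full(config.n_segments, q), rng)
    return calls


def _apply_dropout(
    calls: np.ndarray,
    config: SimulationConfig,
    seg_probs: Sequence[float],
    rng: np.random.Generator,
) -> None:
    seg = np.asarray(config.segment_of_site)
    for s in range(config.n_segments):
        q = float(seg_probs[s]) if s < len(seg_probs) else 0.0
        if q <= 0:
            continue
        dropped = rng.random(calls.shape[0]) < q
        cols = np.flatnonzero(seg == s)
        calls[np.ix_(dropped, cols)] = MISSING


def simulate_phenotypes(
    calls: np.ndarray,
    config: SimulationConfig,
    population: str,
    rng: np.random.Generator,
    id_prefix: str = "S",
) -> list[SubjectRecord]:
    """Draw phenotypes for a pool of genotyped subjects of one population.

    SD status follows logit(P) = b0 + ln(OR_burden) * (rare alleles carried)
    + covariates; BMI category odds (overweight+obese vs normal) follow
    ln(OR_bmi) per minor allele at the configured common site, in EA subjects
    only, with BMI values drawn from truncated normals per category.
    """
    from scipy.stats import truncnorm

    eff = config.effects
    n = calls.shape[0]
    site_index = {s.site_id: j for j, s in enumerate(config.sites)}
    rare_cols = [site_index[sid] for sid in config.rare_site_ids]
    rare_calls = calls[:, rare_cols].astype(float)
    rare_count = np.where(rare_calls == MISSING, 0, rare_calls).sum(axis=1)
    j_bmi = site_index[config.common_site_ids[config.bmi_common_site]]
    bmi_dosage = np.maximum(calls[:, j_bmi], 0).astype(float)

    male = rng.random(n) < 0.6
    age = np.clip(rng.normal(40.0, 10.0, size=n), 18.0, 90.0)
    if population == "AA":
        ancestry = 0.5 + 0.5 * rng.beta(5.0, 2.0, size=n)
    else:
        ancestry = 0.5 * rng.beta(2.0, 5.0, size=n)
        ancestry = np.minimum(ancestry, 0.4999)

    logit_sd = (
        eff.sd_intercept
        + np.log(eff.burden_or_sd) * rare_count
        + eff.beta_sex_male * male
        + eff.beta_age_decade * (age - 40.0) / 10.0
        + eff.beta_ancestry * (ancestry - 0.5)
    )
    sd = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_sd))

    logit_high = eff.bmi_high_intercept + (
        np.log(eff.common_or_bmi) * bmi_dosage if population == "EA" else 0.0
    )
    p_high = 1.0 / (1.0 + np.exp(-logit_high))
    u = rng.random(n)
    under = u < eff.p_underweight
    high = ~under & (rng.random(n) < p_high)
    obese = high & (rng.random(n) < eff.p_obese_given_high)

    bmi = np.empty(n)
    _fill_truncnorm(bmi, under, 18.4, 0.1, 14.0, 18.5 - 1e-6, rng, truncnorm)
    _fill_truncnorm(bmi, ~under & ~high, 22.4, 1.6, 18.5, 25.0 - 1e-6, rng, truncnorm)
    _fill_truncnorm(bmi, high & ~obese, 27.1, 1.4, 25.0, 30.0 - 1e-6, rng, truncnorm)
    _fill_truncnorm(bmi, obese, 35.5, 5.1, 30.0, 70.0, rng, truncnorm)

    records = []
    for i in range(n):
        flags = {"ad": False, "cd": False, "od": False, "mjd": False}
        if sd[i]:
            # at least one specific dependence; marginal rates echo the cohort
            probs = {"ad": 0.8, "cd": 0.7, "od": 0.25, "mjd": 0.4}
            while not any(flags.values()):
                flags = {k: bool(rng.random() < p) for k, p in probs.items()}
        records.append(
            SubjectRecord(
                subject_id=f"{id_prefix}{i:05d}",
                sex=Sex.M if male[i] else Sex.F,
                age=float(age[i]),
                ancestry_prop=float(ancestry[i]),
                ad=flags["ad"],
                cd=flags["cd"],
                od=flags["od"],
                mjd=flags["mjd"],
                screened_control=not bool(sd[i]),
                bmi=float(bmi[i]),
            )
        )
    return records


def _fill_truncnorm(out, mask, mu, sigma, lo, hi, rng, truncnorm) -> None:
    k = int(mask.sum())
    if k == 0:
        return
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    out[mask] = truncnorm.rvs(a, b, loc=mu, scale=sigma, size=k, random_state=rng)


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> CohortStudy:
    """Generate a full subject-level study meeting the configured group sizes.

    For each population an oversized pool is genotyped and phenotyped; the
    first ``n`` cases and controls fill the quotas (rejection resampling),
    regenerating with a larger pool when a draw falls short.  Per-group
    amplicon dropout is applied after selection.  Deterministic under seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.group_sizes()
    per_group_dropout = not isinstance(config.exon_dropout, (int, float))
    all_subjects: list[SubjectRecord] = []
    all_calls: list[np.ndarray] = []
    for pop in _POPS:
        want_case = sizes[f"{pop}_case"]
        want_ctrl = sizes[f"{pop}_ctrl"]
        if want_case + want_ctrl == 0:
            continue
        got: dict[bool, list[int]] = {True: [], False: []}
        pool_calls: np.ndarray | None = None
        pool_records: list[SubjectRecord] = []
        factor = 3
        for attempt in range(8):
            n_pool = factor * (want_case + want_ctrl) + 50
            calls = simulate_genotypes(
                config, pop, n_pool, rng, apply_dropout=not per_group_dropout
            )
            records = simulate_phenotypes(
                calls, config, pop, rng, id_prefix=f"{pop}{attempt}_"
            )
            base = len(pool_records)
            if pool_calls is None:
                pool_calls = calls
            else:
                pool_calls = np.vstack([pool_calls, calls])
            pool_records.extend(records)
            for i in range(base, len(pool_records)):
                got[pool_records[i].sd_case].append(i)
            if len(got[True]) >= want_case and len(got[False]) >= want_ctrl:
                break
            factor *= 2
        else:
            raise ValueError(
                f"unattainable group counts for {pop}: drew {len(got[True])} cases "
                f"and {len(got[False])} controls; check the effect specification"
            )
        chosen = got[True][:want_case] + got[False][:want_ctrl]
        sel_calls = pool_calls[np.array(chosen, dtype=int)]
        sel_records = [pool_records[i] for i in chosen]
        if per_group_dropout:
            case_rows = np.arange(want_case)
            ctrl_rows = np.arange(want_case, want_case + want_ctrl)
            for rows, gid in ((case_rows, f"{pop}_case"), (ctrl_rows, f"{pop}_ctrl")):
                probs = config.exon_dropout.get(gid)
                if probs and len(rows):
                    sub = sel_calls[rows]
                    _apply_dropout(sub, config, probs, rng)
                    sel_calls[rows] = sub
        all_subjects.extend(sel_records)
        all_calls.append(sel_calls)
    if not all_subjects:
        raise ValueError("empty cohort requested")
    calls = np.vstack(all_calls)
    # re-key subject ids to be globally unique and stable
    subjects = [
        replace(s, subject_id=f"SUBJ{i:05d}") for i, s in enumerate(all_subjects)
    ]
    genotypes = GenotypeMatrix(list(config.sites), subjects, calls)
    return build_count_table(genotypes)


def pomc_study_preset(seed: int = 0, effects: EffectSpec | None = None) -> SimulationConfig:
    """The POMC exon-resequencing study conditions as a simulation config.

    Group sizes 167/113 (AA case/ctrl) and 144/164 (EA); common-site MAFs from
    the published control frequencies (9-bp insertion 0.284 AA / 0.048 EA;
    3'UTR T allele 0.140 AA / 0.210 EA); rare-site frequencies pooled from the
    packaged count table per population; per-group amplicon dropout set so the
    expected per-variant chromosome denominators reproduce the published ones.
    Default effects: rare-burden OR 3.3 on SD (the allele-level enrichment the
    published collapsed AA counts imply) and OR 2.0 of overweight/obese per
    3'UTR minor allele in EAs.
    """
    study = load_count_fixture()
    sites = tuple(study.sites)
    common_ids = ("c.560_561insAGCAGCGGC", "c.1130C>T")
    # amplicon segments, identified by the blocks of equal denominators
    seg_of: list[int] = []
    seen: dict[tuple[int, ...], int] = {}
    for s in sites:
        key = tuple(study.count_table[s.site_id][g].n_total for g in
                    ("AA_case", "AA_ctrl", "EA_case", "EA_ctrl"))
        if key not in seen:
            seen[key] = len(seen)
        seg_of.append(seen[key])
    sizes = {"AA_case": 167, "AA_ctrl": 113, "EA_case": 144, "EA_ctrl": 164}
    dropout: dict[str, tuple[float, ...]] = {}
    n_seg = len(seen)
    for gid, n_subj in sizes.items():
        probs = [0.0] * n_seg
        for key, s_idx in seen.items():
            g_idx = ("AA_case", "AA_ctrl", "EA_case", "EA_ctrl").index(gid)
            probs[s_idx] = max(0.0, 1.0 - key[g_idx] / (2 * n_subj))
        dropout[gid] = tuple(probs)
    rare_freqs: dict[str, tuple[float, ...]] = {}
    for pop in _POPS:
        fs = []
        for s in sites:
            if s.site_id in common_ids:
                continue
            case = study.count_table[s.site_id][f"{pop}_case"]
            ctrl = study.count_table[s.site_id][f"{pop}_ctrl"]
            fs.append((case.n_minor + ctrl.n_minor) / (case.n_total + ctrl.n_total))
        rare_freqs[pop] = tuple(fs)
    return SimulationConfig(
        n_aa_case=167,
        n_aa_ctrl=113,
        n_ea_case=144,
        n_ea_ctrl=164,
        sites=sites,
        segment_of_site=tuple(seg_of),
        common_site_ids=common_ids,
        common_maf={"AA": (0.284, 0.140), "EA": (0.048, 0.210)},
        common_d_prime=-0.9,
        rare_freqs=rare_freqs,
        exon_dropout=dropout,
        effects=effects or EffectSpec(burden_or_sd=3.3, common_or_bmi=2.0),
        seed=seed,
    )
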