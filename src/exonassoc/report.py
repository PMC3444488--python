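"""Pipeline orchestration and plain-text report rendering.

``run_pipeline`` drives the full analysis — cohort load or synthesis, the
per-variant count table, common-variant association, two-marker haplotype
analysis, the rare-variant collapsing burden test, and the retrospective
power summary — writing deterministic TSV mirrors of the study's tables plus
a provenance log.  Count-only inputs run the stages that counts support and
record an explicit notice for the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as burden_mod
from .cohort import (
    CohortStudy,
    GROUP_IDS,
    Population,
    Provenance,
    load_count_fixture,
    load_count_table,
    load_genotypes,
    load_phenotypes,
    build_count_table,
    pooled_group_count,
    write_count_table,
)
from .common import BmiContrast, ConvergenceFailure, run_bmi_contrasts, run_sd_assoc
from .haplotype import haplotype_assoc, ld_stats
from .power import PowerSpec, min_detectable_or
from .simulate import pomc_study_preset, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "render_report", "fmt_p", "fmt_freq"]

_TRAITS = ("sd", "ad", "cd", "od", "mjd")


def fmt_p(p: float) -> str:
    """p to 3 decimals, scientific below 0.001."""
    if p < 0.001:
        return f"{p:.2e}"
    return f"{p:.3f}"


def fmt_freq(x: float) -> str:
    return f"{x:.3f}"


@dataclass
class PipelineConfig:
    out_dir: str | Path
    counts_path: str | Path | None = None  # count-only input
    phenotypes_path: str | Path | None = None  # subject-level input ...
    vcf_path: str | Path | None = None  # ... both required together
    use_preset: bool = False  # synthesize the packaged study conditions
    seed: int = 17
    n_perm: int = 10_000
    maf_threshold: float = burden_mod.DEFAULT_MAF_THRESHOLD
    alpha: float = 0.05
    bonferroni_k: int = 5
    contrasts: tuple[str, ...] = _TRAITS

    def __post_init__(self) -> None:
        chosen = sum(
            [
                self.counts_path is not None,
                self.phenotypes_path is not None or self.vcf_path is not None,
                self.use_preset,
            ]
        )
        if chosen == 0:
            self.counts_path = "fixture:pomc_exon_counts"
        if (self.phenotypes_path is None) != (self.vcf_path is None):
            raise ValueError("phenotypes and VCF must be given together")


def _load_study(config: PipelineConfig, log: list[str]) -> CohortStudy:
    if config.use_preset:
        log.append(f"stage load: synthesizing preset cohort, seed={config.seed}")
        return simulate_cohort(pomc_study_preset(seed=config.seed))
    if config.phenotypes_path is not None:
        log.append(
            f"stage load: subject-level input {config.phenotypes_path} + {config.vcf_path}"
        )
        subjects = load_phenotypes(config.phenotypes_path)
        genotypes = load_genotypes(config.vcf_path, subjects)
        return build_count_table(genotypes)
    path = str(config.counts_path)
    if path.startswith("fixture:"):
        log.append(f"stage load: packaged count fixture {path.split(':', 1)[1]}")
        return load_count_fixture(path.split(":", 1)[1])
    log.append(f"stage load: count table {path}")
    return load_count_table(path)


def render_report(study: CohortStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the per-variant count table mirror (n/N cells, 3-decimal MAFs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    df = study.count_frame()
    display = pd.DataFrame(
        {
            "site_id": df["site_id"],
            "exon": df["exon"],
            "region": df["region"],
            "dbsnp": df["dbsnp"],
            "aa_case": [
                f"{n}/{N}" for n, N in zip(df["aa_case_n"], df["aa_case_N"])
            ],
            "ea_case": [
                f"{n}/{N}" for n, N in zip(df["ea_case_n"], df["ea_case_N"])
            ],
            "maf_case": df["maf_case"].map(fmt_freq),
            "aa_ctrl": [
                f"{n}/{N}" for n, N in zip(df["aa_ctrl_n"], df["aa_ctrl_N"])
            ],
            "ea_ctrl": [
                f"{n}/{N}" for n, N in zip(df["ea_ctrl_n"], df["ea_ctrl_N"])
            ],
            "maf_ctrl": df["maf_ctrl"].map(fmt_freq),
        }
    )
    paths["variants_display"] = out_dir / "variant_counts_display.tsv"
    display.to_csv(paths["variants_display"], sep="\t", index=False)
    paths["variants"] = out_dir / "variant_counts.tsv"
    write_count_table(study, paths["variants"])
    return paths


def _burden_stage(
    study: CohortStudy, config: PipelineConfig, out_dir: Path, log: list[str]
) -> Path:
    panel = burden_mod.classify_rare(study, config.maf_threshold)
    log.append(
        f"stage burden: panel of {len(panel)} rare sites "
        f"(threshold {config.maf_threshold}): {', '.join(panel.site_ids)}"
    )
    subject_level = study.provenance is Provenance.SUBJECT_LEVEL
    rows = []
    pops: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
        "AA": (("AA_case",), ("AA_ctrl",)),
        "EA": (("EA_case",), ("EA_ctrl",)),
        "AA+EA": (("AA_case", "EA_case"), ("AA_ctrl", "EA_ctrl")),
    }

    def group_map(gids: tuple[str, ...], label: str):
        return {
            sid: pooled_group_count(
                [study.count_table[sid][g] for g in gids], label
            )
            for sid in panel.site_ids
        }

    from .cohort import count_alleles

    def trait_group_map(trait: str, pop: str | None, label: str):
        g = study.genotypes
        mask = []
        for s in g.subjects:
            ok = not s.excluded
            if pop is not None and s.population.value != pop:
                ok = False
            if trait == "ctrl":
                ok = ok and s.screened_control
            elif trait == "sd":
                ok = ok and s.sd_case
            else:
                ok = ok and getattr(s, trait)
            mask.append(ok)
        mask = np.array(mask, dtype=bool)
        return {
            sid: count_alleles(g, sid, mask, label) for sid in panel.site_ids
        }

    p_values_by_pop: dict[str, list[float]] = {k: [] for k in pops}
    for pop_label, (case_gids, ctrl_gids) in pops.items():
        pop = None if pop_label == "AA+EA" else pop_label
        traits = config.contrasts if subject_level else ("sd",)
        for trait in traits:
            if subject_level:
                ga = trait_group_map(trait, pop, f"{pop_label}_{trait}_case")
                gb = trait_group_map("ctrl", pop, f"{pop_label}_ctrl")
            else:
                ga = group_map(case_gids, f"{pop_label}_{trait}_case")
                gb = group_map(ctrl_gids, f"{pop_label}_ctrl")
            try:
                res = burden_mod.burden_test(
                    panel, ga, gb, f"{pop_label}_{trait}_case", f"{pop_label}_ctrl"
                )
            except ValueError as exc:
                log.append(f"stage burden: {pop_label}/{trait} untestable: {exc}")
                continue
            p_values_by_pop[pop_label].append(res.p_fet)
            rows.append(
                {
                    "population": pop_label,
                    "contrast": f"{trait.upper()} cases vs. Controls",
                    "counts": f"{res.group_a.adj_minor}/{res.group_a.adj_total}, "
                    f"{res.group_b.adj_minor}/{res.group_b.adj_total}",
                    "raw_counts": f"{res.group_a.raw_minor}/{res.group_a.raw_total}, "
                    f"{res.group_b.raw_minor}/{res.group_b.raw_total}",
                    "p_fet_1df": fmt_p(res.p_fet),
                    "p_fet_raw": fmt_p(res.p_fet_raw),
                }
            )
        if not subject_level and len(config.contrasts) > 1:
            log.append(
                f"stage burden: {pop_label}: per-trait contrasts "
                f"{[t for t in config.contrasts if t != 'sd']} skipped "
                "(count-only input has no per-trait counts)"
            )
    # Bonferroni across the trait contrasts within each sample set
    adj_lookup: dict[str, list[dict]] = {
        pop: burden_mod.bonferroni_adjust(
            ps, k=config.bonferroni_k, alpha=config.alpha
        )
        for pop, ps in p_values_by_pop.items()
    }
    seen: dict[str, int] = {k: 0 for k in pops}
    for row in rows:
        pop = row["population"]
        adj = adj_lookup[pop][seen[pop]]
        seen[pop] += 1
        row["significant_bonferroni"] = str(bool(adj["significant"]))
    out = out_dir / "burden.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def _common_stage(
    study: CohortStudy, config: PipelineConfig, out_dir: Path, log: list[str]
) -> Path | None:
    if study.provenance is not Provenance.SUBJECT_LEVEL:
        log.append(
            "stage common-assoc: skipped (requires subject-level data; "
            "count-only input)"
        )
        return None
    common_ids = [
        s.site_id
        for s in study.sites
        if s.site_id in ("c.560_561insAGCAGCGGC", "c.1130C>T")
    ] or [s.site_id for s in study.sites[:2]]
    rows = []
    rng = np.random.default_rng(config.seed + 1)
    for site_id in common_ids:
        for pop in (Population.AA, Population.EA, None):
            pop_label = pop.value if pop else "AA+EA"
            for contrast in BmiContrast:
                try:
                    allelic, logistic = run_bmi_contrasts(
                        study,
                        site_id,
                        contrast,
                        population=pop,
                        n_perm=config.n_perm,
                        seed=rng,
                    )
                except (ValueError, ConvergenceFailure) as exc:
                    log.append(
                        f"stage common-assoc: {site_id}/{pop_label}/"
                        f"{contrast.value}: untestable ({exc})"
                    )
                    continue
                rows.append(
                    {
                        "site": site_id,
                        "population": pop_label,
                        "comparison": contrast.value + " vs. normal",
                        "freq": f"{allelic.freq_conditioned:.3f}/"
                        f"{allelic.freq_comparison:.3f}",
                        "chi2": f"{allelic.chi2:.2f}",
                        "p_obs": fmt_p(allelic.p_obs),
                        "or": f"{allelic.or_:.2f}",
                        "ci95": f"({allelic.ci95[0]:.2f}-{allelic.ci95[1]:.2f})",
                        "p_emp": fmt_p(allelic.p_emp),
                        "stat": f"{logistic.stat:.2f}",
                        "p_adj": fmt_p(logistic.p_adj),
                        "or_adj": f"{logistic.or_adj:.2f}",
                    }
                )
    out = out_dir / "common_assoc.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def _haplotype_stage(
    study: CohortStudy, config: PipelineConfig, out_dir: Path, log: list[str]
) -> Path | None:
    if study.provenance is not Provenance.SUBJECT_LEVEL:
        log.append("stage haplotype: skipped (requires subject-level data)")
        return None
    site1, site2 = "c.560_561insAGCAGCGGC", "c.1130C>T"
    if not {site1, site2} <= {s.site_id for s in study.sites}:
        log.append("stage haplotype: skipped (standard common-site pair absent)")
        return None
    rows = []
    rng = np.random.default_rng(config.seed + 2)
    for pop in (Population.AA, Population.EA):
        try:
            table, results = haplotype_assoc(
                study,
                site1,
                site2,
                BmiContrast.OVERWEIGHT_OBESE_VS_NORMAL,
                population=pop,
                n_perm=config.n_perm,
                seed=rng,
            )
        except (ValueError, RuntimeError) as exc:
            log.append(f"stage haplotype: {pop.value}: untestable ({exc})")
            continue
        ld = ld_stats(table)
        log.append(
            f"stage haplotype: {pop.value}: D'={ld.d_prime:.2f} r2={ld.r2:.2f} "
            f"(EM {table.n_iter} iters)"
        )
        for r in results:
            rows.append(
                {
                    "population": pop.value,
                    "haplotype": r.haplotype,
                    "freq": f"{r.freq_conditioned:.3f}/{r.freq_comparison:.3f}",
                    "chi2": f"{r.chi2:.2f}",
                    "p_obs": fmt_p(r.p_obs),
                    "p_emp": fmt_p(r.p_emp) if r.p_emp is not None else ".",
                    "reliable": str(r.reliable),
                }
            )
    out = out_dir / "haplotype_assoc.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def _power_stage(config: PipelineConfig, out_dir: Path, log: list[str]) -> Path:
    scenarios = [
        ("c.560_561insAGCAGCGGC", "AA", 0.284, 167, 113),
        ("c.560_561insAGCAGCGGC", "EA", 0.048, 144, 164),
        ("c.1130C>T", "AA", 0.140, 167, 113),
        ("c.1130C>T", "EA", 0.210, 144, 164),
    ]
    rows = []
    for site, pop, p0, n_case, n_ctrl in scenarios:
        spec = PowerSpec(p0=p0, n_case=n_case, n_ctrl=n_ctrl, alpha=config.alpha)
        rows.append(
            {
                "site": site,
                "population": pop,
                "control_maf": f"{p0:.3f}",
                "n_case": n_case,
                "n_ctrl": n_ctrl,
                "min_detectable_or": f"{min_detectable_or(spec):.2f}",
            }
        )
    out = out_dir / "power.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    log.append("stage power: retrospective minimum detectable OR at 80% power")
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage the input supports; returns paths of the outputs.

    All randomness flows from ``config.seed``; rerunning with the same config
    produces byte-identical files.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {config.seed}", f"n_perm: {config.n_perm}"]
    paths: dict[str, Path] = {}
    stage = "load"
    try:
        study = _load_study(config, log)
        stage = "variant-table"
        paths.update(render_report(study, out_dir))
        stage = "common-assoc"
        p = _common_stage(study, config, out_dir, log)
        if p:
            paths["common_assoc"] = p
        stage = "haplotype"
        p = _haplotype_stage(study, config, out_dir, log)
        if p:
            paths["haplotype"] = p
        stage = "burden"
        paths["burden"] = _burden_stage(study, config, out_dir, log)
        stage = "power"
        paths["power"] = _power_stage(config, out_dir, log)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    paths["log"] = out_dir / "pipeline_log.txt"
    paths["log"].write_text("\n".join(log) + "\n")
    return paths
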