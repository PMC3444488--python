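"""Domain model for a candidate-gene exon resequencing case-control study.

The study design this package targets is a four-exon candidate gene (POMC)
Sanger-sequenced in two ancestry groups, African American (AA) and European
American (EA), each split into substance-dependence (SD) cases and screened
controls.  Because each amplicon has its own PCR success rate, the number of
successfully sequenced chromosomes differs variant by variant; every allele
count is therefore carried as an ``n/N`` pair (minor-allele count over total
chromosomes) rather than assuming a constant denominator.

Two representations of a study coexist:

* subject level — a :class:`GenotypeMatrix` (per-subject minor-allele dosages)
  plus :class:`SubjectRecord` phenotypes, from which any group's counts can be
  recomputed; and
* count only — a per-variant, per-group table of ``n/N`` pairs, in the form
  journal variant tables print.  The packaged fixture ``pomc_exon_counts``
  is such a table for the 23 POMC exonic variants.
"""

from __future__ import annotations

import enum
import importlib.resources
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "Population",
    "Sex",
    "BmiClass",
    "Provenance",
    "MISSING",
    "GROUP_IDS",
    "COHORT_SIZES",
    "VariantSite",
    "GroupCount",
    "SubjectRecord",
    "GenotypeMatrix",
    "CohortStudy",
    "assign_population",
    "classify_bmi",
    "derive_sd_status",
    "count_alleles",
    "compute_maf",
    "pooled_group_count",
    "build_count_table",
    "load_phenotypes",
    "write_phenotypes",
    "load_genotypes",
    "write_vcf",
    "load_count_fixture",
    "write_count_table",
    "load_count_table",
]

#: Dosage code for a failed / unsequenced call.
MISSING = -1

#: The four standard analysis groups (population x SD status).
GROUP_IDS = ("AA_case", "AA_ctrl", "EA_case", "EA_ctrl")

#: Published cohort sizes (subjects).  The source abstract prints 114 EA cases
#: but its own totals (311 cases, 308 EAs) and the per-variant chromosome
#: denominators (up to 282 > 2*114) require 144; 144 is used throughout and
#: the alternative figure is recorded here for transparency.
COHORT_SIZES = {
    "AA_case": 167,
    "AA_ctrl": 113,
    "EA_case": 144,
    "EA_ctrl": 164,
    "EA_case_abstract_variant": 114,
}


class Region(enum.Enum):
    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    THREE_UTR = "THREE_UTR"


class Population(enum.Enum):
    AA = "AA"
    EA = "EA"


class Sex(enum.Enum):
    M = "M"
    F = "F"


class BmiClass(enum.Enum):
    UNDERWEIGHT = "UNDERWEIGHT"
    NORMAL = "NORMAL"
    OVERWEIGHT = "OVERWEIGHT"
    OBESE = "OBESE"


class Provenance(enum.Enum):
    SUBJECT_LEVEL = "SUBJECT_LEVEL"
    COUNT_ONLY = "COUNT_ONLY"


@dataclass(frozen=True)
class VariantSite:
    """One exonic variant.  ``novel`` means absent from dbSNP at study time."""

    site_id: str
    exon: int
    region: Region
    dbsnp_id: str | None = None
    effect_label: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.exon <= 4:
            raise ValueError(f"{self.site_id}: exon must be 1-4, got {self.exon}")

    @property
    def novel(self) -> bool:
        return self.dbsnp_id is None


@dataclass(frozen=True)
class GroupCount:
    """Minor-allele count ``n_minor`` over ``n_total`` sequenced chromosomes."""

    group_id: str
    n_minor: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_minor < 0 or self.n_total < 0:
            raise ValueError("allele counts must be non-negative")
        if self.n_minor > self.n_total:
            raise ValueError(
                f"{self.group_id}: n_minor={self.n_minor} exceeds n_total={self.n_total}"
            )

    @property
    def freq(self) -> float:
        """Minor-allele frequency p_i = n_minor / n_total (nan when N=0)."""
        if self.n_total == 0:
            return float("nan")
        return self.n_minor / self.n_total

    @property
    def degenerate(self) -> bool:
        return self.n_total == 0


@dataclass
class SubjectRecord:
    subject_id: str
    sex: Sex
    age: float
    ancestry_prop: float
    ad: bool
    cd: bool
    od: bool
    mjd: bool
    screened_control: bool
    bmi: float
    # derived
    population: Population = field(init=False)
    sd_case: bool = field(init=False)
    bmi_class: BmiClass = field(init=False)

    def __post_init__(self) -> None:
        self.population = assign_population(self.ancestry_prop)
        self.bmi_class = classify_bmi(self.bmi)
        self.sd_case = self.ad or self.cd or self.od or self.mjd
        if self.sd_case and self.screened_control:
            raise ValueError(
                f"{self.subject_id}: subject labelled both SD case and screened control"
            )

    @property
    def excluded(self) -> bool:
        """Neither a case nor a screened control: outside case-control contrasts."""
        return not self.sd_case and not self.screened_control

    @property
    def group_id(self) -> str | None:
        if self.excluded:
            return None
        return f"{self.population.value}_{'case' if self.sd_case else 'ctrl'}"


def assign_population(ancestry_prop: float) -> Population:
    """African-ancestry proportion >= 0.50 -> AA, otherwise EA."""
    if ancestry_prop is None or not np.isfinite(ancestry_prop):
        raise ValueError("ancestry proportion is missing or non-finite")
    if not 0.0 <= ancestry_prop <= 1.0:
        raise ValueError(f"ancestry proportion {ancestry_prop} outside [0, 1]")
    return Population.AA if ancestry_prop >= 0.50 else Population.EA


def classify_bmi(bmi: float) -> BmiClass:
    """WHO categories: <18.5, [18.5, 25), [25, 30), >=30 kg/m^2.

    The intervals are half-open; the conventional "24.9" / "29.9" upper bounds
    are display forms of the same cut points.
    """
    if bmi is None or not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi}")
    if bmi < 18.5:
        return BmiClass.UNDERWEIGHT
    if bmi < 25.0:
        return BmiClass.NORMAL
    if bmi < 30.0:
        return BmiClass.OVERWEIGHT
    return BmiClass.OBESE


def derive_sd_status(subject: SubjectRecord) -> SubjectRecord:
    """Return the subject with SD status refreshed from the four diagnosis flags.

    SD = alcohol, cocaine, opioid and/or marijuana dependence.  Subjects who
    are neither SD cases nor screened controls are retained but flagged
    ``excluded`` and take no part in case-control contrasts.
    """
    fresh = replace(
        subject,
        ad=subject.ad,
        cd=subject.cd,
        od=subject.od,
        mjd=subject.mjd,
    )
    return fresh


class GenotypeMatrix:
    """Per-subject minor-allele dosages (0/1/2; :data:`MISSING` for no call).

    For indel sites the dosage counts insertion alleles.
    """

    def __init__(
        self,
        sites: Sequence[VariantSite],
        subjects: Sequence[SubjectRecord],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int16)
        if calls.shape != (len(subjects), len(sites)):
            raise ValueError(
                f"calls shape {calls.shape} != (n_subjects={len(subjects)}, "
                f"n_sites={len(sites)})"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")
        self.sites = list(sites)
        self.subjects = list(subjects)
        self.calls = calls
        self._site_index = {s.site_id: j for j, s in enumerate(self.sites)}
        if len(self._site_index) != len(self.sites):
            raise ValueError("duplicate site ids")
        ids = {s.subject_id for s in self.subjects}
        if len(ids) != len(self.subjects):
            raise ValueError("duplicate subject ids")

    def site_index(self, site_id: str) -> int:
        try:
            return self._site_index[site_id]
        except KeyError:
            raise KeyError(f"unknown site {site_id!r}") from None

    def subset_subjects(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        subjects = [s for s, m in zip(self.subjects, mask) if m]
        return GenotypeMatrix(self.sites, subjects, self.calls[mask])


GroupPredicate = Callable[[SubjectRecord], bool]


def count_alleles(
    genotypes: GenotypeMatrix,
    site: VariantSite | str,
    group: GroupPredicate | np.ndarray,
    group_id: str = "group",
) -> GroupCount:
    """Count minor alleles at one site over the subjects a predicate selects.

    ``n_total`` is twice the number of selected subjects with a non-missing
    call (two chromosomes each); missing calls contribute to neither count.
    """
    site_id = site if isinstance(site, str) else site.site_id
    j = genotypes.site_index(site_id)
    if callable(group):
        mask = np.fromiter(
            (bool(group(s)) for s in genotypes.subjects),
            dtype=bool,
            count=len(genotypes.subjects),
        )
    else:
        mask = np.asarray(group, dtype=bool)
    col = genotypes.calls[mask, j]
    called = col != MISSING
    gc = GroupCount(group_id, int(col[called].sum()), int(2 * called.sum()))
    if gc.degenerate:
        warnings.warn(
            f"{site_id}/{group_id}: no successfully sequenced chromosomes",
            stacklevel=2,
        )
    return gc


def compute_maf(counts: Iterable[GroupCount]) -> float:
    """Pooled minor-allele frequency sum(n_minor)/sum(n_total) across groups."""
    counts = list(counts)
    n = sum(c.n_minor for c in counts)
    total = sum(c.n_total for c in counts)
    if total == 0:
        raise ValueError("zero total chromosomes; pooled MAF undefined")
    return n / total


def pooled_group_count(counts: Iterable[GroupCount], group_id: str) -> GroupCount:
    counts = list(counts)
    return GroupCount(
        group_id,
        sum(c.n_minor for c in counts),
        sum(c.n_total for c in counts),
    )


@dataclass
class CohortStudy:
    """A study either backed by subject-level genotypes or by counts alone.

    ``count_table`` maps site_id -> {group_id -> GroupCount}.  When provenance
    is SUBJECT_LEVEL the table is derived from (and reproducible from) the
    genotype matrix.
    """

    count_table: dict[str, dict[str, GroupCount]]
    sites: list[VariantSite]
    provenance: Provenance
    genotypes: GenotypeMatrix | None = None

    def __post_init__(self) -> None:
        if self.provenance is Provenance.SUBJECT_LEVEL and self.genotypes is None:
            raise ValueError("SUBJECT_LEVEL study requires genotypes")

    @property
    def subjects(self) -> list[SubjectRecord]:
        if self.genotypes is None:
            raise ValueError("count-only study has no subject-level data")
        return self.genotypes.subjects

    def site(self, site_id: str) -> VariantSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"unknown site {site_id!r}")

    def counts(self, site_id: str, group_id: str) -> GroupCount:
        return self.count_table[site_id][group_id]

    def count_frame(self) -> pd.DataFrame:
        """Flat table: one row per site with n/N per standard group and MAFs."""
        rows = []
        for s in self.sites:
            per_group = self.count_table[s.site_id]
            row: dict[str, object] = {
                "site_id": s.site_id,
                "exon": s.exon,
                "region": s.region.value,
                "dbsnp": s.dbsnp_id or ".",
                "effect": s.effect_label or ".",
            }
            for gid in GROUP_IDS:
                gc = per_group[gid]
                key = gid.lower().replace("_", "_")
                row[f"{key}_n"] = gc.n_minor
                row[f"{key}_N"] = gc.n_total
            case = [per_group["AA_case"], per_group["EA_case"]]
            ctrl = [per_group["AA_ctrl"], per_group["EA_ctrl"]]
            row["maf_case"] = compute_maf(case) if sum(c.n_total for c in case) else np.nan
            row["maf_ctrl"] = compute_maf(ctrl) if sum(c.n_total for c in ctrl) else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def build_count_table(genotypes: GenotypeMatrix) -> CohortStudy:
    """Derive the four standard population x SD-status group counts per site."""
    table: dict[str, dict[str, GroupCount]] = {}
    masks = {
        gid: np.fromiter(
            (s.group_id == gid for s in genotypes.subjects),
            dtype=bool,
            count=len(genotypes.subjects),
        )
        for gid in GROUP_IDS
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty groups are legal here
        for site in genotypes.sites:
            table[site.site_id] = {
                gid: count_alleles(genotypes, site, masks[gid], gid)
                for gid in GROUP_IDS
            }
    return CohortStudy(
        count_table=table,
        sites=list(genotypes.sites),
        provenance=Provenance.SUBJECT_LEVEL,
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_PHENO_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "ancestry_prop",
    "ad",
    "cd",
    "od",
    "mjd",
    "screened",
    "bmi",
]


def load_phenotypes(path: str | Path) -> list[SubjectRecord]:
    """Read the phenotype TSV (header per :data:`_PHENO_COLUMNS`; booleans 0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in _PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype table lacks columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty phenotype file", stacklevel=2)
        return []
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{path}: duplicate subject id {dup!r}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row.subject_id),
                    sex=Sex(str(row.sex)),
                    age=float(row.age),
                    ancestry_prop=float(row.ancestry_prop),
                    ad=bool(int(row.ad)),
                    cd=bool(int(row.cd)),
                    od=bool(int(row.od)),
                    mjd=bool(int(row.mjd)),
                    screened_control=bool(int(row.screened)),
                    bmi=float(row.bmi),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def write_phenotypes(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "sex": s.sex.value,
            "age": f"{s.age:.2f}",
            "ancestry_prop": f"{s.ancestry_prop:.4f}",
            "ad": int(s.ad),
            "cd": int(s.cd),
            "od": int(s.od),
            "mjd": int(s.mjd),
            "screened": int(s.screened_control),
            "bmi": f"{s.bmi:.2f}",
        }
        for s in subjects
    ]
    pd.DataFrame(rows, columns=_PHENO_COLUMNS).to_csv(path, sep="\t", index=False)


def load_genotypes(
    path: str | Path,
    subjects: Sequence[SubjectRecord],
    sites: Sequence[VariantSite] | None = None,
) -> GenotypeMatrix:
    """Read a VCF of biallelic records into a dosage matrix.

    Record IDs must carry the site ids; sample names must match the phenotype
    subjects exactly.  ALT-allele dosage is taken as the minor-allele dosage
    (for the 9-bp indel the insertion is the ALT and the minor allele).
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_names = list(vf.header.samples)
    ids = [s.subject_id for s in subjects]
    if sample_names != ids:
        raise ValueError(
            f"{path}: VCF samples do not match phenotype subjects "
            f"(first mismatch near index "
            f"{next((k for k, (a, b) in enumerate(zip(sample_names, ids)) if a != b), min(len(sample_names), len(ids)))})"
        )
    site_meta = {s.site_id: s for s in sites} if sites is not None else {}
    out_sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    for rec in vf:
        if rec.id is None:
            raise ValueError(f"{path}: record at {rec.chrom}:{rec.pos} lacks an ID")
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"{path}: {rec.id}: only biallelic records supported")
        meta = site_meta.get(rec.id)
        if meta is None:
            exon = int(rec.info.get("EXON", 1))
            region = Region(str(rec.info.get("REGION", "CDS")))
            dbsnp = rec.id if rec.id.startswith("rs") else None
            meta = VariantSite(rec.id, exon, region, dbsnp)
        out_sites.append(meta)
        row = np.full(len(sample_names), MISSING, dtype=np.int16)
        for k, name in enumerate(sample_names):
            gt = rec.samples[name].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            row[k] = sum(1 for a in gt if a == 1)
        rows.append(row)
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(subjects), 0), dtype=np.int16)
    )
    return GenotypeMatrix(out_sites, list(subjects), calls)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr2,length=243199373>
##INFO=<ID=EXON,Number=1,Type=Integer,Description="Exon number">
##INFO=<ID=REGION,Number=1,Type=String,Description="FIVE_UTR/CDS/THREE_UTR">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

#: Synthetic REF/ALT alleles per region kind; indels get explicit sequences.
_DEFAULT_ALLELES = ("A", "G")


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCF v4.2 (GT-only, './.' for missing)."""
    lines = [_VCF_HEADER.rstrip("\n")]
    names = [s.subject_id for s in genotypes.subjects]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names)
    )
    gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    for j, site in enumerate(genotypes.sites):
        pos = 25_383_722 + 100 * (j + 1)
        ref, alt = _DEFAULT_ALLELES
        if "ins" in site.site_id:
            inserted = site.site_id.split("ins")[-1]
            ref, alt = "A", "A" + inserted
        elif "del" in site.site_id:
            ref, alt = "AT", "A"
        info = f"EXON={site.exon};REGION={site.region.value}"
        cells = "\t".join(gt_str[int(d)] for d in genotypes.calls[:, j])
        lines.append(
            f"chr2\t{pos}\t{site.site_id}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{cells}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


_COUNT_COLUMNS = [
    "site_id",
    "exon",
    "region",
    "dbsnp",
    "aa_case_n",
    "aa_case_N",
    "ea_case_n",
    "ea_case_N",
    "aa_ctrl_n",
    "aa_ctrl_N",
    "ea_ctrl_n",
    "ea_ctrl_N",
]

_COL_TO_GROUP = {
    "aa_case": "AA_case",
    "ea_case": "EA_case",
    "aa_ctrl": "AA_ctrl",
    "ea_ctrl": "EA_ctrl",
}


def load_count_table(path: str | Path) -> CohortStudy:
    """Read a per-variant count TSV (see package data for the column layout)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: count table lacks columns {missing}")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValueError(f"{path}: duplicate site id {dup!r}")
    sites: list[VariantSite] = []
    table: dict[str, dict[str, GroupCount]] = {}
    for i, row in df.iterrows():
        dbsnp = None if str(row.dbsnp) in (".", "nan", "") else str(row.dbsnp)
        effect = None
        if "effect" in df.columns and str(row.effect) not in (".", "nan", ""):
            effect = str(row.effect)
        try:
            site = VariantSite(
                str(row.site_id), int(row.exon), Region(str(row.region)), dbsnp, effect
            )
            table[site.site_id] = {
                gid: GroupCount(gid, int(row[f"{col}_n"]), int(row[f"{col}_N"]))
                for col, gid in _COL_TO_GROUP.items()
            }
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
        sites.append(site)
    return CohortStudy(
        count_table=table, sites=sites, provenance=Provenance.COUNT_ONLY
    )


def write_count_table(study: CohortStudy, path: str | Path) -> None:
    rows = []
    for s in study.sites:
        per = study.count_table[s.site_id]
        row = {
            "site_id": s.site_id,
            "exon": s.exon,
            "region": s.region.value,
            "dbsnp": s.dbsnp_id or ".",
        }
        for col, gid in _COL_TO_GROUP.items():
            row[f"{col}_n"] = per[gid].n_minor
            row[f"{col}_N"] = per[gid].n_total
        row["effect"] = s.effect_label or "."
        rows.append(row)
    pd.DataFrame(rows, columns=_COUNT_COLUMNS + ["effect"]).to_csv(
        path, sep="\t", index=False
    )


def load_count_fixture(name: str = "pomc_exon_counts") -> CohortStudy:
    """Load a packaged count-only study (default: the 23-variant POMC table)."""
    resource = importlib.resources.files("exonassoc.data").joinpath(f"{name}.tsv")
    if not resource.is_file():
        raise FileNotFoundError(f"no packaged count fixture named {name!r}")
    with importlib.resources.as_file(resource) as p:
        return load_count_table(p)
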