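"""Domain types, phenotype derivation, allele counting, and file round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exonassoc.cohort import (
    BmiClass,
    GenotypeMatrix,
    GroupCount,
    MISSING,
    Population,
    Region,
    Sex,
    SubjectRecord,
    VariantSite,
    assign_population,
    build_count_table,
    classify_bmi,
    compute_maf,
    count_alleles,
    load_count_table,
    load_genotypes,
    load_phenotypes,
    write_count_table,
    write_phenotypes,
    write_vcf,
)
from conftest import brute_force_allele_count


# -- population assignment and BMI classes ----------------------------------


@pytest.mark.parametrize(
    "prop, expected",
    [(0.50, Population.AA), (0.49, Population.EA), (1.0, Population.AA), (0.0, Population.EA)],
)
def test_population_threshold(prop, expected):
    assert assign_population(prop) is expected


@pytest.mark.parametrize("bad", [-0.01, 1.01, float("nan"), None])
def test_population_rejects_invalid(bad):
    with pytest.raises(ValueError):
        assign_population(bad)


@pytest.mark.parametrize(
    "bmi, expected",
    [
        (18.4, BmiClass.UNDERWEIGHT),
        (18.5, BmiClass.NORMAL),
        (22.4, BmiClass.NORMAL),
        (24.999, BmiClass.NORMAL),
        (25.0, BmiClass.OVERWEIGHT),
        (27.1, BmiClass.OVERWEIGHT),
        (29.999, BmiClass.OVERWEIGHT),
        (30.0, BmiClass.OBESE),
        (35.5, BmiClass.OBESE),
    ],
)
def test_bmi_classes(bmi, expected):
    assert classify_bmi(bmi) is expected


@pytest.mark.parametrize("bad", [0.0, -3.0, float("nan")])
def test_bmi_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        classify_bmi(bad)


@given(st.floats(min_value=10.0, max_value=60.0), st.floats(min_value=10.0, max_value=60.0))
def test_bmi_classification_is_monotone(x, y):
    order = list(BmiClass)
    lo, hi = min(x, y), max(x, y)
    assert order.index(classify_bmi(lo)) <= order.index(classify_bmi(hi))


# -- subject records --------------------------------------------------------


def _subject(**kw):
    base = dict(
        subject_id="s1",
        sex=Sex.F,
        age=40.0,
        ancestry_prop=0.9,
        ad=False,
        cd=False,
        od=False,
        mjd=False,
        screened_control=False,
        bmi=24.0,
    )
    base.update(kw)
    return SubjectRecord(**base)


def test_sd_status_is_or_of_four_flags():
    assert _subject(ad=True).sd_case
    assert _subject(mjd=True).sd_case
    assert not _subject(screened_control=True).sd_case


def test_unscreened_noncase_is_excluded_from_contrasts():
    s = _subject()  # all flags false, not screened
    assert s.excluded and s.group_id is None
    c = _subject(screened_control=True)
    assert not c.excluded and c.group_id == "AA_ctrl"


def test_case_and_control_label_conflict_rejected():
    with pytest.raises(ValueError):
        _subject(ad=True, screened_control=True)


# -- allele counting --------------------------------------------------------


def _random_matrix(rng, n=50, m=5, missing_rate=0.15):
    sites = [VariantSite(f"v{j}", 4, Region.CDS) for j in range(m)]
    subjects = [
        _subject(subject_id=f"s{i}", screened_control=bool(i % 2), ad=not (i % 2))
        for i in range(n)
    ]
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int16)
    calls[rng.random((n, m)) < missing_rate] = MISSING
    return GenotypeMatrix(sites, subjects, calls)


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_count_alleles_matches_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    g = _random_matrix(rng)
    mask = rng.random(len(g.subjects)) < 0.5
    for j, site in enumerate(g.sites):
        gc = count_alleles(g, site, mask)
        assert (gc.n_minor, gc.n_total) == brute_force_allele_count(g.calls, mask, j)


def test_group_counts_sum_over_partition():
    rng = np.random.default_rng(7)
    g = _random_matrix(rng)
    parts = rng.integers(0, 3, size=len(g.subjects))
    for site in g.sites:
        whole = count_alleles(g, site, np.ones(len(g.subjects), bool))
        pieces = [count_alleles(g, site, parts == k) for k in range(3)]
        assert sum(p.n_minor for p in pieces) == whole.n_minor
        assert sum(p.n_total for p in pieces) == whole.n_total


def test_empty_group_is_degenerate_with_warning():
    g = _random_matrix(np.random.default_rng(1))
    with pytest.warns(UserWarning):
        gc = count_alleles(g, g.sites[0], np.zeros(len(g.subjects), bool))
    assert gc.degenerate and gc.n_minor == 0 and gc.n_total == 0


def test_unknown_site_rejected():
    g = _random_matrix(np.random.default_rng(2))
    with pytest.raises(KeyError):
        count_alleles(g, "nope", np.ones(len(g.subjects), bool))


def test_compute_maf_pools_and_rejects_empty():
    counts = [GroupCount("a", 3, 100), GroupCount("b", 1, 100)]
    assert compute_maf(counts) == pytest.approx(0.02)
    with pytest.raises(ValueError):
        compute_maf([GroupCount("a", 0, 0)])
    assert compute_maf([GroupCount("a", 0, 50)]) == 0.0


def test_group_count_invariants():
    with pytest.raises(ValueError):
        GroupCount("g", 5, 4)
    with pytest.raises(ValueError):
        GroupCount("g", -1, 4)


# -- packaged fixture -------------------------------------------------------


def test_fixture_shape_and_novelty(fixture_study):
    assert len(fixture_study.sites) == 23
    assert sum(s.novel for s in fixture_study.sites) == 12
    # the two common polymorphisms are present with their dbSNP names
    by_id = {s.site_id: s for s in fixture_study.sites}
    assert by_id["c.560_561insAGCAGCGGC"].dbsnp_id == "rs10654394"
    assert by_id["c.1130C>T"].dbsnp_id == "rs1042571"


@pytest.mark.parametrize(
    "site_id, group, n, N",
    [
        ("c.560_561insAGCAGCGGC", "AA_case", 66, 258),
        ("c.560_561insAGCAGCGGC", "EA_ctrl", 14, 292),
        ("c.61A>G", "AA_case", 6, 270),
        ("c.1130C>T", "EA_ctrl", 68, 324),
        ("c.281C>T", "EA_case", 4, 274),
        ("c.1187A>G", "EA_ctrl", 1, 324),
    ],
)
def test_fixture_cells_match_published_table(fixture_study, site_id, group, n, N):
    gc = fixture_study.counts(site_id, group)
    assert (gc.n_minor, gc.n_total) == (n, N)


def test_fixture_pooled_mafs(fixture_study):
    s = fixture_study

    def maf(site, groups):
        return compute_maf([s.counts(site, g) for g in groups])

    cases, ctrls = ("AA_case", "EA_case"), ("AA_ctrl", "EA_ctrl")
    assert round(maf("c.560_561insAGCAGCGGC", cases), 3) == 0.164
    assert round(maf("c.61A>G", cases), 3) == 0.011
    assert round(maf("c.1130C>T", ctrls), 3) == 0.181
    assert round(maf("c.281C>T", ctrls), 3) == 0.008


# -- file round trips -------------------------------------------------------


def test_phenotype_round_trip(tmp_path):
    subjects = [
        _subject(subject_id="a", ad=True),
        _subject(subject_id="b", screened_control=True, ancestry_prop=0.2, bmi=31.0),
    ]
    path = tmp_path / "pheno.tsv"
    write_phenotypes(subjects, path)
    back = load_phenotypes(path)
    assert [s.subject_id for s in back] == ["a", "b"]
    assert back[0].sd_case and back[1].bmi_class is BmiClass.OBESE
    assert back[1].population is Population.EA


def test_empty_phenotype_file_warns(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("subject_id\tsex\tage\tancestry_prop\tad\tcd\tod\tmjd\tscreened\tbmi\n")
    with pytest.warns(UserWarning):
        assert load_phenotypes(path) == []


def test_duplicate_subject_rejected_with_context(tmp_path):
    path = tmp_path / "dup.tsv"
    write_phenotypes([_subject(subject_id="a"), _subject(subject_id="b")], path)
    text = path.read_text().splitlines()
    path.write_text("\n".join(text + [text[1]]) + "\n")
    with pytest.raises(ValueError, match="duplicate"):
        load_phenotypes(path)


def test_vcf_round_trip_including_het_and_missing(tmp_path):
    rng = np.random.default_rng(5)
    g = _random_matrix(rng, n=12, m=3)
    path = tmp_path / "g.vcf"
    write_vcf(g, path)
    back = load_genotypes(path, g.subjects)
    assert np.array_equal(back.calls, g.calls)
    assert [s.site_id for s in back.sites] == [s.site_id for s in g.sites]


def test_vcf_subject_mismatch_rejected(tmp_path):
    g = _random_matrix(np.random.default_rng(5), n=6, m=2)
    path = tmp_path / "g.vcf"
    write_vcf(g, path)
    with pytest.raises(ValueError, match="samples"):
        load_genotypes(path, list(reversed(g.subjects)))


def test_count_table_round_trip(tmp_path, fixture_study):
    path = tmp_path / "counts.tsv"
    write_count_table(fixture_study, path)
    back = load_count_table(path)
    assert [s.site_id for s in back.sites] == [s.site_id for s in fixture_study.sites]
    for s in fixture_study.sites:
        for g in ("AA_case", "AA_ctrl", "EA_case", "EA_ctrl"):
            assert back.counts(s.site_id, g) == fixture_study.counts(s.site_id, g)


def test_subject_level_counts_reproducible_from_genotypes():
    g = _random_matrix(np.random.default_rng(11))
    study = build_count_table(g)
    for site in g.sites:
        for gid in ("AA_case", "AA_ctrl"):
            mask = np.array([s.group_id == gid for s in g.subjects])
            direct = count_alleles(g, site, mask)
            assert study.counts(site.site_id, gid).n_minor == direct.n_minor
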