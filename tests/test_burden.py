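"""Rare-panel classification, harmonic-mean collapsing, and the exact burden test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from exonassoc.burden import (
    DEFAULT_MAF_THRESHOLD,
    adjusted_collapsed_counts,
    bonferroni_adjust,
    burden_test,
    classify_rare,
    fisher_exact_2x2,
    harmonic_mean_size,
)
from exonassoc.cohort import (
    CohortStudy,
    GroupCount,
    Provenance,
    Region,
    VariantSite,
)


def fet_enumeration_oracle(a, b, c, d):
    """Brute-force two-sided FET: enumerate every table with the observed
    margins via scipy's hypergeometric pmf and sum probability-ordered mass."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-7)].sum()))


def _study(rows):
    """rows: (site_id, {group: (n, N)})"""
    sites, table = [], {}
    for sid, groups in rows:
        sites.append(VariantSite(sid, 4, Region.CDS))
        table[sid] = {g: GroupCount(g, *nv) for g, nv in groups.items()}
    return CohortStudy(count_table=table, sites=sites, provenance=Provenance.COUNT_ONLY)


STD = ("AA_case", "AA_ctrl", "EA_case", "EA_ctrl")


# -- panel classification ---------------------------------------------------


def test_fixture_panel_is_21_rare_plus_2_common(fixture_study):
    panel = classify_rare(fixture_study)
    assert len(panel) == 21
    excluded = {s.site_id for s in fixture_study.sites} - set(panel.site_ids)
    assert excluded == {"c.560_561insAGCAGCGGC", "c.1130C>T"}


def test_empty_table_gives_empty_panel():
    study = _study([])
    assert len(classify_rare(study)) == 0


def test_site_exactly_at_threshold_excluded():
    # pooled case MAF exactly 0.012: strict < excludes it
    rows = [
        ("at", {g: ((12, 1000) if g.endswith("case") else (0, 1000)) for g in STD}),
        ("below", {g: ((11, 1000) if g.endswith("case") else (0, 1000)) for g in STD}),
    ]
    panel = classify_rare(_study(rows), maf_threshold=0.012)
    assert panel.site_ids == ("below",)


def test_unsequenced_site_excluded_with_warning():
    rows = [("dead", {g: (0, 0) for g in STD})]
    with pytest.warns(UserWarning, match="zero total"):
        panel = classify_rare(_study(rows))
    assert len(panel) == 0


# -- harmonic mean ----------------------------------------------------------


def test_harmonic_mean_of_equal_sizes():
    assert harmonic_mean_size([100] * 5) == pytest.approx(100.0)
    assert harmonic_mean_size([123]) == pytest.approx(123.0)


def test_harmonic_mean_fixture_aa_case_denominators():
    ns = [270] + [292] * 4 + [258] * 6 + [288] * 8 + [302] * 2
    assert harmonic_mean_size(ns) == pytest.approx(279.78, abs=0.05)


def test_harmonic_mean_rejects_zero():
    with pytest.raises(ValueError):
        harmonic_mean_size([100, 0])
    with pytest.raises(ValueError):
        harmonic_mean_size([])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.integers(1, 500), min_size=1, max_size=30))
def test_harmonic_never_exceeds_arithmetic_mean(ns):
    h = harmonic_mean_size(ns)
    assert min(ns) - 1e-9 <= h <= max(ns) + 1e-9
    assert h <= np.mean(ns) + 1e-9
    if len(set(ns)) == 1:
        assert h == pytest.approx(ns[0])


# -- collapsing -------------------------------------------------------------


def test_fixture_collapsed_counts_match_published_numerators(fixture_study):
    panel = classify_rare(fixture_study)
    expected = {"AA_case": 16, "AA_ctrl": 4, "EA_case": 14, "EA_ctrl": 18}
    for gid, raw in expected.items():
        gm = {sid: fixture_study.counts(sid, gid) for sid in panel.site_ids}
        cc = adjusted_collapsed_counts(panel, gm, gid)
        assert cc.raw_minor == raw
    # the spec'd adjusted examples
    gm = {sid: fixture_study.counts(sid, "AA_case") for sid in panel.site_ids}
    assert adjusted_collapsed_counts(panel, gm, "AA_case").adj_minor == 16
    gm = {sid: fixture_study.counts(sid, "EA_ctrl") for sid in panel.site_ids}
    assert adjusted_collapsed_counts(panel, gm, "EA_ctrl").adj_minor == 18


def test_adjusted_equals_raw_when_denominators_equal():
    rows = [(f"v{k}", {g: (k % 3, 200) for g in STD}) for k in range(6)]
    study = _study(rows)
    panel = classify_rare(study)
    gm = {sid: study.counts(sid, "AA_case") for sid in panel.site_ids}
    cc = adjusted_collapsed_counts(panel, gm, "AA_case")
    assert cc.adj_minor == cc.raw_minor
    assert cc.harmonic_N == pytest.approx(200.0)


def test_collapse_rejects_missing_site_counts(fixture_study):
    panel = classify_rare(fixture_study)
    gm = {sid: fixture_study.counts(sid, "AA_case") for sid in panel.site_ids[:-1]}
    with pytest.raises(ValueError, match="lacks counts"):
        adjusted_collapsed_counts(panel, gm, "AA_case")


# -- Fisher's exact ---------------------------------------------------------


@pytest.mark.parametrize(
    "cells, expected",
    [((0, 10, 0, 10), 1.0), ((5, 5, 5, 5), 1.0)],
)
def test_fet_degenerate_and_symmetric(cells, expected):
    assert fisher_exact_2x2(*cells) == pytest.approx(expected)


def test_fet_matches_enumeration_on_burden_sized_table():
    p = fisher_exact_2x2(13, 178, 3, 207)
    assert p == pytest.approx(fet_enumeration_oracle(13, 178, 3, 207), abs=1e-12)
    assert p == pytest.approx(0.00869, abs=5e-5)


@settings(max_examples=300, deadline=None)
@given(st.tuples(*[st.integers(0, 60)] * 4))
def test_fet_matches_enumeration_random_tables(cells):
    assert fisher_exact_2x2(*cells) == pytest.approx(
        fet_enumeration_oracle(*cells), abs=1e-12
    )


def test_fet_rejects_negative_or_fractional():
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        fisher_exact_2x2(1.5, 2, 3, 4)


# -- burden test ------------------------------------------------------------


def test_identical_groups_give_p_one(fixture_study):
    panel = classify_rare(fixture_study)
    gm = {sid: fixture_study.counts(sid, "AA_case") for sid in panel.site_ids}
    res = burden_test(panel, gm, gm)
    assert res.p_fet == pytest.approx(1.0)


def test_fixture_aa_sd_burden_is_nominally_significant(fixture_study):
    panel = classify_rare(fixture_study)
    ga = {sid: fixture_study.counts(sid, "AA_case") for sid in panel.site_ids}
    gb = {sid: fixture_study.counts(sid, "AA_ctrl") for sid in panel.site_ids}
    res = burden_test(panel, ga, gb, "AA_case", "AA_ctrl")
    assert res.group_a.adj_minor == 16 and res.group_b.adj_minor == 4
    # enrichment direction and nominal significance, as in the source study
    assert res.p_fet < 0.05
    assert res.group_a.adj_minor / res.group_a.adj_total > (
        res.group_b.adj_minor / res.group_b.adj_total
    )


def test_adding_case_only_carrier_never_increases_significance(fixture_study):
    base_panel = classify_rare(fixture_study)
    ga = {sid: fixture_study.counts(sid, "AA_case") for sid in base_panel.site_ids}
    gb = {sid: fixture_study.counts(sid, "AA_ctrl") for sid in base_panel.site_ids}
    p0 = burden_test(base_panel, ga, gb).p_fet
    extra = VariantSite("extra", 4, Region.CDS)
    panel2 = type(base_panel)(base_panel.sites + (extra,), base_panel.maf_threshold)
    ga2 = dict(ga, extra=GroupCount("AA_case", 2, 280))
    gb2 = dict(gb, extra=GroupCount("AA_ctrl", 0, 210))
    p1 = burden_test(panel2, ga2, gb2).p_fet
    assert p1 <= p0 + 1e-12


def test_burden_effect_orders_p_values_against_null():
    """Median burden p under an enriched alternative falls below the null's."""
    from exonassoc.simulate import simulate_cohort
    from conftest import small_config

    def median_p(burden_or, seeds):
        ps = []
        for s in seeds:
            study = simulate_cohort(
                small_config(seed=s, burden_or=burden_or, n_case=100, n_ctrl=100)
            )
            # generous threshold keeps the panel identical across arms even
            # when enrichment pushes a site's sample MAF past the 1.2% default
            panel = classify_rare(study, maf_threshold=0.05)
            if len(panel) == 0:
                continue
            ga = {sid: study.counts(sid, "AA_case") for sid in panel.site_ids}
            gb = {sid: study.counts(sid, "AA_ctrl") for sid in panel.site_ids}
            ps.append(burden_test(panel, ga, gb).p_fet)
        return float(np.median(ps))

    seeds = range(40)
    assert median_p(3.0, seeds) < median_p(1.0, seeds)


# -- Bonferroni -------------------------------------------------------------


def test_bonferroni_threshold_and_capping():
    out = bonferroni_adjust([0.007, 0.026, 0.3], k=5, alpha=0.05)
    assert out[0]["threshold"] == pytest.approx(0.01)
    assert out[0]["significant"] and not out[1]["significant"]
    assert out[2]["p_bonferroni"] == 1.0
    assert bonferroni_adjust([0.04], k=1)[0]["significant"]
    with pytest.raises(ValueError):
        bonferroni_adjust([0.5], k=0)
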