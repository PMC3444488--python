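import numpy as np
import pytest

from exonassoc.cohort import Region, VariantSite, load_count_fixture
from exonassoc.simulate import EffectSpec, SimulationConfig


@pytest.fixture(scope="session")
def fixture_study():
    return load_count_fixture()


def small_config(
    seed: int = 0,
    burden_or: float = 1.0,
    bmi_or: float = 1.0,
    n_case: int = 150,
    n_ctrl: int = 150,
    two_pops: bool = False,
    rare_freq: float = 0.01,
    n_rare: int = 8,
    dropout: float = 0.05,
) -> SimulationConfig:
    """Compact single-population (AA by default) study for simulation tests."""
    sites = [
        VariantSite("common1", 1, Region.CDS, "rs0001"),
        VariantSite("common2", 4, Region.THREE_UTR, "rs0002"),
    ] + [VariantSite(f"rare{k}", 4, Region.CDS) for k in range(n_rare)]
    seg = (0, 1) + tuple(k % 2 for k in range(n_rare))
    rare = tuple([rare_freq] * n_rare)
    return SimulationConfig(
        n_aa_case=n_case,
        n_aa_ctrl=n_ctrl,
        n_ea_case=n_case if two_pops else 0,
        n_ea_ctrl=n_ctrl if two_pops else 0,
        sites=tuple(sites),
        segment_of_site=seg,
        common_site_ids=("common1", "common2"),
        common_maf={"AA": (0.25, 0.15), "EA": (0.10, 0.20)},
        common_d_prime=-0.9,
        rare_freqs={"AA": rare, "EA": rare},
        exon_dropout=dropout,
        effects=EffectSpec(burden_or_sd=burden_or, common_or_bmi=bmi_or),
        seed=seed,
    )


def brute_force_allele_count(calls: np.ndarray, mask: np.ndarray, j: int):
    """Independent loop-and-sum oracle for count_alleles."""
    n_minor = 0
    n_chrom = 0
    for i in range(calls.shape[0]):
        if not mask[i]:
            continue
        d = calls[i, j]
        if d < 0:
            continue
        n_minor += int(d)
        n_chrom += 2
    return n_minor, n_chrom
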