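import numpy as np
import pytest

from crisisgraph.balance import BalanceConfig, DepthProfile, derive_edge_bounds, fit_joint
from crisisgraph.graph import Breakend, GenomicInterval, Junction, build_prototype
from crisisgraph.pipeline import build_compendium_from_data
from crisisgraph.simulate import default_scenario, simulate


def deletion_toy_graph():
    """Chromosome [0,30k) in 3 segments with a deletion junction 10k+ -> 20k-."""
    j = Junction(Breakend("1", 10_000, "+"), Breakend("1", 20_000, "-"))
    comp = build_prototype(
        {"c": [GenomicInterval("1", 0, 30_000)]}, {"c": [j]}
    )
    return comp, j


def flat_profile(values_per_seg, seg_bins=10, bin_width=1_000, chrom="1"):
    """1-kbp binned profile with constant value per segment."""
    vals = np.repeat(np.asarray(values_per_seg, float), seg_bins)
    starts = np.arange(len(vals)) * bin_width
    return DepthProfile(
        np.array([chrom] * len(vals), object), starts, starts + bin_width, vals
    )


@pytest.fixture(scope="session")
def deletion_toy():
    comp, j = deletion_toy_graph()
    return comp, j, flat_profile([2.0, 1.0, 2.0])


def _fit_cohort(cohort, lambda_=100.0, cn_cap=12):
    comp = build_compendium_from_data(
        cohort.depth, cohort.junctions, cohort.junction_support
    )
    bounds = derive_edge_bounds(comp, cohort.junction_support, min_support=1)
    sol = fit_joint(
        comp, cohort.depth, bounds, BalanceConfig(lambda_=lambda_, cn_cap=cn_cap)
    )
    return comp, bounds, sol


@pytest.fixture(scope="session")
def clean_cohort():
    sc = default_scenario(seed=11)
    sc.depth_sd = 0.0
    sc.dropout = 0.0
    return simulate(sc, 11)


@pytest.fixture(scope="session")
def clean_fit(clean_cohort):
    return _fit_cohort(clean_cohort)


@pytest.fixture(scope="session")
def noisy_cohort():
    sc = default_scenario(seed=12)
    sc.depth_sd = 0.15
    sc.dropout = 0.1
    return simulate(sc, 12)


@pytest.fixture(scope="session")
def noisy_fit(noisy_cohort):
    return _fit_cohort(noisy_cohort)


FUSION = Junction(Breakend("12", 20_000_000, "+"), Breakend("21", 6_000_000, "-"))


@pytest.fixture(scope="session")
def dropout_cohort():
    """The shared stabilizing-fusion junction dropped in every BFB clone."""
    sc = default_scenario(seed=13)
    sc.depth_sd = 0.0
    sc.forced_dropout = [FUSION]
    return simulate(sc, 13)
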