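import pytest

import ctdnaprof as cp

SEED = 7


@pytest.fixture(scope="session")
def sim_config() -> cp.SimulationConfig:
    return cp.SimulationConfig(seed=SEED)


@pytest.fixture(scope="session")
def selector(sim_config) -> cp.Selector:
    return cp.gen_selector(sim_config.genes, seed=SEED)


@pytest.fixture(scope="session")
def controls(selector, sim_config) -> cp.DepthMatrix:
    return cp.gen_control_cohort(selector, sim_config)


@pytest.fixture(scope="session")
def model(selector, controls) -> cp.CopyNumberIndexModel:
    return cp.CopyNumberIndexModel(selector=selector).fit(controls)


@pytest.fixture
def tiny_selector() -> cp.Selector:
    """Three autosomal regions of one gene, convenient for arithmetic checks."""
    return cp.Selector([
        cp.SelectorRegion("GENEA|0", "GENEA", "chr1", 100, 200),
        cp.SelectorRegion("GENEA|1", "GENEA", "chr1", 1000, 1400),
        cp.SelectorRegion("GENEA|2", "GENEA", "chr1", 5000, 5200),
    ])


def make_variant(**kwargs) -> cp.VariantCall:
    """VariantCall with sensible defaults; vaf kept consistent with counts."""
    defaults = dict(
        sample_id="S1", patient_id="P1", timepoint_label="pretreatment",
        gene="EGFR", variant_label="EGFR L858R", variant_class="activating",
        effect="nonsynonymous", blacklisted=False,
    )
    defaults.update(kwargs)
    if "vaf" in kwargs and "depth" not in kwargs:
        depth = 100000
        alt = round(kwargs["vaf"] * depth)
        defaults.update(vaf=alt / depth, depth=depth, alt_reads=alt)
    return cp.VariantCall(**defaults)
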