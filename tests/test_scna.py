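"""Copy-number index: normalization, calibration, scoring, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ctdnaprof as cp
from ctdnaprof.scna import (
    CopyNumberIndexModel,
    calibrate_threshold,
    call_scna,
    copy_number_index,
    normalize_depth,
    normalized_copy_number,
    region_zscores,
)


def _handmade_model(tiny_selector, mu, sigma, thresholds=None):
    """Fitted-state model with prescribed per-region parameters."""
    model = CopyNumberIndexModel(selector=tiny_selector)
    ids = tiny_selector.region_ids
    model.mu_ = pd.Series(mu, index=ids, dtype=float)
    model.sigma_ = pd.Series(sigma, index=ids, dtype=float)
    model.normality_p_ = pd.Series(1.0, index=ids)
    model.included_regions_ = [r for r, s in zip(ids, sigma) if s > 0]
    model.excluded_regions_ = [r for r, s in zip(ids, sigma) if s <= 0]
    incl = set(model.included_regions_)
    model.gene_regions_ = {g: [r for r in tiny_selector.gene_region_ids(g)
                               if r in incl] for g in tiny_selector.genes}
    model.uncallable_genes_ = [g for g, ids_ in model.gene_regions_.items()
                               if not ids_]
    model.thresholds_ = thresholds or {g: 2.0 for g in tiny_selector.genes}
    model.threshold_flagged_ = {g: False for g in tiny_selector.genes}
    model.n_controls_ = 27
    model.control_indices_ = pd.DataFrame()
    return model


# ------------------------------------------------------------ normalization

def test_normalize_depth_hand_arithmetic(tiny_selector):
    row = pd.Series([100.0, 200.0, 400.0], index=tiny_selector.region_ids)
    norm = normalize_depth(row, tiny_selector)
    np.testing.assert_allclose(norm.to_numpy(), [-1.0, 0.0, 1.0])


def test_normalize_depth_constant_is_zero(tiny_selector):
    row = pd.Series([250.0] * 3, index=tiny_selector.region_ids)
    assert (normalize_depth(row, tiny_selector) == 0).all()


def test_normalize_depth_zero_region_sentinel(tiny_selector):
    row = pd.Series([0.0, 200.0, 400.0], index=tiny_selector.region_ids)
    norm = normalize_depth(row, tiny_selector)
    assert norm.iloc[0] == -np.inf
    np.testing.assert_allclose(norm.iloc[1:].to_numpy(), [0.0, 1.0])


def test_normalize_depth_all_zero_errors(tiny_selector):
    row = pd.Series([0.0, 0.0, 0.0], index=tiny_selector.region_ids)
    with pytest.raises(cp.ValidationError):
        normalize_depth(row, tiny_selector)


def test_autosomal_median_anchor():
    """Sex-chromosome regions do not participate in the median."""
    sel = cp.Selector([
        cp.SelectorRegion("A|0", "A", "chr1", 0, 100),
        cp.SelectorRegion("A|1", "A", "chr1", 200, 300),
        cp.SelectorRegion("A|2", "A", "chr1", 400, 500),
        cp.SelectorRegion("AR|0", "AR", "chrX", 0, 100, autosomal=False),
    ])
    row = pd.Series([100.0, 200.0, 400.0, 10_000.0], index=sel.region_ids)
    norm = normalize_depth(row, sel)
    np.testing.assert_allclose(norm.to_numpy()[:3], [-1.0, 0.0, 1.0])
    # odd autosomal count: median of normalized autosomal depths is 0 exactly
    assert np.median(norm.to_numpy()[:3]) == 0.0


# ---------------------------------------------------------------- z & index

def test_zscores_zero_when_at_control_mean(tiny_selector):
    model = _handmade_model(tiny_selector, mu=[0.1, -0.2, 0.0],
                            sigma=[0.1, 0.1, 0.1])
    norm = pd.Series([0.1, -0.2, 0.0], index=tiny_selector.region_ids)
    assert (region_zscores(norm, model) == 0).all()


def test_zscore_arithmetic(tiny_selector):
    model = _handmade_model(tiny_selector, mu=[0.0] * 3, sigma=[0.1] * 3)
    norm = pd.Series([0.24, 0.0, 0.0], index=tiny_selector.region_ids)
    z = region_zscores(norm, model)
    assert z.iloc[0] == pytest.approx(2.4)


def test_excluded_region_absent_from_zscores(tiny_selector):
    model = _handmade_model(tiny_selector, mu=[0.0] * 3, sigma=[0.1, 0.0, 0.1])
    norm = pd.Series([0.1, 0.1, 0.1], index=tiny_selector.region_ids)
    z = region_zscores(norm, model)
    assert "GENEA|1" not in z.index and len(z) == 2


@pytest.mark.parametrize("z_values,expected", [
    ([1.0, 1.0, 1.0, 1.0], 2.0),          # 4 / sqrt(4)
    ([0.0, 0.0, 0.0, 0.0], 0.0),
    ([2.0, 3.0], 5.0 / math.sqrt(2.0)),    # ~3.5355
])
def test_copy_number_index_arithmetic(z_values, expected):
    sel = cp.Selector([cp.SelectorRegion(f"G|{i}", "G", "chr2", 1000 * i,
                                         1000 * i + 100)
                       for i in range(len(z_values))])
    model = _handmade_model(sel, mu=[0.0] * len(z_values),
                            sigma=[1.0] * len(z_values))
    z = pd.Series(z_values, index=sel.region_ids)
    assert copy_number_index(z, "G", model) == pytest.approx(expected)


def test_uncallable_gene_raises(tiny_selector):
    model = _handmade_model(tiny_selector, mu=[0.0] * 3, sigma=[0.0] * 3)
    z = pd.Series([], dtype=float)
    with pytest.raises(cp.ValidationError, match="uncallable"):
        copy_number_index(z, "GENEA", model)


# --------------------------------------------------------------- calibration

def test_calibrate_threshold_enumeration():
    # 27 distinct indices 0.1..2.7: max gives FPR 1/27 < 0.05
    values = [0.1 * k for k in range(1, 28)]
    t, flagged = calibrate_threshold(values, alpha=0.05)
    assert t == pytest.approx(2.7) and not flagged


def test_calibrate_threshold_sentinel_when_unreachable():
    # best achievable FPR on 20 distinct values is 1/20 = 0.05, not < 0.05
    values = [0.05 * k for k in range(1, 21)]
    t, flagged = calibrate_threshold(values, alpha=0.05)
    assert flagged and t > max(values)


def test_calibrate_threshold_degenerate_all_equal():
    t, flagged = calibrate_threshold([1.5] * 27, alpha=0.05)
    assert flagged and t > 1.5 and t == pytest.approx(1.5)


def test_calibrate_threshold_empty_errors():
    with pytest.raises(cp.ValidationError):
        calibrate_threshold([], alpha=0.05)


def test_identical_controls_make_genes_uncallable(tiny_selector):
    frame = pd.DataFrame({"C1": [100.0, 200.0, 300.0],
                          "C2": [100.0, 200.0, 300.0]},
                         index=tiny_selector.region_ids)
    model = CopyNumberIndexModel(selector=tiny_selector,
                                 calibration="in_sample").fit(frame)
    assert model.included_regions_ == []
    assert model.uncallable_genes_ == ["GENEA"]
    assert math.isinf(model.thresholds_["GENEA"])


def test_fit_requires_two_controls(tiny_selector):
    frame = pd.DataFrame({"C1": [100.0, 200.0, 300.0]},
                         index=tiny_selector.region_ids)
    with pytest.raises(cp.ValidationError, match="2 control"):
        CopyNumberIndexModel(selector=tiny_selector).fit(frame)


def test_fit_is_deterministic(selector, controls):
    m1 = CopyNumberIndexModel(selector=selector).fit(controls)
    m2 = CopyNumberIndexModel(selector=selector).fit(controls)
    pd.testing.assert_series_equal(m1.mu_, m2.mu_)
    pd.testing.assert_series_equal(m1.sigma_, m2.sigma_)
    assert m1.thresholds_ == m2.thresholds_


def test_sigma_recovery_large_cohort(selector):
    config = cp.SimulationConfig(seed=13)
    cohort = cp.gen_control_cohort(cp.gen_selector(config.genes, seed=13),
                                   config, n=1000)
    model = CopyNumberIndexModel(
        selector=cp.gen_selector(config.genes, seed=13)).fit(cohort)
    assert abs(model.sigma_.loc[model.included_regions_].mean() - 0.10) < 0.005


# --------------------------------------------------- normalized copy number

@pytest.mark.parametrize("r,f,expected", [
    (1.0, 0.3, 2.0),       # no depth change => diploid
    (1.275, 0.05, 13.0),
    (1.9, 0.10, 20.0),
])
def test_normalized_copy_number(r, f, expected):
    assert normalized_copy_number(r, f) == pytest.approx(expected)


def test_normalized_copy_number_requires_positive_fraction():
    with pytest.raises(cp.ValidationError):
        normalized_copy_number(1.2, 0.0)


def test_normalized_copy_number_clipped_at_zero():
    assert normalized_copy_number(0.1, 0.5) == 0.0


# -------------------------------------------------------------- null model

def test_null_index_distribution_is_standard_normal(selector):
    """Gene indices of held-out controls match N(0,1)
    (Kolmogorov distance < 0.05 at n = 10,000)."""
    config = cp.SimulationConfig(seed=17)
    sel = cp.gen_selector(config.genes, seed=17)
    train = cp.gen_control_cohort(sel, config, n=500, cohort="train")
    model = CopyNumberIndexModel(selector=sel).fit(train)
    held = cp.gen_control_cohort(sel, config, n=10_000, cohort="null")
    indices = model.transform(held)
    ks = stats.kstest(indices.loc["EGFR"].to_numpy(), "norm").statistic
    assert ks < 0.05


def test_calibration_validity_held_out(selector, controls, model):
    """Mean per-gene false-positive rate on 1,000 held-out controls stays
    near the calibration target (<= 0.06); individual genes fluctuate
    because each threshold is an extreme order statistic of 27 draws."""
    config = cp.SimulationConfig(seed=7)
    held = cp.gen_control_cohort(selector, config, n=1000, cohort="heldout")
    fpr = model.predict(held).to_numpy().mean()
    assert fpr <= 0.06


def test_index_monotone_in_fraction_and_cn(selector, controls, model):
    """For a fixed noise realization the index increases with tumour
    fraction and with copy number."""
    control_row = controls.sample(controls.samples[0])
    met = selector.gene_region_ids("MET")

    def index_at(f, cn):
        row = control_row.copy()
        row.loc[met] *= (1 - f) + f * cn / 2.0
        return model.transform(pd.DataFrame({"S": row})).loc["MET", "S"]

    by_f = [index_at(f, 13.0) for f in (0.0, 0.02, 0.05, 0.1, 0.3)]
    assert all(b > a for a, b in zip(by_f, by_f[1:]))
    by_cn = [index_at(0.05, cn) for cn in (2.0, 4.0, 8.0, 13.0, 20.0)]
    assert all(b > a for a, b in zip(by_cn, by_cn[1:]))


def test_call_scna_gate_and_significance(selector, controls, model):
    config = cp.SimulationConfig(seed=7)
    profile = cp.TumourProfile(cn_events={"MET": 13.0})
    row, _ = cp.gen_tumour_sample(selector, profile, 0.05, config, sample_id="T")
    calls = {c.gene: c for c in call_scna(row, model, ctdna_fraction=0.05,
                                          activating_raw_vaf=0.01)}
    met = calls["MET"]
    assert met.significant
    assert not met.conclusive          # gate: raw VAF 1% < 2%
    assert met.normalized_cn == pytest.approx(13.0, rel=0.25)
    # non-significant gene: no normalized CN
    assert calls["TP53"].normalized_cn is None or calls["TP53"].significant


def test_cn_round_trip_recovery(selector, model):
    """gen_tumour_sample -> call_scna -> normalized_copy_number recovers the
    planted copy number within 10% (mean over 30 replicates, f = 0.05)."""
    config = cp.SimulationConfig(seed=7)
    profile = cp.TumourProfile(cn_events={"MET": 13.0})
    estimates = []
    for k in range(30):
        row, _ = cp.gen_tumour_sample(selector, profile, 0.05, config,
                                      sample_id=f"RT{k}")
        met = next(c for c in call_scna(row, model, ctdna_fraction=0.05)
                   if c.gene == "MET")
        assert met.significant
        estimates.append(met.normalized_cn)
    assert abs(np.mean(estimates) - 13.0) / 13.0 < 0.10


def test_model_save_load_round_trip(selector, controls, model, tmp_path):
    model.save(tmp_path / "model")
    again = CopyNumberIndexModel.load(tmp_path / "model", selector)
    pd.testing.assert_series_equal(model.mu_, again.mu_, check_names=False)
    assert again.thresholds_ == model.thresholds_
    held = cp.gen_control_cohort(selector, cp.SimulationConfig(seed=7),
                                 n=5, cohort="rt")
    pd.testing.assert_frame_equal(model.predict(held), again.predict(held))


def test_sklearn_params_round_trip(selector):
    model = CopyNumberIndexModel(selector=selector, alpha=0.01)
    params = model.get_params()
    assert params["alpha"] == 0.01
    clone = CopyNumberIndexModel().set_params(**params)
    assert clone.alpha == 0.01 and clone.selector is selector
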