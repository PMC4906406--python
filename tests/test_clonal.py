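"""Clonal quantification: filters, ctDNA fraction, LOD, the ratio, ROC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

import ctdnaprof as cp
from ctdnaprof.clonal import (
    corrected_activating_vaf,
    estimate_ctdna_fraction,
    filter_germline,
    lod_vaf,
    ratio_trajectory,
    roc_cutpoint,
    t790m_ratio,
)
from ctdnaprof.scna import GeneCnCall

from conftest import make_variant


def _egfr_call(significant, r=1.0, cn=None):
    return GeneCnCall(gene="EGFR", index=5.0 if significant else 0.0,
                      threshold=2.58, significant=significant,
                      relative_depth=r, normalized_cn=cn, conclusive=True,
                      n_regions=12)


# ---------------------------------------------------------------- filtering

def test_germline_window_removes_het_snp():
    v = make_variant(vaf=0.50, variant_class="other", variant_label="X")
    res = filter_germline([v], ctdna=0.05)
    assert res.kept == [] and res.removed[0][1] == "germline_window"


def test_synonymous_removed():
    v = make_variant(vaf=0.03, effect="synonymous", variant_class="other")
    res = filter_germline([v], ctdna=0.05)
    assert res.removed[0][1] == "non_nonsynonymous"


def test_window_suspended_at_high_tumour_fraction():
    v = make_variant(vaf=0.50, variant_class="other")
    assert filter_germline([v], ctdna=0.95).kept == [v]


def test_blacklist_and_homozygous_rules():
    v1 = make_variant(vaf=0.03, blacklisted=True)
    v2 = make_variant(vaf=0.95, variant_class="other", variant_label="Y")
    v3 = make_variant(vaf=0.03, variant_class="other", variant_label="Z")
    res = filter_germline([v1, v2, v3], ctdna=0.06)
    assert [r for _, r in res.removed] == ["blacklist", "germline_window"]
    assert res.kept == [v3]


def test_explicit_blacklist_set():
    v = make_variant(vaf=0.03, gene="KRAS", variant_label="KRAS G12A",
                     variant_class="other")
    res = filter_germline([v], ctdna=0.05, blacklist={("KRAS", "KRAS G12A")})
    assert res.removed[0][1] == "blacklist"


# ------------------------------------------------------- fraction estimation

def test_fraction_from_truncal_tp53():
    v = make_variant(vaf=0.12, gene="TP53", variant_label="TP53 R273H",
                     variant_class="truncal_TP53")
    est = estimate_ctdna_fraction([v])
    assert est.fraction == pytest.approx(0.24)
    assert est.source == "TP53_truncal"
    assert est.raw_truncal_vaf == pytest.approx(0.12)


def test_fraction_from_corrected_activating():
    """Activating VAF 0.5263 with a called EGFR gain (r = 1.9) implies a
    heterozygous-equivalent VAF of 0.05, hence f = 0.10."""
    v = make_variant(vaf=0.5263)
    est = estimate_ctdna_fraction([v], [_egfr_call(True, r=1.9, cn=20.0)])
    assert est.source == "EGFR_activating_corrected"
    assert est.fraction == pytest.approx(0.10, abs=1e-3)


def test_fraction_without_gain_uses_raw_activating():
    v = make_variant(vaf=0.04)
    est = estimate_ctdna_fraction([v], [_egfr_call(False)])
    assert est.fraction == pytest.approx(0.08)


def test_fraction_none_when_no_anchor():
    v = make_variant(vaf=0.03, variant_class="other")
    est = estimate_ctdna_fraction([v])
    assert est.source == "none" and math.isnan(est.fraction)
    assert not est.available


def test_raw_vaf_mode():
    v = make_variant(vaf=0.12, gene="TP53", variant_class="truncal_TP53")
    est = estimate_ctdna_fraction([v], mode="raw_vaf")
    assert est.fraction == pytest.approx(0.12)


# --------------------------------------------------------------- correction

def test_corrected_activating_vaf_worked_example():
    # forward model: f=0.1, 20 EGFR copies all mutant -> raw 0.5263, r 1.9
    assert corrected_activating_vaf(0.5263, 1.9, 20.0) \
        == pytest.approx(0.05, abs=1e-4)


def test_correction_identity_without_gain():
    assert corrected_activating_vaf(0.10, 1.9, 20.0, significant=False) == 0.10
    assert corrected_activating_vaf(0.10, 1.0, 2.0) == 0.10  # diploid identity
    assert corrected_activating_vaf(0.10, 1.0, None) == 0.10


# --------------------------------------------------------------------- LOD

def test_lod_closed_form_single_read():
    assert lod_vaf(3000, min_supporting_reads=1) \
        == pytest.approx(1.0 - 0.05 ** (1.0 / 3000.0), abs=1e-12)
    assert lod_vaf(3000, min_supporting_reads=1) == pytest.approx(9.98e-4, rel=1e-3)


def test_lod_closed_form_matches_numeric_solver():
    """Independent numeric inversion of the binomial tail reproduces the
    closed form to 1e-9."""
    for depth in (500, 3000, 20000):
        numeric = optimize.brentq(
            lambda v: stats.binom.sf(0, depth, v) - 0.95, 1e-15, 1.0,
            xtol=1e-14)
        assert abs(lod_vaf(depth, 1) - numeric) < 1e-9


def test_lod_monotone_in_support_and_depth():
    assert lod_vaf(3000, 2) > lod_vaf(3000, 1)
    assert lod_vaf(6000, 2) < lod_vaf(3000, 2)
    # brute-force check of the s = 2 solution on a VAF grid
    v2 = lod_vaf(3000, 2)
    assert stats.binom.sf(1, 3000, v2) == pytest.approx(0.95, abs=1e-9)
    assert stats.binom.sf(1, 3000, v2 * 0.99) < 0.95


def test_lod_zero_depth_errors():
    with pytest.raises(cp.ValidationError):
        lod_vaf(0)


# -------------------------------------------------------------- t790m ratio

def test_ratio_low_group():
    t790m = make_variant(vaf=0.10, variant_label="EGFR T790M",
                         variant_class="T790M")
    act = make_variant(vaf=0.25)
    res = t790m_ratio([t790m, act])
    assert res.ratio == pytest.approx(0.4)
    assert res.group == "low" and not res.censored


def test_ratio_equal_vafs_high_group():
    t790m = make_variant(vaf=0.10, variant_label="EGFR T790M",
                         variant_class="T790M")
    act = make_variant(vaf=0.10)
    res = t790m_ratio([t790m, act])
    assert res.ratio == pytest.approx(1.0) and res.group == "high"


def test_ratio_censoring_min_rule():
    """Undetected T790M at depth 3000 with activating VAF 0.0005: the
    activating VAF (< LOD ~ 0.000998) bounds the censored ratio at 1."""
    act = cp.VariantCall(sample_id="S", patient_id="P",
                         timepoint_label="progression", gene="EGFR",
                         variant_label="EGFR L858R", variant_class="activating",
                         vaf=10 / 20000, depth=20000, alt_reads=10)
    t790m_row = cp.VariantCall(sample_id="S", patient_id="P",
                               timepoint_label="progression", gene="EGFR",
                               variant_label="EGFR T790M",
                               variant_class="T790M", vaf=0.0, depth=3000,
                               alt_reads=0)
    res = t790m_ratio([act, t790m_row], min_supporting_reads=1)
    assert res.censored
    assert res.vaf_t790m == pytest.approx(0.0005)
    assert res.ratio == pytest.approx(1.0)


def test_ratio_requires_activating():
    t790m = make_variant(vaf=0.1, variant_label="EGFR T790M",
                         variant_class="T790M")
    with pytest.raises(cp.NotEvaluableError):
        t790m_ratio([t790m])


def test_correction_identity_pipeline():
    """With no EGFR copy-number significance the corrected pipeline is
    the raw-VAF pipeline."""
    t790m = make_variant(vaf=0.08, variant_label="EGFR T790M",
                         variant_class="T790M")
    act = make_variant(vaf=0.20)
    raw = t790m_ratio([t790m, act])
    with_calls = t790m_ratio([t790m, act], [_egfr_call(False, r=1.4, cn=None)])
    assert raw.ratio == with_calls.ratio


@settings(max_examples=60, deadline=None, derandomize=True)
@given(depth=st.integers(100, 50_000),
       act_alt=st.integers(1, 400),
       s=st.integers(1, 3))
def test_censored_ratio_never_exceeds_one(depth, act_alt, s):
    act = cp.VariantCall(sample_id="S", patient_id="P",
                         timepoint_label="progression", gene="EGFR",
                         variant_label="EGFR L858R", variant_class="activating",
                         vaf=act_alt / 100_000, depth=100_000,
                         alt_reads=act_alt)
    res = t790m_ratio([act], min_supporting_reads=s, t790m_locus_depth=depth)
    assert res.censored and res.ratio <= 1.0 + 1e-12


# --------------------------------------------------------------- trajectory

def _patient_with_ratios(vafs):
    """vafs: {label: (t790m_vaf, act_vaf)} at huge depth."""
    tps = []
    for day, (label, (vt, va)) in enumerate(vafs.items()):
        depth = 1_000_000
        mk = lambda lab, klass, v: cp.VariantCall(
            sample_id=f"S_{label}", patient_id="P", timepoint_label=label,
            gene="EGFR", variant_label=lab, variant_class=klass,
            vaf=round(v * depth) / depth, depth=depth,
            alt_reads=round(v * depth))
        tps.append(cp.Timepoint(label=label, day=day * 50,
                                depth_sample_id=f"S_{label}",
                                variants=(mk("EGFR T790M", "T790M", vt),
                                          mk("EGFR L858R", "activating", va))))
    return cp.PatientRecord(patient_id="P", timepoints=tps, pfs_days=150,
                            progression_event=True)


def test_trajectory_percent_change():
    patient = _patient_with_ratios({"pretreatment": (0.08, 0.10),
                                    "progression": (0.02, 0.05)})
    traj = ratio_trajectory(patient)
    assert traj.evaluable
    assert traj.pct_change == pytest.approx(-50.0)
    assert traj.direction == "decreased"


def test_trajectory_unchanged():
    patient = _patient_with_ratios({"pretreatment": (0.05, 0.10),
                                    "progression": (0.025, 0.05)})
    traj = ratio_trajectory(patient)
    assert traj.pct_change == pytest.approx(0.0)
    assert traj.direction == "unchanged"


def test_trajectory_floor_exclusion():
    patient = _patient_with_ratios({"pretreatment": (0.08, 0.10),
                                    "progression": (0.001, 0.002)})
    traj = ratio_trajectory(patient)
    assert not traj.evaluable and "floor" in traj.reason


def test_trajectory_requires_pretreatment_t790m():
    patient = _patient_with_ratios({"pretreatment": (0.0, 0.10),
                                    "progression": (0.01, 0.05)})
    traj = ratio_trajectory(patient)
    assert not traj.evaluable and "T790M" in traj.reason


# --------------------------------------------------------------------- ROC

def test_roc_cutpoint_perfect_separation():
    assert roc_cutpoint([0.2, 0.3, 0.9, 1.0], [False, False, True, True]) \
        == pytest.approx(0.6)


def test_roc_cutpoint_tie_breaks_to_smallest():
    # candidates 0.15 and 0.35 both reach J = 0.5; the smallest is returned
    cut = roc_cutpoint([0.1, 0.2, 0.3, 0.4], [False, True, False, True])
    assert cut == pytest.approx(0.15)


def test_roc_cutpoint_single_class_errors():
    with pytest.raises(cp.NotEvaluableError):
        roc_cutpoint([0.1, 0.2], [True, True])


def test_roc_cutpoint_recovers_half_on_separated_cohort():
    """Cohort built with responders above and non-responders below 0.5
    yields a cut-point near 0.5."""
    rng = np.random.default_rng(5)
    low = rng.uniform(0.05, 0.45, size=12)     # low ratio: little shrinkage
    high = rng.uniform(0.55, 1.6, size=29)     # high ratio: responders
    ratios = np.concatenate([low, high])
    responders = np.array([False] * 12 + [True] * 29)
    cut = roc_cutpoint(ratios, responders)
    assert 0.45 <= cut <= 0.56
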