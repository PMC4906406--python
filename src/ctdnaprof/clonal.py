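"""Variant-level clonal quantification.

Covers germline filtering of plasma variant calls, ctDNA tumour-fraction
estimation anchored on truncal mutations, the T790M : activating-mutation
ratio with copy-number correction and limit-of-detection censoring, and
the ROC cut-point separating low- from high-T790M patients.

Conventions
-----------
"% ctDNA" is carried as the tumour genome-equivalent fraction
f = min(1, 2 * VAF) of a heterozygous truncal variant, while gates that
the analysis expresses in VAF units (the 2% copy-number conclusiveness
gate) are applied to the raw VAF; both are always reported.

When a significant EGFR gain is called, the activating VAF is corrected
for the excess EGFR coverage under the model that every amplified copy
carries the activating mutation. With relative depth r and normalized
copy number CN the raw VAF is f*CN / (2*r), so the heterozygous-
equivalent (copy-neutral) VAF is

    corrected = raw * r / CN  ( = f / 2 ).

When CN is itself unknown (it needs f), substituting CN = 2 + 2(r-1)/f
gives the closed form f = raw * r - r + 1, which is what the ctDNA
estimator uses for patients without a truncal TP53 anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from ._utils import NotEvaluableError, ValidationError
from .datatypes import PatientRecord, VariantCall
from .scna import GeneCnCall

GERMLINE_WINDOW = (0.40, 0.60)
HOMOZYGOUS_VAF = 0.90
WINDOW_SUSPEND_FRACTION = 0.40


@dataclass(frozen=True)
class CtdnaEstimate:
    """Tumour genome-equivalent fraction of a plasma sample."""

    fraction: float  # NaN when source == "none"
    raw_truncal_vaf: float  # raw VAF of the anchoring variant (gate units)
    source: str  # TP53_truncal | EGFR_activating_corrected | none

    @property
    def available(self) -> bool:
        return self.source != "none" and not math.isnan(self.fraction)


@dataclass(frozen=True)
class RatioResult:
    """T790M : activating-mutation ratio for one sample."""

    vaf_t790m: float
    vaf_activating_corrected: float
    ratio: float
    group: str  # low (<= cut-point) | high
    censored: bool = False  # True => vaf_t790m is an LOD-based upper bound
    sample_id: str = ""
    timepoint_label: str = ""


@dataclass
class RatioTrajectory:
    """Per-timepoint ratios plus the pre -> progression change."""

    patient_id: str
    ratios: dict[str, RatioResult]
    pct_change: float | None
    direction: str  # decreased | increased | unchanged | not_evaluable
    evaluable: bool
    reason: str = ""


def ratio_results_frame(results: Sequence[RatioResult]):
    import pandas as pd
    cols = ["sample_id", "timepoint_label", "vaf_t790m",
            "vaf_activating_corrected", "ratio", "group", "censored"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)


# -------------------------------------------------------------- filtering

@dataclass
class FilterResult:
    kept: list[VariantCall]
    removed: list[tuple[VariantCall, str]]


def filter_germline(variants: Iterable[VariantCall],
                    ctdna: CtdnaEstimate | float | None = None,
                    blacklist: set[tuple[str, str]] | None = None,
                    germline_window: tuple[float, float] = GERMLINE_WINDOW,
                    homozygous_vaf: float = HOMOZYGOUS_VAF,
                    suspend_fraction: float = WINDOW_SUSPEND_FRACTION
                    ) -> FilterResult:
    """Remove putative germline SNPs and non-candidate variant calls.

    Three rules, each recorded as removal provenance: (1) catalogued
    population variants (the blacklist flag or an explicit blacklist
    set); (2) restriction to nonsynonymous substitutions; (3) the
    MAF-window rule — VAF near 50% or above ~90% marks a germline SNP,
    valid only while the tumour fraction is below `suspend_fraction`
    (an unknown fraction is treated as low, the conservative choice).
    """
    f = ctdna.fraction if isinstance(ctdna, CtdnaEstimate) else (
        math.nan if ctdna is None else float(ctdna))
    windows_active = math.isnan(f) or f < suspend_fraction
    blacklist = blacklist or set()
    lo, hi = germline_window

    kept: list[VariantCall] = []
    removed: list[tuple[VariantCall, str]] = []
    for v in variants:
        if v.blacklisted or (v.gene, v.variant_label) in blacklist:
            removed.append((v, "blacklist"))
        elif v.effect != "nonsynonymous":
            removed.append((v, "non_nonsynonymous"))
        elif windows_active and (lo <= v.vaf <= hi or v.vaf >= homozygous_vaf):
            removed.append((v, "germline_window"))
        else:
            kept.append(v)
    return FilterResult(kept=kept, removed=removed)


# ------------------------------------------------------- fraction estimate

def _best_detected(variants: Iterable[VariantCall], variant_class: str
                   ) -> VariantCall | None:
    cands = [v for v in variants if v.variant_class == variant_class and v.detected]
    return max(cands, key=lambda v: v.vaf) if cands else None


def _egfr_call(scna_calls: Sequence[GeneCnCall] | None) -> GeneCnCall | None:
    for c in scna_calls or ():
        if c.gene == "EGFR":
            return c
    return None


def corrected_activating_vaf(raw_vaf: float, relative_depth: float,
                             normalized_cn: float | None,
                             significant: bool = True) -> float:
    """Heterozygous-equivalent activating VAF given an EGFR gain.

    Identity when no significant gain is called (nothing to correct);
    otherwise raw * r / CN under the all-amplified-copies-mutant model.
    """
    if not significant or normalized_cn is None:
        return raw_vaf
    if relative_depth <= 0:
        raise ValidationError("relative depth must be positive")
    if normalized_cn <= 0:
        raise ValidationError("normalized copy number must be positive")
    if normalized_cn <= 2.0:
        return raw_vaf
    return raw_vaf * relative_depth / normalized_cn


def estimate_ctdna_fraction(variants: Iterable[VariantCall],
                            scna_calls: Sequence[GeneCnCall] | None = None,
                            mode: str = "double_vaf") -> CtdnaEstimate:
    """Tumour fraction from a truncal TP53 variant when present, else from
    the EGFR-activating VAF corrected for excess EGFR coverage.

    With a heterozygous clonal anchor, f = min(1, 2 * VAF) (mode
    ``raw_vaf`` keeps the VAF itself). For the EGFR path under a called
    gain, the self-consistent closed form f = raw * r - r + 1 is used.
    """
    if mode not in ("double_vaf", "raw_vaf"):
        raise ValidationError(f"unknown ctdna_fraction_mode {mode!r}")
    variants = list(variants)
    factor = 2.0 if mode == "double_vaf" else 1.0

    tp53 = _best_detected(variants, "truncal_TP53")
    if tp53 is not None:
        return CtdnaEstimate(fraction=min(1.0, factor * tp53.vaf),
                             raw_truncal_vaf=tp53.vaf, source="TP53_truncal")

    act = _best_detected(variants, "activating")
    if act is not None:
        egfr = _egfr_call(scna_calls)
        if egfr is not None and egfr.significant:
            r = egfr.relative_depth
            corrected = max(0.0, (act.vaf * r - r + 1.0) / 2.0)
        else:
            corrected = act.vaf
        return CtdnaEstimate(fraction=min(1.0, factor * corrected),
                             raw_truncal_vaf=act.vaf,
                             source="EGFR_activating_corrected")

    return CtdnaEstimate(fraction=math.nan, raw_truncal_vaf=math.nan, source="none")


# -------------------------------------------------------------------- LOD

def lod_vaf(depth: int, min_supporting_reads: int = 2,
            confidence: float = 0.95) -> float:
    """Smallest VAF detectable with the given confidence at this depth.

    The smallest v such that P[X >= s] >= confidence for
    X ~ Binomial(depth, v). Closed form for s = 1:
    v = 1 - (1 - confidence)**(1/depth); solved numerically otherwise.
    """
    if depth <= 0:
        raise ValidationError("LOD undefined at zero depth")
    s = int(min_supporting_reads)
    if s < 1:
        raise ValidationError("min_supporting_reads must be >= 1")
    if s > depth:
        return 1.0
    if not 0 < confidence < 1:
        raise ValidationError("confidence must be in (0, 1)")
    if s == 1:
        return 1.0 - (1.0 - confidence) ** (1.0 / depth)

    def shortfall(v: float) -> float:
        return stats.binom.sf(s - 1, depth, v) - confidence

    return float(optimize.brentq(shortfall, 1e-15, 1.0, xtol=1e-14, rtol=1e-13))


# -------------------------------------------------------------- the ratio

def t790m_ratio(variants: Iterable[VariantCall],
                scna_calls: Sequence[GeneCnCall] | None = None, *,
                min_supporting_reads: int = 2, confidence: float = 0.95,
                cutpoint: float = 0.5,
                t790m_locus_depth: int | None = None) -> RatioResult:
    """T790M : activating-mutation ratio for one plasma sample.

    The activating VAF in the denominator is corrected for a called
    EGFR gain. An undetected T790M is censored at the lower of the
    depth-based LOD and the activating VAF itself (bounding the ratio
    at 1), mirroring how an absent resistance allele is handled when
    the activating clone is still measurable.
    """
    variants = list(variants)
    act = _best_detected(variants, "activating")
    if act is None:
        raise NotEvaluableError("no detected activating mutation in sample")

    egfr = _egfr_call(scna_calls)
    if egfr is not None and egfr.significant and egfr.normalized_cn is not None:
        denom = corrected_activating_vaf(act.vaf, egfr.relative_depth,
                                         egfr.normalized_cn, significant=True)
    elif egfr is not None and egfr.significant:
        denom = max(0.0, (act.vaf * egfr.relative_depth
                          - egfr.relative_depth + 1.0) / 2.0)
    else:
        denom = act.vaf
    if denom <= 0:
        raise NotEvaluableError("corrected activating VAF is zero")

    t790m_rows = [v for v in variants if v.variant_class == "T790M"]
    detected = [v for v in t790m_rows if v.detected]
    sample_id = act.sample_id
    label = act.timepoint_label
    if detected:
        vaf_t = max(v.vaf for v in detected)
        censored = False
    else:
        depth = t790m_locus_depth
        if depth is None and t790m_rows:
            depth = t790m_rows[0].depth
        if depth is None:
            depth = act.depth
        vaf_t = min(lod_vaf(depth, min_supporting_reads, confidence), denom)
        censored = True
    ratio = vaf_t / denom
    return RatioResult(
        vaf_t790m=vaf_t, vaf_activating_corrected=denom, ratio=ratio,
        group=("low" if ratio <= cutpoint else "high"), censored=censored,
        sample_id=sample_id, timepoint_label=label,
    )


def ratio_trajectory(patient: PatientRecord,
                     scna_calls_by_sample: Mapping[str, Sequence[GeneCnCall]]
                     | None = None, *,
                     progression_vaf_floor: float = 0.003,
                     min_supporting_reads: int = 2,
                     cutpoint: float = 0.5) -> RatioTrajectory:
    """Ratio at every evaluable timepoint plus the pre -> progression change.

    Eligibility: T790M detectable pretreatment and an activating
    mutation detected at both endpoints; a progression activating VAF
    below `progression_vaf_floor` makes the change incalculable and the
    patient is flagged not evaluable.
    """
    scna_calls_by_sample = scna_calls_by_sample or {}

    def _not_evaluable(reason: str) -> RatioTrajectory:
        return RatioTrajectory(patient_id=patient.patient_id, ratios={},
                               pct_change=None, direction="not_evaluable",
                               evaluable=False, reason=reason)

    pre = patient.timepoint("pretreatment")
    prog = patient.timepoint("progression")
    if pre is None or prog is None:
        return _not_evaluable("missing pretreatment or progression timepoint")
    if _best_detected(pre.variants, "T790M") is None:
        return _not_evaluable("T790M not detected pretreatment")
    for tp, name in ((pre, "pretreatment"), (prog, "progression")):
        if _best_detected(tp.variants, "activating") is None:
            return _not_evaluable(f"no activating mutation detected at {name}")
    prog_act = _best_detected(prog.variants, "activating")
    if prog_act.vaf < progression_vaf_floor:
        return _not_evaluable(
            f"progression activating VAF {prog_act.vaf:.4g} below floor")

    ratios: dict[str, RatioResult] = {}
    for tp in patient.timepoints:
        try:
            ratios[tp.label] = t790m_ratio(
                tp.variants, scna_calls_by_sample.get(tp.depth_sample_id),
                min_supporting_reads=min_supporting_reads, cutpoint=cutpoint)
        except NotEvaluableError:
            continue
    r_pre, r_prog = ratios["pretreatment"].ratio, ratios["progression"].ratio
    pct = (r_prog - r_pre) / r_pre * 100.0
    direction = "unchanged" if pct == 0 else ("decreased" if pct < 0 else "increased")
    return RatioTrajectory(patient_id=patient.patient_id, ratios=ratios,
                           pct_change=pct, direction=direction, evaluable=True)


# ------------------------------------------------------------ ROC cut-point

def roc_cutpoint(ratios: Sequence[float], responders: Sequence[bool]) -> float:
    """Cut-point on the baseline ratio maximizing Youden's J for a
    partial response (>= 30% target-lesion shrinkage), where ratios
    above the cut-point predict response.

    Candidates are midpoints between consecutive sorted unique ratios;
    ties resolve to the smallest candidate.
    """
    ratios = np.asarray(ratios, dtype=float)
    resp = np.asarray(responders, dtype=bool)
    if ratios.shape != resp.shape or ratios.size < 2:
        raise ValidationError("need paired ratios and response indicators")
    if resp.all() or not resp.any():
        raise NotEvaluableError("ROC needs at least one responder and one non-responder")
    uniq = np.unique(ratios)
    if uniq.size < 2:
        raise NotEvaluableError("all ratios identical")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos, n_neg = resp.sum(), (~resp).sum()
    best_c, best_j = None, -np.inf
    for c in candidates:  # ascending, so first max wins ties
        pred = ratios > c
        tpr = (pred & resp).sum() / n_pos
        fpr = (pred & ~resp).sum() / n_neg
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_c = j, float(c)
    return best_c
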