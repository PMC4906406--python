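"""Per-patient orchestration chaining the analysis stages.

For each plasma timepoint: estimate the ctDNA fraction from the raw
variant table, call gene-level copy number with the ctDNA-adequacy
gate, germline-filter the variants, and finally evaluate the
resistance-selection rules between the pretreatment and progression
endpoints and the T790M:activating ratio trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._utils import NotEvaluableError, ValidationError
from .clonal import (
    CtdnaEstimate,
    FilterResult,
    RatioTrajectory,
    estimate_ctdna_fraction,
    filter_germline,
    ratio_trajectory,
)
from .datatypes import PatientRecord, StudyBundle, Timepoint, VariantCall
from .resistance import (
    ResistanceCall,
    call_resistance,
    categorize_mechanisms,
    classify_timing,
)
from .scna import CopyNumberIndexModel, GeneCnCall, call_scna

#: genes whose copy-number state is interrogated for resistance calling;
#: the index is calibrated per gene, but only recurrent NSCLC CN drivers
#: are treated as candidate mechanisms
DEFAULT_SCNA_GENES: tuple[str, ...] = ("EGFR", "ERBB2", "MET")


@dataclass
class TimepointProfile:
    label: str
    ctdna: CtdnaEstimate
    scna_calls: list[GeneCnCall]
    variants_kept: list[VariantCall]


@dataclass
class PatientProfile:
    patient_id: str
    timepoints: dict[str, TimepointProfile]
    mechanisms: list[ResistanceCall]
    category: str
    timing: str
    trajectory: RatioTrajectory


def analyze_timepoint(tp: Timepoint, depth_row: pd.Series,
                      model: CopyNumberIndexModel, *,
                      blacklist: set[tuple[str, str]] | None = None,
                      ctdna_gate_vaf: float = 0.02,
                      ctdna_fraction_mode: str = "double_vaf") -> TimepointProfile:
    """ctDNA estimate, gated copy-number calls and filtered variants
    for one plasma sample.

    The fraction is estimated twice: a provisional pass without
    copy-number context, then re-estimated against the gated calls so
    an EGFR-gain correction can apply.
    """
    variants = list(tp.variants)
    ctdna0 = estimate_ctdna_fraction(variants, None, mode=ctdna_fraction_mode)
    raw_anchor = ctdna0.raw_truncal_vaf if ctdna0.available else None
    f0 = ctdna0.fraction if ctdna0.available else None
    calls = call_scna(depth_row, model, ctdna_fraction=f0,
                      activating_raw_vaf=raw_anchor, ctdna_gate_vaf=ctdna_gate_vaf)
    ctdna = estimate_ctdna_fraction(variants, calls, mode=ctdna_fraction_mode)
    if ctdna.available and (f0 is None or abs(ctdna.fraction - (f0 or 0)) > 1e-12):
        calls = call_scna(depth_row, model, ctdna_fraction=ctdna.fraction,
                          activating_raw_vaf=ctdna.raw_truncal_vaf,
                          ctdna_gate_vaf=ctdna_gate_vaf)
    kept = filter_germline(variants, ctdna, blacklist=blacklist).kept
    return TimepointProfile(label=tp.label, ctdna=ctdna, scna_calls=calls,
                            variants_kept=kept)


def analyze_patient(patient: PatientRecord, depths: pd.DataFrame,
                    model: CopyNumberIndexModel, *,
                    blacklist: set[tuple[str, str]] | None = None,
                    ctdna_gate_vaf: float = 0.02, fold_change: float = 1.0,
                    pfs_split_months: float = 3.0,
                    progression_vaf_floor: float = 0.003,
                    scna_genes: Sequence[str] = DEFAULT_SCNA_GENES) -> PatientProfile:
    """Full per-patient analysis over a regions x samples depth frame."""
    pre = patient.timepoint("pretreatment")
    prog = patient.timepoint("progression")
    if pre is None or prog is None:
        raise NotEvaluableError(
            f"{patient.patient_id}: needs pretreatment and progression timepoints")

    profiles: dict[str, TimepointProfile] = {}
    for tp in patient.timepoints:
        if tp.depth_sample_id not in depths.columns:
            raise ValidationError(
                f"{patient.patient_id}: no depth column {tp.depth_sample_id!r}")
        profiles[tp.label] = analyze_timepoint(
            tp, depths[tp.depth_sample_id], model,
            blacklist=blacklist, ctdna_gate_vaf=ctdna_gate_vaf)

    keep = set(scna_genes)
    mech = call_resistance(
        patient.patient_id,
        profiles["pretreatment"].variants_kept,
        profiles["progression"].variants_kept,
        [c for c in profiles["pretreatment"].scna_calls if c.gene in keep],
        [c for c in profiles["progression"].scna_calls if c.gene in keep],
        profiles["pretreatment"].ctdna,
        profiles["progression"].ctdna,
        fold_change=fold_change,
    )
    scna_by_sample = {tp.depth_sample_id: profiles[tp.label].scna_calls
                      for tp in patient.timepoints}
    traj = ratio_trajectory(patient, scna_by_sample,
                            progression_vaf_floor=progression_vaf_floor)
    return PatientProfile(
        patient_id=patient.patient_id,
        timepoints=profiles,
        mechanisms=mech,
        category=categorize_mechanisms(mech),
        timing=classify_timing(patient.pfs_days, split_months=pfs_split_months),
        trajectory=traj,
    )


def analyze_study(bundle: StudyBundle, model: CopyNumberIndexModel,
                  **kwargs) -> list[PatientProfile]:
    if bundle.patient_depths is None:
        raise ValidationError("study bundle has no patient depth matrix")
    return [analyze_patient(p, bundle.patient_depths.data, model,
                            blacklist=bundle.blacklist or None, **kwargs)
            for p in bundle.patients]
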