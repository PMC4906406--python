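"""In-silico spike-in benchmark for the copy-number caller.

Tumour signal is diluted into healthy-control backgrounds at defined
ctDNA fractions and the calibrated copy-number index is scored on every
mixture, yielding per-gene sensitivity/specificity as a function of
fraction. Mixing operates in depth space: each row is first scaled to
its own autosomal median (genome-equivalent equalization, standing in
for the read-level input-mass adjustment), mixed linearly, and rescaled
so the mixture's autosomal median equals the control's original one.

The canonical design mirrors a 12-fraction dilution ladder
(0.1 ... 10% ctDNA) over a 27-control background panel — 324 spike
samples per tumour profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._utils import ValidationError, derive_seed
from .datatypes import DepthMatrix, Selector
from .scna import CopyNumberIndexModel
from .simulate import SimulationConfig, TumourProfile, gen_tumour_sample

#: the dilution ladder of the canonical design, in % ctDNA
DEFAULT_FRACTIONS_PCT: tuple[float, ...] = (
    0.1, 0.3, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 5.0, 10.0)

#: NCI-H1573-like tumour: ~13 MET copies (6.5x) and ~20 EGFR copies (10x)
H1573_LIKE_PROFILE = TumourProfile(cn_events={"MET": 13.0, "EGFR": 20.0})


@dataclass(frozen=True)
class SpikeDesign:
    """One spike benchmark: a tumour profile over a background panel."""

    fractions_pct: tuple[float, ...] = DEFAULT_FRACTIONS_PCT
    background_ids: tuple[str, ...] = ()
    tumour_profile: TumourProfile = H1573_LIKE_PROFILE
    genes_under_test: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < f <= 100 for f in self.fractions_pct):
            raise ValidationError("fractions must lie in (0, 100] percent")
        if not self.background_ids:
            raise ValidationError("at least one background sample required")


def _autosomal_median(row: pd.Series, selector: Selector) -> float:
    med = float(np.median(row.loc[selector.autosomal_ids].to_numpy(dtype=float)))
    if med <= 0:
        raise ValidationError("autosomal median depth is zero")
    return med


def mix_sample(control_row: pd.Series, tumour_row: pd.Series, fraction: float,
               selector: Selector) -> pd.Series:
    """Linear depth-space mixture at tumour fraction `fraction` in [0, 1].

    Contract: the mixture's autosomal median equals the control's, so a
    mixture is directly comparable to the control cohort the model was
    calibrated on.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must lie in [0, 1]")
    if list(control_row.index) != selector.region_ids \
            or list(tumour_row.index) != selector.region_ids:
        raise ValidationError("depth rows do not match the selector")
    med_c = _autosomal_median(control_row, selector)
    med_t = _autosomal_median(tumour_row, selector)
    mixed = (1.0 - fraction) * (control_row / med_c) \
        + fraction * (tumour_row / med_t)
    return mixed / _autosomal_median(mixed, selector) * med_c


@dataclass
class SpikeResult:
    """Detection matrix of one spike grid run."""

    records: pd.DataFrame  # background, fraction_pct, gene, index, threshold,
    #                        detected, true_cn, spiked

    @property
    def n_spike_samples(self) -> int:
        mask = self.records["spiked"]
        return self.records.loc[mask, ["background", "fraction_pct"]] \
            .drop_duplicates().shape[0]


def run_spike_grid(design: SpikeDesign, model: CopyNumberIndexModel,
                   backgrounds: DepthMatrix, config: SimulationConfig,
                   unspiked_controls: DepthMatrix | None = None) -> SpikeResult:
    """Mix the design's tumour into every background at every fraction
    and score each mixture with the calibrated model.

    `unspiked_controls` (held-out by default in callers) contribute the
    fraction-0 rows used for specificity.
    """
    selector = model.selector
    genes = dict(design.genes_under_test) or {
        g: cn for g, cn in design.tumour_profile.cn_events.items()}
    tumour_row, _ = gen_tumour_sample(
        selector, design.tumour_profile, 1.0, config,
        sample_id="SPIKE_TUMOUR", seed_tokens=("spike", design.seed))

    mixed_cols: dict[tuple[str, float], pd.Series] = {}
    for bg in design.background_ids:
        control_row = backgrounds.sample(bg)
        for pct in design.fractions_pct:
            mixed_cols[(bg, pct)] = mix_sample(
                control_row, tumour_row, pct / 100.0, selector)

    frame = pd.DataFrame({f"{bg}@{pct}": col
                          for (bg, pct), col in mixed_cols.items()})
    indices = model.transform(frame)

    rows = []
    for (bg, pct), key in zip(mixed_cols, frame.columns):
        for gene, true_cn in genes.items():
            c = float(indices.loc[gene, key])
            t = model.thresholds_[gene]
            rows.append({"background": bg, "fraction_pct": pct, "gene": gene,
                         "index": c, "threshold": t, "detected": c >= t,
                         "true_cn": true_cn, "spiked": True})

    if unspiked_controls is not None:
        ctrl_idx = model.transform(unspiked_controls)
        for s in unspiked_controls.samples:
            for gene in genes:
                c = float(ctrl_idx.loc[gene, s])
                t = model.thresholds_[gene]
                rows.append({"background": s, "fraction_pct": 0.0, "gene": gene,
                             "index": c, "threshold": t, "detected": c >= t,
                             "true_cn": 2.0, "spiked": False})
    return SpikeResult(records=pd.DataFrame(rows))


def sensitivity_specificity(result: SpikeResult,
                            fraction_bins: Sequence[tuple[float, float]]
                            | None = None) -> pd.DataFrame:
    """Per-gene detection metrics, stratified by ctDNA-fraction bin.

    Sensitivity = detected / spiked within the bin; specificity
    = 1 - detected / unspiked (fraction-0 records), with exact
    (Clopper-Pearson) binomial intervals. Empty bins yield NaN metrics
    flagged by n = 0.
    """
    rec = result.records
    if fraction_bins is None:
        fraction_bins = [(pct, pct) for pct in
                         sorted(rec.loc[rec["spiked"], "fraction_pct"].unique())]
    rows = []
    unspiked = rec[~rec["spiked"]]
    for gene in sorted(rec["gene"].unique()):
        spec = spec_lo = spec_hi = math.nan
        n_ctrl = int((unspiked["gene"] == gene).sum())
        if n_ctrl:
            fp = int(unspiked.loc[unspiked["gene"] == gene, "detected"].sum())
            spec = 1.0 - fp / n_ctrl
            lo, hi = proportion_confint(n_ctrl - fp, n_ctrl, method="beta")
            spec_lo, spec_hi = float(lo), float(hi)
        for lo_f, hi_f in fraction_bins:
            sub = rec[rec["spiked"] & (rec["gene"] == gene)
                      & (rec["fraction_pct"] >= lo_f)
                      & (rec["fraction_pct"] <= hi_f)]
            n = len(sub)
            if n:
                det = int(sub["detected"].sum())
                sens = det / n
                s_lo, s_hi = proportion_confint(det, n, method="beta")
            else:
                sens, s_lo, s_hi = math.nan, math.nan, math.nan
            rows.append({
                "gene": gene, "fraction_lo_pct": lo_f, "fraction_hi_pct": hi_f,
                "n_spiked": n, "sensitivity": sens,
                "sensitivity_ci_lo": float(s_lo) if n else math.nan,
                "sensitivity_ci_hi": float(s_hi) if n else math.nan,
                "n_controls": n_ctrl, "specificity": spec,
                "specificity_ci_lo": spec_lo, "specificity_ci_hi": spec_hi,
            })
    return pd.DataFrame(rows)
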