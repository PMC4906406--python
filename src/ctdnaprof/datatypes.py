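"""Core domain types shared by every pipeline stage.

Coordinates follow the BED convention throughout: 0-based, half-open
intervals, so a region [100, 200) has length 100. A depth matrix is
oriented regions x samples because the selector (the designed capture
panel) is the stable axis across a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import ValidationError

TIMEPOINT_LABELS = ("pretreatment", "on_treatment", "progression")
VARIANT_CLASSES = ("activating", "T790M", "truncal_TP53", "other")
EFFECTS = ("nonsynonymous", "synonymous", "other")

#: chromosome names treated as non-autosomal
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y", "chrM", "MT"})


@dataclass(frozen=True)
class SelectorRegion:
    """One targeted capture region of the selector panel."""

    region_id: str
    gene: str
    chrom: str
    start: int
    end: int
    autosomal: bool = True

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"region {self.region_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class Selector:
    """The designed set of non-contiguous capture regions.

    Invariants enforced at construction: regions on the same chromosome
    do not overlap, region ids are unique, and each region maps to
    exactly one gene.
    """

    def __init__(self, regions: Sequence[SelectorRegion]):
        if not regions:
            raise ValidationError("selector must contain at least one region")
        ids = [r.region_id for r in regions]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate region ids in selector")
        by_chrom: dict[str, list[SelectorRegion]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            rs = sorted(rs, key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping selector regions on {chrom}: "
                        f"{a.region_id} [{a.start},{a.end}) and "
                        f"{b.region_id} [{b.start},{b.end})"
                    )
        self.regions: tuple[SelectorRegion, ...] = tuple(regions)
        self._by_id = {r.region_id: r for r in regions}

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.gene)
        return list(seen)

    @property
    def autosomal_ids(self) -> list[str]:
        return [r.region_id for r in self.regions if r.autosomal]

    def gene_region_ids(self, gene: str) -> list[str]:
        ids = [r.region_id for r in self.regions if r.gene == gene]
        if not ids:
            raise KeyError(f"gene {gene!r} not on selector")
        return ids

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, region_id: str) -> SelectorRegion:
        return self._by_id[region_id]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Selector) and self.regions == other.regions


class DepthMatrix:
    """Per-region mean sequencing depth for a set of samples.

    Wraps a DataFrame with regions as rows and samples as columns.
    Missing measurements are NaN (an explicit sentinel) — a depth of
    zero is a real observation and participates in normalization.
    """

    def __init__(self, data: pd.DataFrame, selector: Selector | None = None):
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValidationError("duplicate region or sample identifiers")
        values = data.to_numpy(dtype=float)
        if np.any(values[~np.isnan(values)] < 0):
            raise ValidationError("depth values must be non-negative")
        if selector is not None and list(data.index) != selector.region_ids:
            raise ValidationError("depth matrix rows do not match selector region order")
        self.data = data.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def regions(self) -> list[str]:
        return list(self.data.index)

    def sample(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class VariantCall:
    """One observed variant in one plasma sample."""

    sample_id: str
    patient_id: str
    timepoint_label: str
    gene: str
    variant_label: str
    variant_class: str
    vaf: float
    depth: int
    alt_reads: int
    effect: str = "nonsynonymous"
    blacklisted: bool = False

    def __post_init__(self) -> None:
        if self.timepoint_label not in TIMEPOINT_LABELS:
            raise ValidationError(
                f"unknown timepoint label {self.timepoint_label!r} "
                f"(expected one of {TIMEPOINT_LABELS})"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant class {self.variant_class!r}")
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"VAF {self.vaf} outside [0, 1]")
        if self.alt_reads > self.depth:
            raise ValidationError(
                f"{self.sample_id} {self.variant_label}: alt_reads "
                f"{self.alt_reads} > depth {self.depth}"
            )
        if self.depth > 0 and self.alt_reads > 0:
            if abs(self.vaf - self.alt_reads / self.depth) > 1e-6:
                raise ValidationError(
                    f"{self.sample_id} {self.variant_label}: vaf {self.vaf} "
                    f"inconsistent with alt_reads/depth "
                    f"{self.alt_reads / self.depth:.8f}"
                )

    @property
    def detected(self) -> bool:
        return self.alt_reads > 0


@dataclass(frozen=True)
class Timepoint:
    label: str
    day: int
    depth_sample_id: str
    variants: tuple[VariantCall, ...] = ()


@dataclass
class PatientRecord:
    """Longitudinal plasma series plus the clinical endpoints used here."""

    patient_id: str
    timepoints: list[Timepoint]
    pfs_days: float
    progression_event: bool
    best_response_pct: float | None = None
    met_fish_status: str = "unknown"

    def __post_init__(self) -> None:
        days = [tp.day for tp in self.timepoints]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(
                f"{self.patient_id}: timepoint days must be strictly increasing"
            )
        for label in ("pretreatment", "progression"):
            if sum(tp.label == label for tp in self.timepoints) > 1:
                raise ValidationError(
                    f"{self.patient_id}: more than one {label} timepoint"
                )
        if self.pfs_days < 0:
            raise ValidationError(f"{self.patient_id}: negative PFS")
        if self.met_fish_status not in ("positive", "negative", "unknown"):
            raise ValidationError(
                f"{self.patient_id}: bad met_fish_status {self.met_fish_status!r}"
            )

    def timepoint(self, label: str) -> Timepoint | None:
        for tp in self.timepoints:
            if tp.label == label:
                return tp
        return None


@dataclass
class StudyBundle:
    """Everything one analysis run consumes, cross-validated."""

    selector: Selector
    control_depths: DepthMatrix | None
    patient_depths: DepthMatrix | None
    patients: list[PatientRecord] = field(default_factory=list)
    blacklist: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        known: set[str] = set()
        if self.patient_depths is not None:
            known |= set(self.patient_depths.samples)
        for p in self.patients:
            for tp in p.timepoints:
                if self.patient_depths is not None and tp.depth_sample_id not in known:
                    raise ValidationError(
                        f"{p.patient_id}: depth sample {tp.depth_sample_id!r} "
                        "not present in any depth matrix"
                    )
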