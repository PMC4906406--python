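"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a targeted NSCLC capture panel sequenced to deep
coverage in plasma: a selector of non-contiguous regions over a set of
genes, healthy-control cfDNA whose per-region normalized log2 depths
are normal with a fixed per-region capture efficiency, tumour samples
that dilute gene-level copy-number events and clonal/subclonal SNVs
into a control background at a given ctDNA fraction, and longitudinal
patient series realizing named selection scenarios.

Depth model: depth(s, i) = mean_depth * e_i * 2**(sigma_log2 * eps),
with e_i a per-region efficiency drawn once per selector and eps
standard normal per (sample, region). A tumour at fraction f multiplies
the depth of regions in gene g by (1 - f) + f * CN_g / 2. The expected
VAF of a variant carried on m copies per tumour cell in a clone that is
fraction c of the tumour is

    E[VAF] = f * c * m / (2 * (1 - f) + f * CN_g)

so a heterozygous truncal variant in a copy-neutral gene has E[VAF]
= f / 2. Alt reads are drawn binomially at the realized region depth
(optionally beta-binomially via the overdispersion knob).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import ValidationError, derive_seed
from .datatypes import (
    DepthMatrix,
    PatientRecord,
    Selector,
    SelectorRegion,
    Timepoint,
    VariantCall,
)

#: ballast panel genes mimicking the breadth of a recurrently-mutated
#: NSCLC selector: genes under copy-number test must be a small share of
#: the autosomal regions, or amplifications would drag the selector-wide
#: median used for normalization
_BALLAST_GENES: tuple[str, ...] = (
    "ALK", "ROS1", "RET", "BRCA1", "BRCA2", "NOTCH1", "NF1", "PTEN",
    "STK11", "KEAP1", "SMAD4", "ARID1A", "ATM", "APC", "CDK4", "CDK6",
    "CCND1", "MYC", "FGFR1", "FGFR2", "FGFR3", "ERBB3", "ERBB4", "AKT1",
    "MTOR", "JAK2", "KIT", "PDGFRA", "SMO", "CTNNB1",
)

#: default panel: gene -> region count (>= 10 EGFR regions; TP53 is the
#: designated truncal-marker gene); 242 regions over 40 genes
DEFAULT_GENES: tuple[tuple[str, int], ...] = (
    ("EGFR", 12), ("MET", 10), ("ERBB2", 8), ("TP53", 5), ("KRAS", 6),
    ("PIK3CA", 6), ("BRAF", 4), ("CDKN2A", 4), ("NRAS", 3), ("RB1", 4),
) + tuple((g, 6) for g in _BALLAST_GENES)

_GENE_CHROMS = {
    "EGFR": "chr7", "MET": "chr7", "BRAF": "chr7", "ERBB2": "chr17",
    "TP53": "chr17", "KRAS": "chr12", "PIK3CA": "chr3", "CDKN2A": "chr9",
    "NRAS": "chr1", "RB1": "chr13", "AR": "chrX",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the control design the analysis was built for:
    27 healthy plasma controls at ~5,500x median depth with per-region
    log2 depth noise of 0.10.
    """

    n_controls: int = 27
    mean_depth: float = 5500.0
    sigma_log2: float = 0.10
    genes: tuple[tuple[str, int], ...] = DEFAULT_GENES
    capture_bias_sd: float = 0.25
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValidationError("n_controls must be >= 2")
        if self.sigma_log2 <= 0:
            raise ValidationError("sigma_log2 must be > 0")
        if any(n < 1 for _, n in self.genes):
            raise ValidationError("every gene needs at least one region")


@dataclass(frozen=True)
class PlannedVariant:
    """A variant planted in a tumour clone.

    mutant_copies is the number of copies per tumour cell carrying the
    variant (1 = heterozygous in a copy-neutral gene; CN = every
    amplified copy mutant).
    """

    gene: str
    label: str
    variant_class: str = "other"
    effect: str = "nonsynonymous"
    mutant_copies: float = 1.0


@dataclass(frozen=True)
class Clone:
    fraction: float  # fraction of the tumour occupied by this clone
    variants: tuple[PlannedVariant, ...] = ()


@dataclass(frozen=True)
class TumourProfile:
    """Copy-number events plus clone structure of one tumour."""

    cn_events: Mapping[str, float] = field(default_factory=dict)
    clones: tuple[Clone, ...] = ()
    truncal_variants: tuple[PlannedVariant, ...] = ()

    def __post_init__(self) -> None:
        if any(cn < 0 for cn in self.cn_events.values()):
            raise ValidationError("copy numbers must be >= 0")
        fracs = [c.fraction for c in self.clones]
        if any(not 0 < fr <= 1 for fr in fracs):
            raise ValidationError("clone fractions must lie in (0, 1]")
        if sum(fracs) > 1 + 1e-9:
            raise ValidationError("clone fractions sum above 1")

    def gene_cn(self, gene: str) -> float:
        return float(self.cn_events.get(gene, 2.0))


# ----------------------------------------------------------------- selector

def gen_selector(genes: Sequence[tuple[str, int]] = DEFAULT_GENES,
                 seed: int = 0) -> Selector:
    """Deterministic non-overlapping selector over the given genes."""
    if not genes:
        raise ValidationError("empty gene list")
    rng = np.random.default_rng(derive_seed(seed, "selector"))
    regions: list[SelectorRegion] = []
    cursors: dict[str, int] = {}
    for gene, n_regions in genes:
        if n_regions < 1:
            raise ValidationError(f"{gene}: region count must be >= 1")
        chrom = _GENE_CHROMS.get(gene, f"chr{(abs(hash(gene)) % 20) + 1}")
        pos = cursors.get(chrom, 1_000_000)
        for i in range(n_regions):
            length = int(rng.integers(120, 500))
            gap = int(rng.integers(500, 5_000))
            start = pos + gap
            regions.append(SelectorRegion(
                region_id=f"{gene}|{i}", gene=gene, chrom=chrom,
                start=start, end=start + length,
                autosomal=chrom not in ("chrX", "chrY"),
            ))
            pos = start + length
        cursors[chrom] = pos + 100_000
    return Selector(regions)


def capture_efficiencies(selector: Selector, config: SimulationConfig) -> pd.Series:
    """Fixed per-region efficiency, drawn once per (selector, seed)."""
    rng = np.random.default_rng(derive_seed(config.seed, "capture"))
    e = np.power(2.0, rng.normal(0.0, config.capture_bias_sd, size=len(selector)))
    return pd.Series(e, index=selector.region_ids)


# ----------------------------------------------------------------- cohorts

def _noise_factor(rng: np.random.Generator, sigma: float, size: int) -> np.ndarray:
    return np.power(2.0, sigma * rng.standard_normal(size))


def gen_control_cohort(selector: Selector, config: SimulationConfig,
                       n: int | None = None, cohort: str = "control",
                       prefix: str = "CTRL") -> DepthMatrix:
    """Healthy-control depth matrix; one seeded stream per sample."""
    n = config.n_controls if n is None else n
    if n < 2:
        raise ValidationError("control cohort needs >= 2 samples")
    eff = capture_efficiencies(selector, config).to_numpy()
    cols = {}
    for k in range(n):
        rng = np.random.default_rng(derive_seed(config.seed, cohort, k))
        noise = _noise_factor(rng, config.sigma_log2, len(selector))
        cols[f"{prefix}{k:03d}"] = config.mean_depth * eff * noise
    return DepthMatrix(pd.DataFrame(cols, index=selector.region_ids), selector)


def _draw_alt_reads(rng: np.random.Generator, depth: int, p: float,
                    overdispersion: float) -> int:
    p = min(max(p, 0.0), 1.0)
    if depth == 0 or p == 0.0:
        return 0
    if overdispersion > 0:
        rho = overdispersion
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        p = rng.beta(max(a, 1e-12), max(b, 1e-12))
    return int(rng.binomial(depth, p))


def gen_tumour_sample(selector: Selector, profile: TumourProfile,
                      tumour_fraction: float, config: SimulationConfig, *,
                      sample_id: str = "TUM000", patient_id: str = "P0",
                      timepoint_label: str = "pretreatment",
                      seed_tokens: tuple = ()) -> tuple[pd.Series, list[VariantCall]]:
    """One plasma sample: ctDNA at fraction f mixed with normal cfDNA.

    Returns the depth row and the variant observations (planned variants
    with zero supporting reads are emitted too, carrying their locus
    depth, so downstream censoring logic can see them).
    """
    if not 0.0 <= tumour_fraction <= 1.0:
        raise ValidationError("tumour fraction must lie in [0, 1]")
    f = tumour_fraction
    rng = np.random.default_rng(
        derive_seed(config.seed, "tumour", sample_id, *seed_tokens))
    eff = capture_efficiencies(selector, config).to_numpy()
    rel = np.array([
        (1.0 - f) + f * profile.gene_cn(r.gene) / 2.0 for r in selector.regions
    ])
    noise = _noise_factor(rng, config.sigma_log2, len(selector))
    depth_row = pd.Series(config.mean_depth * eff * rel * noise,
                          index=selector.region_ids)

    planned: list[tuple[float, PlannedVariant]] = [
        (1.0, v) for v in profile.truncal_variants
    ]
    planned += [(cl.fraction, v) for cl in profile.clones for v in cl.variants]

    calls: list[VariantCall] = []
    for clone_fraction, v in planned:
        cn_g = profile.gene_cn(v.gene)
        denom = 2.0 * (1.0 - f) + f * cn_g
        expected_vaf = 0.0 if denom <= 0 else f * clone_fraction * v.mutant_copies / denom
        locus = selector.gene_region_ids(v.gene)[0]
        locus_depth = int(round(depth_row.loc[locus]))
        alt = _draw_alt_reads(rng, locus_depth, expected_vaf, config.overdispersion)
        calls.append(VariantCall(
            sample_id=sample_id, patient_id=patient_id,
            timepoint_label=timepoint_label, gene=v.gene, variant_label=v.label,
            variant_class=v.variant_class,
            vaf=(alt / locus_depth if locus_depth else 0.0),
            depth=locus_depth, alt_reads=alt, effect=v.effect,
        ))
    return depth_row, calls


# ------------------------------------------------------------- longitudinal

SCENARIOS = ("t790m_depletion", "emergent_met", "increasing_snv",
             "mixed_mechanisms", "null")

#: ground-truth mechanism: (alteration label, type, evidence)
Truth = tuple[str, str, str]


@dataclass
class PatientSeries:
    """A generated longitudinal patient plus its planted ground truth."""

    patient: PatientRecord
    depths: pd.DataFrame  # regions x one column per timepoint sample
    truth: list[Truth]
    scenario: str


_ACTIVATING = PlannedVariant("EGFR", "EGFR L858R", "activating", mutant_copies=1)
_T790M = PlannedVariant("EGFR", "EGFR T790M", "T790M", mutant_copies=1)
_TP53 = PlannedVariant("TP53", "TP53 R273H", "truncal_TP53", mutant_copies=1)


def _series_profiles(scenario: str, prm: dict, rng: np.random.Generator
                     ) -> tuple[TumourProfile, TumourProfile, list[Truth]]:
    """Pretreatment and progression tumour profiles plus planted truth."""
    c_pre = float(rng.uniform(0.5, 0.95))
    truncal = (_TP53, _ACTIVATING)

    if scenario == "t790m_depletion":
        c_prog = c_pre * float(rng.uniform(
            prm.get("depletion_low", 0.20), prm.get("depletion_high", 0.45)))
        pre = TumourProfile(clones=(Clone(c_pre, (_T790M,)),),
                            truncal_variants=truncal)
        prog = TumourProfile(clones=(Clone(c_prog, (_T790M,)),),
                             truncal_variants=truncal)
        return pre, prog, []

    if scenario == "emergent_met":
        met_cn = float(prm.get("met_cn", 9.0))
        pre = TumourProfile(clones=(Clone(c_pre, (_T790M,)),),
                            truncal_variants=truncal)
        prog = TumourProfile(cn_events={"MET": met_cn},
                             clones=(Clone(c_pre, (_T790M,)),),
                             truncal_variants=truncal)
        return pre, prog, [("MET", "SCNA", "emergent")]

    if scenario == "increasing_snv":
        snv = PlannedVariant("PIK3CA", "PIK3CA E545K", "other")
        c_t790m = float(rng.uniform(0.30, 0.55))  # leave room for the subclone
        c_lo = float(prm.get("snv_pre_fraction", 0.10))
        c_hi = float(prm.get("snv_prog_fraction", 0.40))
        pre = TumourProfile(clones=(Clone(c_t790m, (_T790M,)), Clone(c_lo, (snv,))),
                            truncal_variants=truncal)
        prog = TumourProfile(clones=(Clone(c_t790m, (_T790M,)), Clone(c_hi, (snv,))),
                             truncal_variants=truncal)
        return pre, prog, [("PIK3CA E545K", "SNV", "increasing")]

    if scenario == "mixed_mechanisms":
        kras = PlannedVariant("KRAS", "KRAS G12A", "other")
        c_t790m = float(rng.uniform(0.30, 0.55))
        pre = TumourProfile(cn_events={"MET": float(prm.get("met_cn_pre", 4.0))},
                            clones=(Clone(c_t790m, (_T790M,)),),
                            truncal_variants=truncal)
        prog = TumourProfile(cn_events={"MET": float(prm.get("met_cn_prog", 9.0))},
                             clones=(Clone(c_t790m, (_T790M,)), Clone(0.4, (kras,))),
                             truncal_variants=truncal)
        return pre, prog, [("MET", "SCNA", "increasing"),
                           ("KRAS G12A", "SNV", "emergent")]

    if scenario == "null":
        pre = TumourProfile(clones=(Clone(c_pre, (_T790M,)),),
                            truncal_variants=truncal)
        return pre, pre, []

    raise ValidationError(f"unknown scenario {scenario!r} (choose from {SCENARIOS})")


def gen_patient_series(scenario: str, params: dict | None = None,
                       seed: int = 0, patient_id: str = "P0",
                       config: SimulationConfig | None = None) -> PatientSeries:
    """Pre / on-treatment / progression plasma series for one scenario.

    Ground-truth mechanism labels ride along for recovery testing.
    """
    prm = dict(params or {})
    config = config or SimulationConfig(seed=seed)
    if config.seed != seed:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(derive_seed(seed, "series", patient_id))
    pre_profile, prog_profile, truth = _series_profiles(scenario, prm, rng)

    f_pre = float(prm.get("f_pre", rng.uniform(0.05, 0.20)))
    f_on = float(prm.get("f_on", f_pre * rng.uniform(0.05, 0.30)))
    f_prog = float(prm.get("f_prog", rng.uniform(0.05, 0.20)))
    pfs_days = float(prm.get("pfs_days", 168.0))
    prog_day = int(prm.get("progression_day", max(int(pfs_days), 43)))
    best_response = prm.get("best_response_pct",
                            float(rng.uniform(-60.0, -10.0)))

    selector = prm.get("selector") or gen_selector(config.genes, seed=config.seed)
    plan = [
        ("pretreatment", 0, f_pre, pre_profile),
        ("on_treatment", 21, f_on, pre_profile),
        ("progression", prog_day, f_prog, prog_profile),
    ]
    depth_cols = {}
    timepoints = []
    for label, day, f, profile in plan:
        sample_id = f"{patient_id}_{label}"
        depth_row, calls = gen_tumour_sample(
            selector, profile, f, config, sample_id=sample_id,
            patient_id=patient_id, timepoint_label=label,
            seed_tokens=(patient_id, label))
        depth_cols[sample_id] = depth_row
        timepoints.append(Timepoint(label=label, day=day,
                                    depth_sample_id=sample_id,
                                    variants=tuple(calls)))
    record = PatientRecord(
        patient_id=patient_id, timepoints=timepoints, pfs_days=pfs_days,
        progression_event=bool(prm.get("progression_event", True)),
        best_response_pct=best_response,
        met_fish_status=prm.get("met_fish_status", "unknown"),
    )
    return PatientSeries(
        patient=record,
        depths=pd.DataFrame(depth_cols, index=selector.region_ids),
        truth=truth, scenario=scenario,
    )
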