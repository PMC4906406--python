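"""Readers and writers for the plain-text study formats.

Files
-----
selector.bed      BED4; name field is ``GENE|index`` and doubles as region_id.
depths.tsv        regions x samples; first column ``region_id``, one column
                  per sample; empty cells are explicit missing values.
variants.tsv      one row per observed variant per sample.
timepoints.tsv    (optional) sample_id/patient_id/timepoint/day registry, so
                  that plasma samples with zero detected variants still exist.
patients.tsv      clinical endpoints per patient.
blacklist.tsv     population-variant blacklist keyed by (gene, variant).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import FormatError, ValidationError, config_hash
from .datatypes import (
    DepthMatrix,
    PatientRecord,
    Selector,
    SelectorRegion,
    SEX_CHROMS,
    StudyBundle,
    Timepoint,
    VariantCall,
)

VARIANT_COLUMNS = [
    "sample_id", "patient_id", "timepoint", "day", "gene", "variant",
    "class", "vaf", "depth", "alt_reads", "effect", "blacklisted",
]
PATIENT_COLUMNS = [
    "patient_id", "pfs_days", "progression_event", "best_response_pct",
    "met_fish_status",
]


# ---------------------------------------------------------------- selector

def read_selector_bed(path: str | Path) -> Selector:
    path = Path(path)
    regions: list[SelectorRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: BED line needs 4 columns, got {len(fields)}"
                )
            chrom, start, end, name = fields[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            gene = name.split("|", 1)[0]
            try:
                regions.append(
                    SelectorRegion(
                        region_id=name,
                        gene=gene,
                        chrom=chrom,
                        start=start_i,
                        end=end_i,
                        autosomal=chrom not in SEX_CHROMS,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return Selector(regions)


def write_selector_bed(selector: Selector, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in selector.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ------------------------------------------------------------ depth matrix

def read_depth_tsv(path: str | Path, selector: Selector | None = None) -> DepthMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "region_id":
        raise FormatError(f"{path}: first column must be 'region_id'")
    df = df.set_index("region_id")
    df.index.name = None
    return DepthMatrix(df.astype(float), selector=selector)


def write_depth_tsv(matrix: DepthMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "region_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------- variants

def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes")


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "blacklisted" not in df.columns:
        df["blacklisted"] = "false"
    return df


def variant_calls_from_frame(df: pd.DataFrame, source: str = "variants.tsv"
                             ) -> list[VariantCall]:
    calls: list[VariantCall] = []
    for i, row in df.iterrows():
        try:
            calls.append(
                VariantCall(
                    sample_id=row["sample_id"],
                    patient_id=row["patient_id"],
                    timepoint_label=row["timepoint"],
                    gene=row["gene"],
                    variant_label=row["variant"],
                    variant_class=row["class"],
                    vaf=float(row["vaf"]),
                    depth=int(row["depth"]),
                    alt_reads=int(row["alt_reads"]),
                    effect=row["effect"],
                    blacklisted=_parse_bool(row["blacklisted"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{source}, row {i + 2}: {exc}") from exc
    return calls


def write_variants_tsv(calls: Iterable[VariantCall], path: str | Path,
                       days: Mapping[tuple[str, str], int] | None = None) -> None:
    """`days` maps (sample_id, timepoint) -> day; defaults to 0."""
    rows = []
    for c in calls:
        day = 0 if days is None else days.get((c.sample_id, c.timepoint_label), 0)
        rows.append({
            "sample_id": c.sample_id, "patient_id": c.patient_id,
            "timepoint": c.timepoint_label, "day": day, "gene": c.gene,
            "variant": c.variant_label, "class": c.variant_class,
            "vaf": repr(c.vaf), "depth": c.depth, "alt_reads": c.alt_reads,
            "effect": c.effect, "blacklisted": str(c.blacklisted).lower(),
        })
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- patients

def read_patients_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_timepoints_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "patient_id", "timepoint", "day"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def write_patients_tsv(patients: Sequence[PatientRecord], path: str | Path) -> None:
    rows = []
    for p in patients:
        rows.append({
            "patient_id": p.patient_id,
            "pfs_days": f"{p.pfs_days:g}",
            "progression_event": str(p.progression_event).lower(),
            "best_response_pct": "" if p.best_response_pct is None
                                 else f"{p.best_response_pct:g}",
            "met_fish_status": p.met_fish_status,
        })
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_timepoints_tsv(patients: Sequence[PatientRecord], path: str | Path) -> None:
    rows = []
    for p in patients:
        for tp in p.timepoints:
            rows.append({
                "sample_id": tp.depth_sample_id, "patient_id": p.patient_id,
                "timepoint": tp.label, "day": tp.day,
            })
    pd.DataFrame(rows, columns=["sample_id", "patient_id", "timepoint", "day"]
                 ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- blacklist

def read_blacklist_tsv(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene", "variant"}.issubset(df.columns):
        raise FormatError(f"{path}: blacklist needs 'gene' and 'variant' columns")
    return {(row["gene"], row["variant"]) for _, row in df.iterrows()}


def write_blacklist_tsv(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    rows = sorted(entries)
    pd.DataFrame(rows, columns=["gene", "variant"]).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- study load

def _build_patients(variants_df: pd.DataFrame, patients_df: pd.DataFrame,
                    timepoints_df: pd.DataFrame | None) -> list[PatientRecord]:
    calls = variant_calls_from_frame(variants_df)
    by_sample: dict[str, list[VariantCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)

    # timepoint registry: explicit file wins, else derived from variant rows
    registry: dict[str, list[tuple[str, int, str]]] = {}
    if timepoints_df is not None:
        src = timepoints_df
    else:
        src = variants_df[["sample_id", "patient_id", "timepoint", "day"]].drop_duplicates()
    for _, row in src.iterrows():
        registry.setdefault(row["patient_id"], []).append(
            (row["sample_id"], int(row["day"]), row["timepoint"])
        )

    patients: list[PatientRecord] = []
    for _, row in patients_df.iterrows():
        pid = row["patient_id"]
        tps = []
        for sample_id, day, label in sorted(registry.get(pid, []), key=lambda t: t[1]):
            tps.append(Timepoint(
                label=label, day=day, depth_sample_id=sample_id,
                variants=tuple(by_sample.get(sample_id, ())),
            ))
        patients.append(PatientRecord(
            patient_id=pid,
            timepoints=tps,
            pfs_days=float(row["pfs_days"]),
            progression_event=_parse_bool(row["progression_event"]),
            best_response_pct=(None if row["best_response_pct"] == ""
                               else float(row["best_response_pct"])),
            met_fish_status=row["met_fish_status"] or "unknown",
        ))
    return patients


def load_study(paths: Mapping[str, str | Path]) -> StudyBundle:
    """Load and cross-validate a study directory.

    `paths` keys: selector (required), control_depths, patient_depths,
    variants, patients, timepoints, blacklist (all optional).
    """
    selector = read_selector_bed(paths["selector"])
    control = (read_depth_tsv(paths["control_depths"], selector)
               if "control_depths" in paths else None)
    patient_depths = (read_depth_tsv(paths["patient_depths"], selector)
                      if "patient_depths" in paths else None)
    blacklist = (read_blacklist_tsv(paths["blacklist"])
                 if "blacklist" in paths else set())
    patients: list[PatientRecord] = []
    if "variants" in paths and "patients" in paths:
        variants_df = read_variants_tsv(paths["variants"])
        patients_df = read_patients_tsv(paths["patients"])
        timepoints_df = (read_timepoints_tsv(paths["timepoints"])
                         if "timepoints" in paths else None)
        patients = _build_patients(variants_df, patients_df, timepoints_df)
    return StudyBundle(
        selector=selector,
        control_depths=control,
        patient_depths=patient_depths,
        patients=patients,
        blacklist=blacklist,
    )


def load_study_dir(directory: str | Path) -> StudyBundle:
    """Convenience wrapper mapping conventional file names in a directory."""
    directory = Path(directory)
    names = {
        "selector": "selector.bed",
        "control_depths": "control_depths.tsv",
        "patient_depths": "patient_depths.tsv",
        "variants": "variants.tsv",
        "patients": "patients.tsv",
        "timepoints": "timepoints.tsv",
        "blacklist": "blacklist.tsv",
    }
    paths = {k: directory / v for k, v in names.items() if (directory / v).exists()}
    if "selector" not in paths:
        raise FormatError(f"{directory}: no selector.bed found")
    return load_study(paths)


# ------------------------------------------------------------ result dump

def write_results(destination: str | Path, *, scna_calls=None, ratios=None,
                  mechanisms=None, config: dict | None = None,
                  seed: int | None = None) -> list[Path]:
    """Write finalized result objects as deterministic, column-stable TSVs
    plus a run manifest. Accepts the dataclasses from the analysis modules
    or pre-built DataFrames; empty inputs yield header-only files.
    """
    from . import __version__
    from .scna import scna_calls_frame
    from .clonal import ratio_results_frame
    from .resistance import resistance_calls_frame

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(obj, to_frame, name):
        if obj is None:
            return
        frame = obj if isinstance(obj, pd.DataFrame) else to_frame(obj)
        path = dest / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.8g")
        written.append(path)

    _emit(scna_calls, scna_calls_frame, "scna_calls.tsv")
    _emit(ratios, ratio_results_frame, "ratios.tsv")
    _emit(mechanisms, resistance_calls_frame, "mechanisms.tsv")

    manifest = {
        "package": "ctdnaprof",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "config": config or {},
        "outputs": sorted(p.name for p in written),
    }
    manifest_path = dest / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written
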