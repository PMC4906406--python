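"""Depth-based somatic copy-number calling for targeted capture panels.

The statistic
-------------
For each sample, per-region mean depths are normalized to the
selector-wide autosomal median and log2-transformed ("normalized
depth"). A control cohort of healthy plasma samples provides per-region
means mu_i and standard deviations sigma_i of normalized depth, giving
per-region z-scores for a test sample:

    z_i = (d_i - mu_i) / sigma_i

These are combined per gene g, in the manner of Stouffer's unweighted
combination, into a copy-number index

    C_g = sum_{i in g} z_i / sqrt(n_g)

where n_g is the number of included regions covering g. Because
neighbouring capture regions are not independent, C_g is not treated as
a meta-z-score: its detection threshold t_g is calibrated empirically
as the smallest observed control index for which the control
false-positive rate is below a target alpha (default 0.05). A gain is
called when C_g >= t_g.

For a called gain, the linear relative depth r (mean over the gene's
regions of 2**(d_i - mu_i), i.e. the excess over the control baseline;
diploid baseline 1) inverts the ctDNA mixture model
r = (1 - f) + f * CN / 2 to give the normalized copy number — the mean
copy number across the DNA-contributing cells:

    CN = 2 + 2 (r - 1) / f

with f the tumour (ctDNA) fraction of the sample.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import ValidationError
from .datatypes import DepthMatrix, Selector


# ------------------------------------------------------------ primitives

def normalize_depth(depth_row: pd.Series, selector: Selector) -> pd.Series:
    """log2 of depth over the selector-wide autosomal median depth.

    Regions with zero depth map to -inf, an explicit sentinel excluded
    downstream. Raises if the autosomal median is zero.
    """
    row = depth_row.reindex(selector.region_ids)
    auto = row.loc[selector.autosomal_ids].to_numpy(dtype=float)
    auto = auto[~np.isnan(auto)]
    if auto.size == 0 or np.nanmax(auto) <= 0:
        raise ValidationError("all autosomal depths are zero or missing")
    med = float(np.median(auto))
    if med <= 0:
        raise ValidationError("autosomal median depth is zero")
    with np.errstate(divide="ignore"):
        return pd.Series(np.log2(row.to_numpy(dtype=float) / med), index=row.index)


def calibrate_threshold(control_indices: Sequence[float], alpha: float = 0.05
                        ) -> tuple[float, bool]:
    """Smallest candidate threshold with control false-positive rate < alpha.

    Candidates are the observed control index values; the detection rule
    is C >= t, so FPR(t) = #{C >= t} / N. If no observed value
    qualifies, the threshold is a sentinel just above the maximum
    (FPR 0) and the result is flagged.

    Returns (threshold, flagged).
    """
    values = np.asarray(list(control_indices), dtype=float)
    if values.size == 0:
        raise ValidationError("calibrate_threshold: empty control index set")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    n = values.size
    for cand in np.unique(values):
        if np.count_nonzero(values >= cand) / n < alpha:
            return float(cand), False
    vmax = float(values.max())
    return float(np.nextafter(vmax, math.inf)), True


def normalized_copy_number(relative_depth: float, tumour_fraction: float) -> float:
    """Mean copy number across DNA-contributing cells.

    Inverts r = (1 - f) + f * CN / 2; clipped below at 0 copies.
    """
    if tumour_fraction <= 0:
        raise ValidationError("normalized copy number undefined for f <= 0")
    cn = 2.0 + 2.0 * (relative_depth - 1.0) / tumour_fraction
    return max(cn, 0.0)


def region_zscores(normalized: pd.Series, model: "CopyNumberIndexModel") -> pd.Series:
    """Per-region z-scores against the fitted control model.

    Only regions included by the model appear in the output.
    """
    model._check_fitted()
    idx = model.included_regions_
    missing = [r for r in idx if r not in normalized.index]
    if missing:
        raise ValidationError(f"sample lacks model regions (e.g. {missing[:3]})")
    d = normalized.loc[idx].to_numpy(dtype=float)
    z = (d - model.mu_.loc[idx].to_numpy()) / model.sigma_.loc[idx].to_numpy()
    return pd.Series(z, index=idx)


def copy_number_index(zscores: pd.Series, gene: str,
                      model: "CopyNumberIndexModel") -> float:
    """C_g = sum of the gene's region z-scores / sqrt(region count)."""
    model._check_fitted()
    ids = model.gene_regions_.get(gene)
    if not ids:
        raise ValidationError(f"gene {gene!r} is uncallable (no included regions)")
    z = zscores.loc[ids].to_numpy(dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValidationError(f"non-finite z-scores for gene {gene!r}")
    return float(z.sum() / math.sqrt(len(ids)))


# ------------------------------------------------------------- call type

@dataclass(frozen=True)
class GeneCnCall:
    """Per-gene copy-number result for one sample."""

    gene: str
    index: float
    threshold: float
    significant: bool
    relative_depth: float
    normalized_cn: float | None
    conclusive: bool
    threshold_flagged: bool = False
    n_regions: int = 0


def scna_calls_frame(calls: Sequence[GeneCnCall]) -> pd.DataFrame:
    cols = ["gene", "index", "threshold", "significant", "relative_depth",
            "normalized_cn", "conclusive", "threshold_flagged", "n_regions"]
    rows = [{c: getattr(call, c) for c in cols} for call in calls]
    return pd.DataFrame(rows, columns=cols)


# ------------------------------------------------------------- estimator

class CopyNumberIndexModel(BaseEstimator):
    """Control-cohort depth model with empirically calibrated thresholds.

    scikit-learn style estimator: ``fit`` on a healthy-control depth
    matrix (regions x samples), then ``transform`` test samples to
    gene-level copy-number indices or ``predict`` per-gene significance.

    Parameters
    ----------
    selector : Selector
        Panel geometry; defines the gene -> region map and autosomal set.
    alpha : float, default 0.05
        Target control false-positive rate for threshold calibration.
    calibration : {"loo", "in_sample"}, default "loo"
        How the null control indices behind the thresholds are computed.
        "loo" scores each control against leave-one-out per-region
        means/sds, so the calibration indices are exchangeable with an
        unseen sample and the advertised false-positive rate holds out
        of sample. "in_sample" scores each control against the model
        fitted on the full cohort; with a small cohort this understates
        the null spread and the out-of-sample false-positive rate
        exceeds alpha.

    Fitted attributes (trailing underscore)
    ---------------------------------------
    mu_, sigma_ : per-region mean / sd of normalized log2 depth.
    normality_p_ : per-region Shapiro-Wilk p-value (QC metadata only).
    included_regions_, excluded_regions_ : sigma > 0 and finite vs not.
    gene_regions_ : gene -> included region ids.
    thresholds_ : gene -> calibrated t_g (sentinel above max when flagged).
    threshold_flagged_ : gene -> bool.
    uncallable_genes_ : genes with no included regions.
    control_indices_ : DataFrame gene x control sample of null indices.
    n_controls_ : number of control samples used.
    """

    def __init__(self, selector: Selector | None = None, alpha: float = 0.05,
                 calibration: str = "loo"):
        self.selector = selector
        self.alpha = alpha
        self.calibration = calibration

    # -- fitting -----------------------------------------------------

    def fit(self, X: DepthMatrix | pd.DataFrame, y=None) -> "CopyNumberIndexModel":
        if self.selector is None:
            raise ValidationError("CopyNumberIndexModel requires a selector")
        data = X.data if isinstance(X, DepthMatrix) else X
        if data.shape[1] < 2:
            raise ValidationError("at least 2 control samples required")
        norm = self._normalize_matrix(data)

        values = norm.to_numpy(dtype=float)
        finite = np.isfinite(values).all(axis=1)
        mu = np.where(finite, np.nanmean(np.where(np.isfinite(values), values, np.nan),
                                         axis=1), np.nan)
        sd = np.where(finite, np.nanstd(np.where(np.isfinite(values), values, np.nan),
                                        axis=1, ddof=1), np.nan)
        regions = list(norm.index)
        self.mu_ = pd.Series(mu, index=regions)
        self.sigma_ = pd.Series(sd, index=regions)

        included = [r for r, ok, s in zip(regions, finite, sd) if ok and s > 0]
        self.included_regions_ = included
        self.excluded_regions_ = [r for r in regions if r not in set(included)]

        pvals = {}
        for r in included:
            vec = norm.loc[r].to_numpy(dtype=float)
            # Shapiro-Wilk needs >= 3 observations and non-constant input
            pvals[r] = float(stats.shapiro(vec).pvalue) if len(vec) >= 3 else np.nan
        self.normality_p_ = pd.Series(pvals).reindex(included)

        incl = set(included)
        self.gene_regions_ = {
            g: [rid for rid in self.selector.gene_region_ids(g) if rid in incl]
            for g in self.selector.genes
        }
        self.uncallable_genes_ = [g for g, ids in self.gene_regions_.items() if not ids]

        self.n_controls_ = data.shape[1]
        if self.calibration == "loo":
            self.control_indices_ = self._loo_control_indices(norm)
        elif self.calibration == "in_sample":
            self.control_indices_ = self._indices_from_normalized(norm)
        else:
            raise ValidationError(f"unknown calibration mode {self.calibration!r}")
        self.thresholds_ = {}
        self.threshold_flagged_ = {}
        for g in self.selector.genes:
            if g in self.uncallable_genes_:
                self.thresholds_[g] = math.inf
                self.threshold_flagged_[g] = True
                continue
            t, flagged = calibrate_threshold(
                self.control_indices_.loc[g].to_numpy(), alpha=self.alpha)
            self.thresholds_[g] = t
            self.threshold_flagged_[g] = flagged
        return self

    def _normalize_matrix(self, data: pd.DataFrame) -> pd.DataFrame:
        cols = {s: normalize_depth(data[s], self.selector) for s in data.columns}
        return pd.DataFrame(cols, index=self.selector.region_ids)

    def _indices_from_normalized(self, norm: pd.DataFrame) -> pd.DataFrame:
        idx = self.included_regions_
        z = (norm.loc[idx].to_numpy(dtype=float)
             - self.mu_.loc[idx].to_numpy()[:, None]) \
            / self.sigma_.loc[idx].to_numpy()[:, None]
        zf = pd.DataFrame(z, index=idx, columns=norm.columns)
        out = {}
        for g, ids in self.gene_regions_.items():
            if ids:
                out[g] = zf.loc[ids].sum(axis=0) / math.sqrt(len(ids))
        return pd.DataFrame(out).T

    def _loo_control_indices(self, norm: pd.DataFrame) -> pd.DataFrame:
        """Each control scored against leave-one-out mu/sigma (closed form)."""
        idx = self.included_regions_
        x = norm.loc[idx].to_numpy(dtype=float)  # regions x samples
        n = x.shape[1]
        if n < 3:
            raise ValidationError("leave-one-out calibration needs >= 3 controls")
        mean = x.mean(axis=1, keepdims=True)
        ss = ((x - mean) ** 2).sum(axis=1, keepdims=True)
        loo_mean = (n * mean - x) / (n - 1)
        # sum of squares about the leave-one-out mean
        loo_ss = ss - (x - mean) ** 2 * n / (n - 1)
        loo_sd = np.sqrt(np.maximum(loo_ss, 0.0) / (n - 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (x - loo_mean) / loo_sd
        z[~np.isfinite(z)] = 0.0  # degenerate leave-one-out sd
        zf = pd.DataFrame(z, index=idx, columns=norm.columns)
        out = {}
        for g, ids in self.gene_regions_.items():
            if ids:
                out[g] = zf.loc[ids].sum(axis=0) / math.sqrt(len(ids))
        return pd.DataFrame(out).T

    def _check_fitted(self) -> None:
        if not hasattr(self, "mu_"):
            raise ValidationError("model is not fitted")

    # -- scoring -----------------------------------------------------

    def zscores(self, X: DepthMatrix | pd.DataFrame) -> pd.DataFrame:
        """Per-region z-scores for each sample column."""
        self._check_fitted()
        data = X.data if isinstance(X, DepthMatrix) else X
        norm = self._normalize_matrix(data)
        idx = self.included_regions_
        z = (norm.loc[idx].to_numpy(dtype=float)
             - self.mu_.loc[idx].to_numpy()[:, None]) \
            / self.sigma_.loc[idx].to_numpy()[:, None]
        return pd.DataFrame(z, index=idx, columns=data.columns)

    def transform(self, X: DepthMatrix | pd.DataFrame) -> pd.DataFrame:
        """Gene x sample matrix of copy-number indices."""
        self._check_fitted()
        data = X.data if isinstance(X, DepthMatrix) else X
        norm = self._normalize_matrix(data)
        return self._indices_from_normalized(norm)

    def predict(self, X: DepthMatrix | pd.DataFrame) -> pd.DataFrame:
        """Boolean gene x sample matrix: index at or above threshold."""
        indices = self.transform(X)
        thr = pd.Series(self.thresholds_).reindex(indices.index)
        return indices.ge(thr, axis=0)

    def relative_depths(self, X: DepthMatrix | pd.DataFrame) -> pd.DataFrame:
        """Gene x sample linear relative depth, diploid baseline 1.

        Mean over the gene's regions of 2**(d_i - mu_i): the excess of
        normalized depth over the control expectation, which cancels
        the fixed per-region capture efficiency.
        """
        self._check_fitted()
        data = X.data if isinstance(X, DepthMatrix) else X
        norm = self._normalize_matrix(data)
        out = {}
        for g, ids in self.gene_regions_.items():
            if ids:
                centered = norm.loc[ids].sub(self.mu_.loc[ids], axis=0)
                out[g] = np.power(2.0, centered).mean(axis=0)
        return pd.DataFrame(out).T

    # -- persistence --------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Versioned TSV/JSON store: regions.tsv, genes.tsv, model.json."""
        from . import __version__
        self._check_fitted()
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        regions = pd.DataFrame({
            "region_id": list(self.mu_.index),
            "mu": self.mu_.to_numpy(),
            "sigma": self.sigma_.to_numpy(),
            "shapiro_p": self.normality_p_.reindex(self.mu_.index).to_numpy(),
            "included": [r in set(self.included_regions_) for r in self.mu_.index],
        })
        regions.to_csv(d / "regions.tsv", sep="\t", index=False)
        genes = pd.DataFrame({
            "gene": list(self.thresholds_),
            "threshold": [self.thresholds_[g] for g in self.thresholds_],
            "flagged": [self.threshold_flagged_[g] for g in self.thresholds_],
            "n_regions": [len(self.gene_regions_.get(g, [])) for g in self.thresholds_],
        })
        genes.to_csv(d / "genes.tsv", sep="\t", index=False)
        meta = {"version": __version__, "alpha": self.alpha,
                "calibration": self.calibration,
                "n_controls": self.n_controls_,
                "control_indices": {g: list(map(float, row))
                                    for g, row in self.control_indices_.iterrows()}}
        (d / "model.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path, selector: Selector) -> "CopyNumberIndexModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        model = cls(selector=selector, alpha=meta["alpha"],
                    calibration=meta.get("calibration", "loo"))
        regions = pd.read_csv(d / "regions.tsv", sep="\t", dtype={"region_id": str},
                              float_precision="round_trip")
        model.mu_ = pd.Series(regions["mu"].to_numpy(), index=regions["region_id"])
        model.sigma_ = pd.Series(regions["sigma"].to_numpy(), index=regions["region_id"])
        model.normality_p_ = pd.Series(regions["shapiro_p"].to_numpy(),
                                       index=regions["region_id"])
        model.included_regions_ = list(regions.loc[regions["included"], "region_id"])
        incl = set(model.included_regions_)
        model.excluded_regions_ = [r for r in regions["region_id"] if r not in incl]
        model.gene_regions_ = {
            g: [rid for rid in selector.gene_region_ids(g) if rid in incl]
            for g in selector.genes
        }
        model.uncallable_genes_ = [g for g, ids in model.gene_regions_.items() if not ids]
        genes = pd.read_csv(d / "genes.tsv", sep="\t",
                            float_precision="round_trip")
        model.thresholds_ = dict(zip(genes["gene"], genes["threshold"].astype(float)))
        model.threshold_flagged_ = dict(zip(genes["gene"], genes["flagged"].astype(bool)))
        model.n_controls_ = int(meta["n_controls"])
        model.control_indices_ = pd.DataFrame(
            {g: vals for g, vals in meta["control_indices"].items()}).T
        return model


# -------------------------------------------------------------- high level

def call_scna(depth_row: pd.Series, model: CopyNumberIndexModel, *,
              ctdna_fraction: float | None = None,
              activating_raw_vaf: float | None = None,
              ctdna_gate_vaf: float = 0.02) -> list[GeneCnCall]:
    """Score one sample against the fitted control model, per gene.

    The conclusiveness gate reflects ctDNA adequacy: a sample whose
    truncal/activating raw VAF is below `ctdna_gate_vaf` cannot support
    a negative copy-number conclusion. Significance is still reported.
    Normalized copy number is filled only for significant calls when a
    tumour fraction is supplied.
    """
    model._check_fitted()
    norm = normalize_depth(depth_row, model.selector)
    z = region_zscores(norm, model)
    conclusive = True
    if activating_raw_vaf is not None:
        conclusive = activating_raw_vaf >= ctdna_gate_vaf

    calls: list[GeneCnCall] = []
    for gene in model.selector.genes:
        ids = model.gene_regions_.get(gene, [])
        if not ids:
            calls.append(GeneCnCall(
                gene=gene, index=math.nan, threshold=math.inf, significant=False,
                relative_depth=math.nan, normalized_cn=None, conclusive=conclusive,
                threshold_flagged=True, n_regions=0))
            continue
        c = copy_number_index(z, gene, model)
        t = model.thresholds_[gene]
        significant = c >= t
        centered = (norm.loc[ids].to_numpy(dtype=float)
                    - model.mu_.loc[ids].to_numpy(dtype=float))
        r = float(np.mean(np.power(2.0, centered)))
        cn = None
        if significant and ctdna_fraction is not None and ctdna_fraction > 0:
            cn = normalized_copy_number(r, ctdna_fraction)
        calls.append(GeneCnCall(
            gene=gene, index=c, threshold=t, significant=significant,
            relative_depth=r, normalized_cn=cn, conclusive=conclusive,
            threshold_flagged=model.threshold_flagged_[gene], n_regions=len(ids)))
    return calls


def fit_control_model(controls: DepthMatrix, selector: Selector,
                      alpha: float = 0.05,
                      calibration: str = "loo") -> CopyNumberIndexModel:
    """Functional wrapper over CopyNumberIndexModel.fit."""
    return CopyNumberIndexModel(selector=selector, alpha=alpha,
                                calibration=calibration).fit(controls)
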