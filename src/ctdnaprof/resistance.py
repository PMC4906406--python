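"""Rule-based resistance-mechanism calling and cohort comparisons.

An alteration counts as a putative resistance mechanism when it is
emergent (absent pretreatment, present at progression) or when its
relative abundance — the ratio of the alteration to the overall ctDNA
level — increases between pretreatment and progression. Two carry-
forward special cases keep pre-existing alterations on the list when
the progression sample cannot rule them out: a pre-existing gene-level
gain whose progression copy-number analysis is inconclusive (activating
VAF below the 2% gate), and a pre-existing SNV when progression plasma
has no detectable ctDNA at all.

Resistance timing is split at three months of progression-free
survival (innate < 3 months <= acquired), mechanism categories per
patient are {SCNA only, SCNA+SNV, SNV only, none}, and the innate
vs acquired category distribution is compared with the Freeman-Halton
exact extension of Fisher's test for an r x c contingency table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._utils import NotEvaluableError, ValidationError
from .clonal import CtdnaEstimate
from .datatypes import PatientRecord, VariantCall
from .scna import GeneCnCall

DAYS_PER_MONTH = 30.44
MECHANISM_CATEGORIES = ("SCNA_only", "SCNA_plus_SNV", "SNV_only", "none")


@dataclass(frozen=True)
class ResistanceCall:
    """One putative resistance mechanism in one patient."""

    patient_id: str
    alteration: str  # variant label for SNVs, gene symbol for SCNAs
    type: str  # SNV | SCNA
    evidence: str  # emergent | increasing | carried_forward
    pre_abundance: float
    post_abundance: float


def resistance_calls_frame(calls: Sequence[ResistanceCall]) -> pd.DataFrame:
    cols = ["patient_id", "alteration", "type", "evidence",
            "pre_abundance", "post_abundance"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in calls],
                        columns=cols)


# ------------------------------------------------------- relative abundance

def relative_abundance(vaf: float, ctdna: CtdnaEstimate) -> float:
    """SNV relative abundance: VAF over the raw truncal/anchoring VAF."""
    if not ctdna.available or ctdna.raw_truncal_vaf <= 0:
        raise NotEvaluableError("no truncal anchor for relative abundance")
    return vaf / ctdna.raw_truncal_vaf


def scna_relative_abundance(call: GeneCnCall) -> float | None:
    """SCNA relative abundance is the normalized copy number itself
    (already expressed per DNA-contributing cell)."""
    return call.normalized_cn


# ---------------------------------------------------------------- the rules

def call_resistance(patient_id: str,
                    pre_variants: Sequence[VariantCall],
                    prog_variants: Sequence[VariantCall],
                    pre_scna: Sequence[GeneCnCall],
                    prog_scna: Sequence[GeneCnCall],
                    ctdna_pre: CtdnaEstimate,
                    ctdna_prog: CtdnaEstimate,
                    fold_change: float = 1.0) -> list[ResistanceCall]:
    """Evaluate every candidate alteration against the selection rules.

    Variants are expected to be germline-filtered already. T790M and the
    activating EGFR mutation are excluded as candidates: they are the
    treatment target, not mechanisms of resistance to it.
    """
    calls: list[ResistanceCall] = []

    # ---- SNVs ----
    def _by_key(variants: Sequence[VariantCall]) -> dict[tuple[str, str], VariantCall]:
        out: dict[tuple[str, str], VariantCall] = {}
        for v in variants:
            if v.variant_class in ("activating", "T790M"):
                continue
            key = (v.gene, v.variant_label)
            if key not in out or v.vaf > out[key].vaf:
                out[key] = v
        return out

    pre_by, prog_by = _by_key(pre_variants), _by_key(prog_variants)
    no_ctdna_at_progression = not ctdna_prog.available

    for key in sorted(set(pre_by) | set(prog_by)):
        gene, label = key
        pre_v, prog_v = pre_by.get(key), prog_by.get(key)
        pre_detected = pre_v is not None and pre_v.detected
        prog_detected = prog_v is not None and prog_v.detected
        if not pre_detected and prog_detected:
            try:
                post = relative_abundance(prog_v.vaf, ctdna_prog)
            except NotEvaluableError:
                post = prog_v.vaf
            calls.append(ResistanceCall(patient_id, label, "SNV", "emergent",
                                        0.0, post))
        elif pre_detected and prog_detected:
            try:
                pre_ra = relative_abundance(pre_v.vaf, ctdna_pre)
                post_ra = relative_abundance(prog_v.vaf, ctdna_prog)
            except NotEvaluableError:
                continue
            if post_ra > fold_change * pre_ra:
                calls.append(ResistanceCall(patient_id, label, "SNV",
                                            "increasing", pre_ra, post_ra))
        elif pre_detected and no_ctdna_at_progression:
            pre_ra: float
            try:
                pre_ra = relative_abundance(pre_v.vaf, ctdna_pre)
            except NotEvaluableError:
                pre_ra = pre_v.vaf
            calls.append(ResistanceCall(patient_id, label, "SNV",
                                        "carried_forward", pre_ra, 0.0))

    # ---- SCNAs ----
    pre_cn = {c.gene: c for c in pre_scna}
    prog_cn = {c.gene: c for c in prog_scna}
    for gene in sorted(set(pre_cn) | set(prog_cn)):
        pc, gc = pre_cn.get(gene), prog_cn.get(gene)
        sig_pre = pc is not None and pc.significant
        sig_prog = gc is not None and gc.significant
        if not sig_pre and sig_prog and gc.conclusive:
            calls.append(ResistanceCall(
                patient_id, gene, "SCNA", "emergent", 0.0,
                gc.normalized_cn if gc.normalized_cn is not None else gc.relative_depth))
        elif sig_pre and sig_prog:
            pre_ab = scna_relative_abundance(pc)
            post_ab = scna_relative_abundance(gc)
            if pre_ab is not None and post_ab is not None \
                    and post_ab > fold_change * pre_ab:
                calls.append(ResistanceCall(patient_id, gene, "SCNA",
                                            "increasing", pre_ab, post_ab))
        elif sig_pre and gc is not None and not gc.conclusive:
            pre_ab = scna_relative_abundance(pc)
            calls.append(ResistanceCall(
                patient_id, gene, "SCNA", "carried_forward",
                pre_ab if pre_ab is not None else pc.relative_depth, 0.0))
    return calls


def classify_timing(pfs_days: float, split_months: float = 3.0,
                    days_per_month: float = DAYS_PER_MONTH) -> str:
    """Innate resistance = progression before `split_months` months.

    The exact boundary is assigned to acquired.
    """
    if pfs_days < 0:
        raise ValidationError("PFS must be non-negative")
    months = pfs_days / days_per_month
    # guard float rounding so an exact split lands on the acquired side
    return "innate" if months < split_months - 1e-9 else "acquired"


def categorize_mechanisms(calls: Iterable[ResistanceCall]) -> str:
    types = {c.type for c in calls}
    if types == {"SCNA"}:
        return "SCNA_only"
    if types == {"SNV"}:
        return "SNV_only"
    if types == {"SCNA", "SNV"}:
        return "SCNA_plus_SNV"
    return "none"


# --------------------------------------------------------- exact r x c test

def _table_logprob(cells, log_margin_const: float) -> float:
    return log_margin_const - sum(math.lgamma(v + 1.0) for v in cells)


def _enumerate_margin_tables(rows: tuple[int, ...], cols: tuple[int, ...],
                             max_tables: int):
    """Yield every non-negative integer matrix with the given margins."""
    n_r, n_c = len(rows), len(cols)
    count = 0

    def rec(r: int, remaining_cols: tuple[int, ...], acc: list[tuple[int, ...]]):
        nonlocal count
        if r == n_r - 1:
            if all(v >= 0 for v in remaining_cols) and sum(remaining_cols) == rows[r]:
                count += 1
                if count > max_tables:
                    raise ValidationError(
                        "margin enumeration exceeds the table guard; "
                        "use method='monte_carlo'")
                yield acc + [remaining_cols]
            return

        def fill(c: int, left: int, row_acc: list[int]):
            if c == n_c - 1:
                if 0 <= left <= remaining_cols[c]:
                    yield row_acc + [left]
                return
            for v in range(min(left, remaining_cols[c]) + 1):
                yield from fill(c + 1, left - v, row_acc + [v])

        for row in fill(0, rows[r], []):
            rest = tuple(rc - v for rc, v in zip(remaining_cols, row))
            yield from rec(r + 1, rest, acc + [tuple(row)])

    yield from rec(0, cols, [])


def freeman_halton_p(table, *, method: str = "exact", tie_tol: float = 1e-7,
                     max_tables: int = 10**7, n_resamples: int = 100_000,
                     seed: int | None = None) -> float:
    """Exact p-value of the Freeman-Halton extension of Fisher's test.

    Conditional on the observed margins, every table is weighted by its
    multivariate hypergeometric probability; the (two-sided,
    probability-ordered) p-value sums the probabilities of all tables
    no more probable than the observed one, with a small relative
    tolerance guarding floating-point ties. For 2 x 2 input this reduces
    to the classical two-sided Fisher test.

    ``method='monte_carlo'`` draws tables with the observed margins
    (Patefield sampling) instead of enumerating, for large counts.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValidationError("contingency table must be 2-D and non-negative")
    rows = tuple(int(x) for x in obs.sum(axis=1))
    cols = tuple(int(x) for x in obs.sum(axis=0))
    if sum(rows) == 0:
        return 1.0
    log_const = (sum(math.lgamma(r + 1.0) for r in rows)
                 + sum(math.lgamma(c + 1.0) for c in cols)
                 - math.lgamma(sum(rows) + 1.0))
    logp_obs = _table_logprob(obs.ravel().tolist(), log_const)
    cutoff = logp_obs + math.log1p(tie_tol)

    if method == "exact":
        total = 0.0
        for tab in _enumerate_margin_tables(rows, cols, max_tables):
            lp = _table_logprob([v for row in tab for v in row], log_const)
            if lp <= cutoff:
                total += math.exp(lp)
        return min(total, 1.0)
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(rows, cols)
        draws = sampler.rvs(n_resamples, random_state=rng)
        lps = log_const - gammaln(draws + 1.0).sum(axis=(1, 2))
        hits = int((lps <= cutoff).sum())
        return (hits + 1) / (n_resamples + 1)
    raise ValidationError(f"unknown method {method!r}")


# ------------------------------------------------------------- MET FISH

def classify_met_fish(met_cep7_ratio: float, mean_met_signals: float,
                      pct_cells_high: float) -> str:
    """Tissue MET amplification: positive iff any criterion is met —
    MET/CEP7 >= 2.0, mean MET signals per nucleus >= 6, or >= 10% of
    cells with >= 15 signals / large clusters."""
    if min(met_cep7_ratio, mean_met_signals, pct_cells_high) < 0:
        raise ValidationError("MET FISH inputs must be non-negative")
    positive = (met_cep7_ratio >= 2.0 or mean_met_signals >= 6.0
                or pct_cells_high >= 10.0)
    return "positive" if positive else "negative"


# -------------------------------------------------------- cohort comparison

@dataclass
class CohortComparison:
    groups: dict[str, dict]
    ranksum_p: float
    logrank_p: float
    km_curves: dict[str, pd.DataFrame]
    underpowered: bool


def cohort_compare(patients: Sequence[PatientRecord],
                   group_of: Callable[[PatientRecord], str]) -> CohortComparison:
    """Best-response and progression-free-survival comparison of two
    patient groups (rank-sum and log-rank tests honouring censoring)."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    by_group: dict[str, list[PatientRecord]] = {}
    for p in patients:
        by_group.setdefault(group_of(p), []).append(p)
    if len(by_group) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {sorted(by_group)}")
    names = sorted(by_group)
    if any(len(v) == 0 for v in by_group.values()):
        raise ValidationError("empty group")
    underpowered = any(len(v) < 2 for v in by_group.values())

    groups: dict[str, dict] = {}
    responses: dict[str, np.ndarray] = {}
    for name in names:
        members = by_group[name]
        resp = np.array([p.best_response_pct for p in members
                         if p.best_response_pct is not None], dtype=float)
        responses[name] = resp
        groups[name] = {
            "n": len(members),
            "mean_best_response_pct": float(resp.mean()) if resp.size else math.nan,
            "median_pfs_days": float(np.median([p.pfs_days for p in members])),
        }

    if underpowered or any(responses[n].size < 2 for n in names):
        ranksum_p = math.nan
    else:
        ranksum_p = float(stats.ranksums(responses[names[0]],
                                         responses[names[1]]).pvalue)

    km_curves: dict[str, pd.DataFrame] = {}
    kmf = KaplanMeierFitter()
    for name in names:
        members = by_group[name]
        kmf.fit([p.pfs_days for p in members],
                [p.progression_event for p in members], label=name)
        km_curves[name] = kmf.survival_function_.copy()
    if underpowered:
        logrank_p = math.nan
    else:
        a, b = by_group[names[0]], by_group[names[1]]
        lr = logrank_test([p.pfs_days for p in a], [p.pfs_days for p in b],
                          [p.progression_event for p in a],
                          [p.progression_event for p in b])
        logrank_p = float(lr.p_value)
    return CohortComparison(groups=groups, ranksum_p=ranksum_p,
                            logrank_p=logrank_p, km_curves=km_curves,
                            underpowered=underpowered)
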