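"""Aberrant alternative-splicing-event (AASE) landscape workflow.

From per-sample inclusion levels (PSI) of events of the five canonical types
-- alternative 3'/5' splice sites (A3/A5), mutually exclusive exons (MX),
retained introns (RI) and exon skipping (SE) -- this module

1. calls aberrant events (tumor vs control Mann-Whitney, BH across all event
   types jointly, |delta PSI| > 0.05 and adjusted p < 0.01 by default),
2. summarizes the landscape (counts per type, affected genes, type overlap),
3. screens passing events for association with progression by univariate Cox
   regression on the inclusion level, and
4. ranks candidate splicing regulators by how many passing events their
   protein abundance is strongly correlated with (|r| > 0.6), both against
   all aberrant events and against the progression-related subset; regulators
   recurring in both top lists are reported as the recurrent set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .omics_io import ASE_TYPES, SampleMeta

__all__ = [
    "SpliceEventTable",
    "aase_passes",
    "call_aase",
    "landscape_summary",
    "progression_aase",
    "sf_correlation_ranking",
    "SFRankingReport",
]


@dataclass
class SpliceEventTable:
    """Splice events with per-sample inclusion levels and sample arms.

    ``events``: DataFrame indexed by event key ("SE:12", ...) with columns
    ``ase_type`` and ``gene``. ``inc``: events x samples inclusion levels in
    [0,1], NaN allowed. ``groups``: per-sample arm (normal / inflammation /
    tumor).
    """

    events: pd.DataFrame
    inc: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.events.index.equals(self.inc.index):
            raise ValueError("events and inc must share the same event index")
        if self.events.index.has_duplicates:
            raise ValueError("duplicate event keys")
        bad = set(self.events["ase_type"]) - set(ASE_TYPES)
        if bad:
            raise ValueError(f"unknown ASE types: {sorted(bad)}")
        vals = self.inc.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= -1e-9) & (vals <= 1 + 1e-9))
        if not ok.all():
            raise ValueError("IncLevel values outside [0,1]")
        if not set(self.inc.columns) <= set(self.groups.index):
            raise ValueError("every inc sample needs a group assignment")

    @property
    def samples(self) -> pd.Index:
        return self.inc.columns

    def tumor_mask(self) -> pd.Series:
        return self.groups.reindex(self.inc.columns) == "tumor"

    @classmethod
    def concat(cls, fragments, groups: pd.Series) -> "SpliceEventTable":
        """Stack per-type ``(events, inc)`` reader fragments into one table."""
        ev = pd.concat([f[0][["ase_type", "gene"]] for f in fragments])
        inc = pd.concat([f[1] for f in fragments])
        return cls(events=ev, inc=inc, groups=groups)


def aase_passes(delta: float, adj_p: float, delta_min: float = 0.05,
                q_max: float = 0.01) -> bool:
    """The aberrance filter: |delta PSI| strictly above delta_min AND
    adjusted p strictly below q_max."""
    return bool(abs(delta) > delta_min and adj_p < q_max)


def call_aase(table: SpliceEventTable, delta_min: float = 0.05,
              q_max: float = 0.01, min_per_group: int = 3) -> pd.DataFrame:
    """Call aberrant events: Mann-Whitney per event, BH jointly across types.

    delta is tumor mean minus control mean inclusion. Events with fewer than
    ``min_per_group`` observed inclusion levels in either arm are skipped
    with a reason and excluded from the BH family.
    """
    tumor = table.tumor_mask().to_numpy()
    if (~tumor).sum() == 0:
        raise ValueError("no control samples")
    if tumor.sum() == 0:
        raise ValueError("no tumor samples")
    vals = table.inc.to_numpy(dtype=float)
    out = table.events[["ase_type", "gene"]].copy()
    deltas = np.full(len(out), math.nan)
    pvals = np.full(len(out), math.nan)
    reasons = np.array([""] * len(out), dtype=object)
    for i in range(len(out)):
        t = vals[i, tumor]
        c = vals[i, ~tumor]
        t = t[np.isfinite(t)]
        c = c[np.isfinite(c)]
        if len(t) < min_per_group or len(c) < min_per_group:
            reasons[i] = "insufficient-samples"
            continue
        deltas[i] = t.mean() - c.mean()
        pvals[i] = stats_core.mann_whitney_u(t, c).p_value
    tested = np.isfinite(pvals)
    qvals = np.full(len(out), math.nan)
    if tested.any():
        qvals[tested] = stats_core.bh_adjust(pvals[tested])
    out["delta_inc_level"] = deltas
    out["p_value"] = pvals
    out["adj_p"] = qvals
    out["passes"] = [
        bool(tested[i]) and aase_passes(deltas[i], qvals[i], delta_min, q_max)
        for i in range(len(out))
    ]
    out["reason"] = reasons
    return out


@dataclass
class LandscapeSummary:
    n_aase: int
    counts_by_type: pd.Series            # passing events per ASE type
    n_genes: int                         # genes affected by >= 1 passing event
    genes_by_type: dict[str, set]
    n_single_type_genes: int             # genes hit by exactly one type
    type_intersection: pd.DataFrame      # gene-overlap counts, types x types
    gene_types: pd.Series                # gene -> frozenset of types


def landscape_summary(calls: pd.DataFrame) -> LandscapeSummary:
    """Pure bookkeeping over the calls table (recountable independently)."""
    passing = calls[calls["passes"]]
    counts = passing["ase_type"].value_counts().reindex(ASE_TYPES, fill_value=0)
    genes_by_type = {t: set(passing.loc[passing["ase_type"] == t, "gene"])
                     for t in ASE_TYPES}
    gene_types = passing.groupby("gene")["ase_type"].agg(lambda s: frozenset(s))
    inter = pd.DataFrame(
        [[len(genes_by_type[a] & genes_by_type[b]) for b in ASE_TYPES]
         for a in ASE_TYPES],
        index=list(ASE_TYPES), columns=list(ASE_TYPES))
    return LandscapeSummary(
        n_aase=int(len(passing)),
        counts_by_type=counts,
        n_genes=int(gene_types.shape[0]),
        genes_by_type=genes_by_type,
        n_single_type_genes=int((gene_types.map(len) == 1).sum()),
        type_intersection=inter,
        gene_types=gene_types,
    )


def progression_aase(calls: pd.DataFrame, table: SpliceEventTable,
                     meta: SampleMeta, endpoint: str = "PFS",
                     p_max: float = 0.05, adjust: bool = False) -> pd.DataFrame:
    """Univariate Cox screen of passing events against a survival endpoint.

    Only events that passed the aberrance filter are tested (the screen sits
    downstream of the calling stage). The inclusion level enters as a
    continuous covariate; significance defaults to raw p < 0.05, with BH
    adjustment available by flag.
    """
    surv = meta.endpoint(endpoint)
    tumor_samples = [s for s in table.samples
                     if table.groups.get(s) == "tumor" and s in surv.index]
    if len(tumor_samples) == 0:
        raise ValueError(f"no tumor samples with known {endpoint}")
    surv = surv.loc[tumor_samples]
    if surv["event"].sum() == 0:
        raise ValueError(f"no observed events for endpoint {endpoint}")
    passing = calls.index[calls["passes"]]
    rows = []
    for ev in passing:
        x = table.inc.loc[ev, tumor_samples].to_numpy(dtype=float)
        keep = np.isfinite(x)
        res = stats_core.cox_fit(pd.DataFrame({"psi": x[keep]}),
                                 surv["time"].to_numpy()[keep],
                                 surv["event"].to_numpy()[keep])["psi"]
        rows.append({
            "event": ev,
            "ase_type": calls.loc[ev, "ase_type"],
            "gene": calls.loc[ev, "gene"],
            "beta": res.estimate,
            "hr": math.exp(res.estimate) if math.isfinite(res.estimate) else math.nan,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p_value": res.p_value,
            "flags": ";".join(res.flags),
        })
    out = pd.DataFrame(rows).set_index("event") if rows else pd.DataFrame(
        columns=["ase_type", "gene", "beta", "hr", "ci_low", "ci_high",
                 "p_value", "flags"])
    pcol = out["p_value"] if len(out) else pd.Series(dtype=float)
    if adjust and len(out):
        tested = pcol.notna()
        adj = pd.Series(math.nan, index=out.index)
        adj[tested] = stats_core.bh_adjust(pcol[tested])
        out["adj_p"] = adj
        out["significant"] = out["adj_p"] < p_max
    elif len(out):
        out["significant"] = pcol < p_max
    return out


@dataclass
class SFRankingReport:
    correlations: pd.DataFrame           # long table: sf, event, r, strong
    ranking_all: pd.DataFrame            # per-SF strong count / mean |r|, all AASEs
    ranking_progression: pd.DataFrame | None
    recurrent_sfs: list[str] = field(default_factory=list)
    strong_event_genes: dict[str, list[str]] = field(default_factory=dict)
    skipped_sfs: list[str] = field(default_factory=list)


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix between A (a x n) and B (b x n),
    pairwise-complete per pair."""
    if np.isfinite(A).all() and np.isfinite(B).all():
        Az = A - A.mean(axis=1, keepdims=True)
        Bz = B - B.mean(axis=1, keepdims=True)
        sa = np.sqrt((Az * Az).sum(axis=1))
        sb = np.sqrt((Bz * Bz).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (Az @ Bz.T) / np.outer(sa, sb)
    out = np.full((A.shape[0], B.shape[0]), math.nan)
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            keep = np.isfinite(A[i]) & np.isfinite(B[j])
            if keep.sum() < 3:
                continue
            a, b = A[i, keep], B[j, keep]
            if a.std() == 0 or b.std() == 0:
                continue
            out[i, j] = np.corrcoef(a, b)[0, 1]
    return out


def _rank_sfs(corr: pd.DataFrame, strong_r: float) -> pd.DataFrame:
    strong = (corr.abs() > strong_r)
    summary = pd.DataFrame({
        "strong_count": strong.sum(axis=1),
        "mean_abs_r": corr.abs().mean(axis=1),
    })
    summary = summary.sort_values(["strong_count", "mean_abs_r"],
                                  ascending=False, kind="mergesort")
    summary["rank"] = np.arange(1, len(summary) + 1)
    return summary


def sf_correlation_ranking(sf_genes, protein: pd.DataFrame,
                           table: SpliceEventTable, calls: pd.DataFrame,
                           progression: pd.DataFrame | None = None,
                           top_k: int = 20, strong_r: float = 0.6) -> SFRankingReport:
    """Correlate regulator protein abundance with event inclusion (tumor scope).

    ``protein`` is the log-scale protein matrix (genes x samples). Per
    splicing factor the summary is the count of strong correlations
    (|r| > ``strong_r``) with a mean-|r| tiebreak; two rankings are built
    (all passing events; progression-significant events) and their top-k
    intersection is the recurrent regulator set.
    """
    sf_present = [g for g in sf_genes if g in protein.index]
    skipped = [g for g in sf_genes if g not in protein.index]
    if skipped:
        warnings.warn(f"{len(skipped)} splicing factors absent from the protein "
                      f"matrix were skipped", stacklevel=2)
    if not sf_present:
        raise ValueError("no splicing factors present in the protein matrix")
    tumor_samples = [s for s in table.samples
                     if table.groups.get(s) == "tumor" and s in protein.columns]
    if len(tumor_samples) < 3:
        raise ValueError("need >= 3 tumor samples with protein data")
    passing = [e for e in calls.index[calls["passes"]]]
    if not passing:
        raise ValueError("no passing aberrant events to correlate")
    P = protein.loc[sf_present, tumor_samples].to_numpy(dtype=float)
    I = table.inc.loc[passing, tumor_samples].to_numpy(dtype=float)
    R = pd.DataFrame(_pearson_rows(P, I), index=sf_present, columns=passing)
    long = R.stack(future_stack=True).rename("r").reset_index()
    long.columns = ["sf", "event", "r"]
    long["strong"] = long["r"].abs() > strong_r
    ranking_all = _rank_sfs(R, strong_r)
    ranking_prog = None
    recurrent: list[str] = []
    if progression is not None and len(progression):
        prog_events = [e for e in progression.index[progression["significant"]]
                       if e in R.columns]
        if prog_events:
            ranking_prog = _rank_sfs(R[prog_events], strong_r)
            top_a = list(ranking_all.index[:top_k])
            top_p = list(ranking_prog.index[:top_k])
            recurrent = sorted(set(top_a) & set(top_p))
    strong_genes = {}
    gene_of = calls["gene"]
    for sf in sf_present:
        evs = R.columns[(R.loc[sf].abs() > strong_r).to_numpy()]
        strong_genes[sf] = sorted(set(gene_of.loc[evs]))
    return SFRankingReport(correlations=long, ranking_all=ranking_all,
                           ranking_progression=ranking_prog,
                           recurrent_sfs=recurrent,
                           strong_event_genes=strong_genes,
                           skipped_sfs=skipped)
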