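"""Gene-set machinery: over-representation, preranked enrichment, and
per-sample enrichment scores.

* ``ora``: hypergeometric over-representation of a hit list within a
  universe (upper tail of the 2x2 membership table), BH across a collection.
* ``gsea_preranked``: weighted Kolmogorov-Smirnov running-sum enrichment
  (weight exponent 1) over a ranked gene list, with NES and nominal p from
  seeded gene-label permutations; FDR across a collection by BH of nominal p.
* ``ssgsea_matrix``: per-sample rank-based enrichment scores (weighted-ECDF
  difference, exponent alpha), linearly rescaled per set across samples to
  [-1, 1]. Being rank-based, the scores are invariant to sample-wise
  monotone transforms, which is what licenses correlating them with the
  per-sample concordance statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats_core

__all__ = ["EnrichmentResult", "ora", "ora_collection", "gsea_preranked",
           "gsea_collection", "ssgsea_matrix", "running_es"]


@dataclass
class EnrichmentResult:
    name: str
    es: float = math.nan              # enrichment score (preranked) in [-1,1]
    nes: float = math.nan
    p_value: float = math.nan
    fdr: float = math.nan
    leading_edge: list[str] = field(default_factory=list)
    overlap: int = 0                  # ORA: |hits & set|
    set_size: int = 0
    enrichment: float = math.nan      # ORA: (k/N)/(n/M) fold enrichment


def ora(hit_genes, gene_set, universe) -> EnrichmentResult:
    """Hypergeometric upper-tail over-representation test."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValueError("hit genes must be a subset of the universe")
    members = set(gene_set) & universe
    if not members:
        raise ValueError("gene set does not intersect the universe")
    M, n, N = len(universe), len(members), len(hits)
    k = len(hits & members)
    p = float(sps.hypergeom.sf(k - 1, M, n, N))
    expected = n * N / M
    return EnrichmentResult(name="", p_value=min(p, 1.0), overlap=k, set_size=n,
                            enrichment=(k / expected) if expected > 0 else math.nan)


def ora_collection(hit_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """ORA across a GMT-style collection with BH adjustment."""
    rows = []
    for name, members in gene_sets.items():
        try:
            r = ora(hit_genes, members, universe)
        except ValueError:
            continue
        rows.append({"gene_set": name, "overlap": r.overlap,
                     "set_size": r.set_size, "enrichment": r.enrichment,
                     "p_value": r.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = stats_core.bh_adjust(out["p_value"])
        out = out.set_index("gene_set").sort_values("p_value", kind="mergesort")
    return out


def running_es(ranked_genes: list[str], scores: np.ndarray,
               members: set, weight: float = 1.0) -> tuple[float, np.ndarray, int]:
    """Weighted KS running sum; returns (ES, running sum, argmax position)."""
    N = len(ranked_genes)
    in_set = np.array([g in members for g in ranked_genes])
    nh = int(in_set.sum())
    w = np.abs(scores) ** weight
    denom_hit = w[in_set].sum()
    if denom_hit <= 0:
        # all hit weights zero: fall back to unweighted steps
        w = np.ones(N)
        denom_hit = float(nh)
    step = np.where(in_set, w / denom_hit, -1.0 / (N - nh))
    run = np.cumsum(step)
    i_max = int(np.argmax(np.abs(run)))
    return float(run[i_max]), run, i_max


def _ranked_input(ranked_scores: pd.Series) -> tuple[list[str], np.ndarray]:
    if ranked_scores.index.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    s = ranked_scores.sort_values(ascending=False, kind="mergesort")
    return list(s.index), s.to_numpy(dtype=float)


def gsea_preranked(ranked_scores: pd.Series, gene_set, n_perm: int = 1000,
                   seed: int = 0, min_size: int = 5, weight: float = 1.0,
                   name: str = "") -> EnrichmentResult:
    """Preranked enrichment with gene-label permutation NES / nominal p.

    ``ranked_scores``: ranking metric per gene (higher = more tumor-like);
    order is established internally by sorting descending. The null is
    random same-size gene sets; nominal p and NES condition on the sign of
    the observed ES (GSEA convention), with +1 smoothing on p.
    """
    genes, scores = _ranked_input(ranked_scores)
    members = set(gene_set) & set(genes)
    if len(members) < min_size:
        raise ValueError(f"gene set too small after intersection ({len(members)} < {min_size})")
    es, run, i_max = running_es(genes, scores, members, weight)
    if es >= 0:
        leading = [g for g in genes[:i_max + 1] if g in members]
    else:
        leading = [g for g in genes[i_max:] if g in members]
    rng = np.random.default_rng(seed)
    size = len(members)
    null = np.empty(n_perm)
    gene_arr = np.array(genes)
    for b in range(n_perm):
        rand = set(gene_arr[rng.choice(len(genes), size=size, replace=False)])
        null[b], _, _ = running_es(genes, scores, rand, weight)
    same = null[null >= 0] if es >= 0 else null[null < 0]
    if len(same) == 0:
        p, nes = 1.0, math.nan
    else:
        p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + len(same))
        mean_same = float(np.mean(np.abs(same)))
        nes = es / mean_same if mean_same > 0 else math.nan
    return EnrichmentResult(name=name, es=es, nes=nes, p_value=float(min(p, 1.0)),
                            leading_edge=leading, set_size=size)


def gsea_collection(ranked_scores: pd.Series, gene_sets: dict,
                    n_perm: int = 1000, seed: int = 0, min_size: int = 5,
                    weight: float = 1.0) -> pd.DataFrame:
    """Preranked enrichment for a collection; FDR = BH over nominal p."""
    rows = []
    for i, (nm, members) in enumerate(gene_sets.items()):
        try:
            r = gsea_preranked(ranked_scores, members, n_perm=n_perm,
                               seed=seed + i, min_size=min_size,
                               weight=weight, name=nm)
        except ValueError:
            continue
        rows.append({"gene_set": nm, "es": r.es, "nes": r.nes,
                     "p_value": r.p_value, "set_size": r.set_size,
                     "leading_edge_size": len(r.leading_edge)})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = stats_core.bh_adjust(out["p_value"])
        out = out.set_index("gene_set").sort_values("p_value", kind="mergesort")
    return out


def _ssgsea_sample(ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    order = np.argsort(-ranks, kind="stable")
    r_ord = ranks[order]
    in_ord = in_set[order]
    w = np.where(in_ord, r_ord ** alpha, 0.0)
    denom = w.sum()
    n_out = (~in_ord).sum()
    p_in = np.cumsum(w) / denom
    p_out = np.cumsum(~in_ord) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(expr: pd.DataFrame, gene_sets: dict,
                  alpha: float = 0.25, rescale: bool = True) -> pd.DataFrame:
    """Per-sample enrichment scores (sets x samples).

    ``expr`` is a complete (no missing values) expression matrix, genes x
    samples. Per sample, genes are ranked by abundance (average ranks for
    ties) and each set's score is the cumulative weighted-ECDF difference
    between member and non-member genes with weight exponent ``alpha``.
    With ``rescale`` each set's scores are mapped linearly across samples to
    [-1, 1] (a constant row maps to 0).
    """
    if expr.isna().any().any():
        raise ValueError("ssgsea_matrix requires a complete matrix")
    genes = expr.index
    ranks = np.apply_along_axis(sps.rankdata, 0, expr.to_numpy(dtype=float))
    scores = {}
    for name, members in gene_sets.items():
        in_set = np.asarray(genes.isin(set(members)))
        if in_set.sum() == 0:
            raise ValueError(f"gene set {name!r} has no expressed members")
        if in_set.all():
            raise ValueError(f"gene set {name!r} covers the whole matrix")
        scores[name] = [_ssgsea_sample(ranks[:, j], in_set, alpha)
                        for j in range(expr.shape[1])]
    out = pd.DataFrame(scores, index=expr.columns).T
    if rescale:
        lo = out.min(axis=1)
        hi = out.max(axis=1)
        span = (hi - lo).replace(0.0, np.nan)
        out = ((out.sub(lo, axis=0)).div(span, axis=0) * 2.0 - 1.0).fillna(0.0)
    return out
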