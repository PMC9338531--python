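"""Inflammation-independence trend analysis of the protein layer.

Each protein's trajectory across the three arms (normal -> inflammation ->
tumor) is classified twice:

* supervised: two step calls from pairwise Welch t-tests, each step up /
  down / flat (flat unless p < 0.05 AND |log2 delta| exceeds the proteome
  fold-change gate), giving the 3 x 3 = nine trend patterns;
* unsupervised: k-means over per-gene z-scored profiles of the
  high-variability genes (top MAD fraction), with per-cluster group-median
  trajectories and segmented-regression slopes between adjacent arms.

The two views merge into the five-class signature: MIMIC-UP (rises with
inflammation, tumor indistinguishable from inflammation), SPECIFIC-UP
(tumor-specific rise), VAGUE-UP (monotone rise without a clean step
structure), and the mirrored MIMIC-DOWN / SPECIFIC-DOWN; a gene gets a
class only when its pattern and its cluster's trend agree in direction.
There is deliberately no VAGUE-DOWN: the five-class vocabulary is asymmetric,
so genes whose negated profile would be VAGUE-UP fall to NONE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats_core
from .cohort_synth import PATTERNS
from .diffexp import LOG2FC_THRESHOLDS

__all__ = ["call_trend_patterns", "cluster_hvgs", "build_signature",
           "ClusterResult", "SIGNATURE_CLASSES"]

ARM_ORDER = ("normal", "inflammation", "tumor")
SIGNATURE_CLASSES = ("MIMIC-UP", "VAGUE-UP", "SPECIFIC-UP",
                     "MIMIC-DOWN", "SPECIFIC-DOWN", "NONE")


def _step_calls(delta: np.ndarray, p: np.ndarray, alpha: float,
                effect_min: float) -> np.ndarray:
    sig = (p < alpha) & (np.abs(delta) > effect_min)
    return np.where(sig & (delta > 0), "up",
                    np.where(sig & (delta < 0), "down", "flat"))


def call_trend_patterns(values: pd.DataFrame, arms, alpha: float = 0.05,
                        effect_min: float | None = None) -> pd.DataFrame:
    """Nine-pattern trend call per gene from three pairwise Welch t-tests.

    ``values`` is the log-scale protein matrix (genes x samples), ``arms``
    the per-sample arm labels. Step 1 is normal->inflammation, step 2
    inflammation->tumor; the normal->tumor contrast is carried along for the
    signature merge. A step is flat unless significant and beyond the
    fold-change gate (default: the proteome DE threshold, log2 1.2).
    """
    if effect_min is None:
        effect_min = LOG2FC_THRESHOLDS["protein"]
    arms = pd.Series(arms, index=values.columns) if not isinstance(arms, pd.Series) \
        else arms.reindex(values.columns)
    groups = {a: values.loc[:, (arms == a).to_numpy()] for a in ARM_ORDER}
    for a in ARM_ORDER:
        if groups[a].shape[1] < 2:
            raise ValueError(f"arm {a!r} needs >= 2 samples")
    out = pd.DataFrame(index=values.index)
    contrasts = {"ni": ("inflammation", "normal"),
                 "it": ("tumor", "inflammation"),
                 "nt": ("tumor", "normal")}
    for tag, (hi, lo) in contrasts.items():
        A = groups[hi].to_numpy(dtype=float)
        B = groups[lo].to_numpy(dtype=float)
        res = sps.ttest_ind(A, B, axis=1, equal_var=False)
        out[f"delta_{tag}"] = A.mean(axis=1) - B.mean(axis=1)
        out[f"p_{tag}"] = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out["step1"] = _step_calls(out["delta_ni"].to_numpy(),
                               out["p_ni"].to_numpy(), alpha, effect_min)
    out["step2"] = _step_calls(out["delta_it"].to_numpy(),
                               out["p_it"].to_numpy(), alpha, effect_min)
    out["pattern"] = out["step1"] + "_" + out["step2"]
    assert set(out["pattern"]) <= set(PATTERNS)
    return out


@dataclass
class ClusterResult:
    labels: pd.Series                 # HVG gene -> cluster id
    trajectories: pd.DataFrame        # per cluster: arm medians + slopes
    elbow: pd.DataFrame               # k vs inertia
    zscores: pd.DataFrame             # z-scored HVG matrix used for clustering


def _slope(y: np.ndarray, x: np.ndarray) -> float:
    if len(np.unique(x)) < 2:
        return math.nan
    return float(np.polyfit(x, y, 1)[0])


def cluster_hvgs(values: pd.DataFrame, arms, mad_quantile: float = 0.5,
                 k: int = 4, seed: int = 0, n_init: int = 10,
                 elbow_ks=range(2, 11)) -> ClusterResult:
    """k-means over z-scored high-variability genes, with trend slopes.

    HVGs are the genes whose MAD (on the log-abundance matrix) lies in the
    top ``mad_quantile`` fraction; their per-gene z-scores are clustered.
    Per cluster, each sample contributes its median z over the cluster's
    genes; the trajectory slopes are least-squares slopes of those medians
    against arm index, segmented per adjacent arm pair plus one overall fit.
    """
    arms = pd.Series(arms, index=values.columns) if not isinstance(arms, pd.Series) \
        else arms.reindex(values.columns)
    if not 0.0 < mad_quantile <= 1.0:
        raise ValueError("mad_quantile must be in (0,1]")
    mad = (values.sub(values.median(axis=1), axis=0)).abs().median(axis=1)
    cutoff = mad.quantile(1.0 - mad_quantile)
    hvg = mad.index[mad >= cutoff]
    if len(hvg) < k:
        raise ValueError(f"only {len(hvg)} HVGs for k={k}")
    sub = values.loc[hvg]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    X = z.to_numpy(dtype=float)
    labels, _, _ = stats_core.kmeans(X, k, seed=seed, n_init=n_init)
    elbow_rows = []
    for kk in elbow_ks:
        if kk > X.shape[0]:
            continue
        _, _, inertia = stats_core.kmeans(X, kk, seed=seed, n_init=n_init)
        elbow_rows.append({"k": kk, "inertia": inertia})
    arm_index = arms.map({a: i for i, a in enumerate(ARM_ORDER)}).to_numpy(dtype=float)
    rows = []
    for c in range(k):
        zc = X[labels == c]
        med = np.median(zc, axis=0)  # per-sample median z in this cluster
        row = {"cluster": c, "n_genes": int((labels == c).sum())}
        for i, a in enumerate(ARM_ORDER):
            row[f"median_{a}"] = float(np.median(med[arm_index == i]))
        m01 = (arm_index <= 1)
        m12 = (arm_index >= 1)
        row["slope_ni"] = _slope(med[m01], arm_index[m01])
        row["slope_it"] = _slope(med[m12], arm_index[m12])
        row["slope_overall"] = _slope(med, arm_index)
        rows.append(row)
    return ClusterResult(
        labels=pd.Series(labels, index=hvg, name="cluster"),
        trajectories=pd.DataFrame(rows).set_index("cluster"),
        elbow=pd.DataFrame(elbow_rows),
        zscores=z,
    )


def build_signature(patterns: pd.DataFrame, clusters: ClusterResult,
                    alpha: float = 0.05,
                    effect_min: float | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Merge trend patterns and cluster trends into the five-class signature.

    Mapping (cluster trend = sign of the cluster's overall slope):
      MIMIC-UP      (up, flat) with significant overall N->T rise, up cluster
      SPECIFIC-UP   (flat, up), up cluster
      VAGUE-UP      (up, up), or (flat, flat) steps with a significant
                    overall N->T rise, up cluster
      MIMIC-DOWN / SPECIFIC-DOWN mirror the first two in a down cluster
      NONE          everything else (incl. genes in only one input, warned)
    """
    if effect_min is None:
        effect_min = LOG2FC_THRESHOLDS["protein"]
    common = clusters.labels.index.intersection(patterns.index)
    only_one = len(clusters.labels.index.difference(patterns.index)) + \
        len(patterns.index.difference(clusters.labels.index))
    if only_one:
        warnings.warn(f"{only_one} genes present in only one input -> NONE",
                      stacklevel=2)
    slope = clusters.trajectories["slope_overall"]
    cluster_dir = np.sign(slope).map({1.0: "up", -1.0: "down", 0.0: "flat"})
    rows = []
    for g in clusters.labels.index:
        cl = int(clusters.labels[g])
        cdir = cluster_dir[cl]
        if g not in common:
            rows.append({"gene": g, "pattern": "", "cluster": cl,
                         "cluster_trend": cdir, "final_class": "NONE"})
            continue
        pat = patterns.loc[g, "pattern"]
        nt_up = (patterns.loc[g, "p_nt"] < alpha
                 and patterns.loc[g, "delta_nt"] > effect_min)
        nt_down = (patterns.loc[g, "p_nt"] < alpha
                   and patterns.loc[g, "delta_nt"] < -effect_min)
        cls = "NONE"
        if cdir == "up":
            if pat == "up_flat" and nt_up:
                cls = "MIMIC-UP"
            elif pat == "flat_up":
                cls = "SPECIFIC-UP"
            elif pat == "up_up" or (pat == "flat_flat" and nt_up):
                cls = "VAGUE-UP"
        elif cdir == "down":
            if pat == "down_flat" and nt_down:
                cls = "MIMIC-DOWN"
            elif pat == "flat_down":
                cls = "SPECIFIC-DOWN"
        rows.append({"gene": g, "pattern": pat, "cluster": cl,
                     "cluster_trend": cdir, "final_class": cls})
    table = pd.DataFrame(rows).set_index("gene")
    counts = table["final_class"].value_counts().reindex(
        SIGNATURE_CLASSES, fill_value=0)
    return table, counts
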