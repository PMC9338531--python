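"""Two-group differential expression per omics layer and cross-layer
concordance classification.

The per-gene test is a moderated t: per-gene pooled variances are shrunk
toward a common prior estimated by fitting a scaled-F distribution to the
observed variances (method-of-moments on log variances, the standard
empirical-Bayes squeeze used for small-n expression studies), which adds
prior degrees of freedom to the test. A plain Welch t is available by flag.

Layer thresholds follow the usual fold-change conventions for these data:
|log2FC| > log2(1.5) for mRNA and > log2(1.2) for protein, with two-sided
p < 0.05; the p-value (not the BH q, which is reported alongside) drives the
up/down/ns status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma

from . import stats_core

__all__ = ["LOG2FC_THRESHOLDS", "run_de", "classify_concordance",
           "moderate_variances"]

LOG2FC_THRESHOLDS = {"mrna": math.log2(1.5), "protein": math.log2(1.2)}


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(_trigamma(y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes variance squeeze.

    Fits the scaled-F prior (s0^2, d0) to the per-gene variances ``s2`` with
    ``df`` residual degrees of freedom each, by moments on log variances,
    and returns (posterior variances, d0, s0^2). d0 = inf collapses every
    variance to the common value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.median(s2))
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(_trigamma(df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
        post = np.full_like(s2, s0_sq)
    return post, d0, s0_sq


def median_center(values: pd.DataFrame) -> pd.DataFrame:
    """Per-sample median centering on the log scale."""
    return values - values.median(axis=0, skipna=True)


def run_de(values: pd.DataFrame, is_tumor, layer: str, normalize: bool = True,
           moderated: bool = True, alpha: float = 0.05,
           log2fc_min: float | None = None) -> pd.DataFrame:
    """Per-gene two-group test (tumor minus control) on a log-scale matrix.

    ``values`` is genes x samples without missing cells (filter/impute
    first); ``is_tumor`` a boolean mask over columns. Returns a table with
    log2fc, t, p, q and status in {up, down, ns}.
    """
    if layer not in LOG2FC_THRESHOLDS:
        raise ValueError(f"unknown layer {layer!r}")
    thr = LOG2FC_THRESHOLDS[layer] if log2fc_min is None else log2fc_min
    is_tumor = np.asarray(is_tumor, dtype=bool)
    if is_tumor.sum() < 2 or (~is_tumor).sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    if values.isna().any().any():
        raise ValueError("run_de requires a complete matrix (impute first)")
    if normalize:
        values = median_center(values)
    A = values.loc[:, is_tumor].to_numpy(dtype=float)
    B = values.loc[:, ~is_tumor].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    if moderated:
        ss = (A.var(axis=1, ddof=1) * (n1 - 1) + B.var(axis=1, ddof=1) * (n2 - 1))
        df = n1 + n2 - 2
        s2 = ss / df
        s2_post, d0, _ = moderate_variances(s2, df)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / se
        df_total = df + d0
        if math.isinf(df_total):
            p = 2.0 * sps.norm.sf(np.abs(t))
        else:
            p = 2.0 * sps.t.sf(np.abs(t), df_total)
        method = "moderated-t"
    else:
        res = sps.ttest_ind(A, B, axis=1, equal_var=False)
        t, p = res.statistic, res.pvalue
        method = "welch"
    p = np.where(np.isnan(p), 1.0, p)
    q = stats_core.bh_adjust(p)
    status = np.where((log2fc > thr) & (p < alpha), "up",
                      np.where((log2fc < -thr) & (p < alpha), "down", "ns"))
    return pd.DataFrame({
        "log2fc": log2fc, "t": t, "p_value": p, "q_value": q,
        "status": status, "layer": layer, "method": method,
    }, index=values.index)


@dataclass
class ConcordanceCounts:
    co_up: int
    co_down: int
    discordant: int
    none: int


def classify_concordance(de_protein: pd.DataFrame,
                         de_mrna: pd.DataFrame) -> tuple[pd.DataFrame, ConcordanceCounts]:
    """Four-way cross-layer classification of the shared gene universe.

    CO-UP / CO-DOWN when both layers call the same direction, DISCORDANT
    when both are significant with opposite signs, NONE when either layer is
    non-significant.
    """
    if set(de_protein.index) != set(de_mrna.index):
        raise ValueError("protein and mRNA DE tables must cover the same genes")
    de_mrna = de_mrna.reindex(de_protein.index)
    sp = de_protein["status"].to_numpy()
    sm = de_mrna["status"].to_numpy()
    cls = np.full(len(sp), "NONE", dtype=object)
    cls[(sp == "up") & (sm == "up")] = "CO-UP"
    cls[(sp == "down") & (sm == "down")] = "CO-DOWN"
    cls[((sp == "up") & (sm == "down")) | ((sp == "down") & (sm == "up"))] = "DISCORDANT"
    table = pd.DataFrame({
        "class": cls,
        "protein_status": sp, "mrna_status": sm,
        "protein_log2fc": de_protein["log2fc"].to_numpy(),
        "mrna_log2fc": de_mrna["log2fc"].to_numpy(),
    }, index=de_protein.index)
    counts = ConcordanceCounts(
        co_up=int((cls == "CO-UP").sum()),
        co_down=int((cls == "CO-DOWN").sum()),
        discordant=int((cls == "DISCORDANT").sum()),
        none=int((cls == "NONE").sum()),
    )
    return table, counts
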