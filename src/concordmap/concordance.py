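"""Per-sample global protein-mRNA concordance and its clinical associations.

The headline statistic: for each sample, the Spearman correlation between
its protein and mRNA abundances over the shared (pairwise-complete) gene
set. Because protein and transcript detection differ between disease arms,
the pair universe is built separately per scope (tumor pairs and control
pairs may legitimately differ in count).

Downstream associations: arm and subgroup comparisons (Mann-Whitney),
correlation with numeric covariates such as proliferation-marker abundance
or per-sample gene-set scores (Pearson), and survival: a median split of
the tumor samples feeding Kaplan-Meier / log-rank plus a univariate Cox fit
on the continuous concordance. The median split assigns ties at the median
to the low group (deterministic, ceil(n/2) low vs floor(n/2) high).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats_core
from .omics_io import ENDPOINTS, PairedCohort, SampleMeta
from .stats_core import TestResult

__all__ = ["compute_concordance", "median_split", "compare_groups",
           "correlate_with", "concordance_survival",
           "concordance_geneset_ranking", "SurvivalResult"]


def _scope_samples(cohort: PairedCohort, group_scope) -> list[str]:
    arm = cohort.meta.arm
    if isinstance(group_scope, str):
        if group_scope == "tumor":
            return [s for s in cohort.samples if arm[s] == "tumor"]
        if group_scope == "control":
            return [s for s in cohort.samples if arm[s] != "tumor"]
        if group_scope in ("normal", "inflammation"):
            return [s for s in cohort.samples if arm[s] == group_scope]
        raise ValueError(f"unknown scope {group_scope!r}")
    return [s for s in group_scope if s in set(cohort.samples)]


def compute_concordance(cohort: PairedCohort, group_scope="tumor",
                        min_pairs: int = 100,
                        detect_frac: float = 0.8) -> pd.DataFrame:
    """Per-sample Spearman concordance within one scope.

    The scope's pair universe is the set of genes observed in at least
    ``detect_frac`` of the scope's samples in both layers; each sample's rho
    then uses its pairwise-complete values over that universe. Samples with
    fewer than ``min_pairs`` complete pairs are excluded and flagged.

    Returns a profile table (rho, n_pairs, group, arm, excluded) whose
    ``attrs["n_pairs_universe"]`` records the scope's pair-universe size.
    """
    samples = _scope_samples(cohort, group_scope)
    if not samples:
        raise ValueError("empty scope")
    prot = cohort.protein.values[samples]
    mrna = cohort.mrna.values[samples]
    obs = (prot.notna().mean(axis=1) >= detect_frac) & \
          (mrna.notna().mean(axis=1) >= detect_frac)
    universe = prot.index[obs]
    rows = []
    for s in samples:
        x = prot.loc[universe, s].to_numpy(dtype=float)
        y = mrna.loc[universe, s].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        n = int(keep.sum())
        if n < max(min_pairs, 3):
            rows.append({"sample": s, "rho": math.nan, "n_pairs": n,
                         "excluded": True})
            continue
        res = stats_core.spearman_rho(x[keep], y[keep])
        rows.append({"sample": s, "rho": res.estimate, "n_pairs": n,
                     "excluded": "constant" in res.flags})
    out = pd.DataFrame(rows).set_index("sample")
    out["group"] = cohort.meta.table.loc[out.index, "group"]
    out["arm"] = cohort.meta.arm.loc[out.index]
    out.attrs["n_pairs_universe"] = int(len(universe))
    return out


def median_split(profiles: pd.DataFrame) -> pd.Series:
    """high/low labels by the median rho; ties at the median go low."""
    rho = profiles.loc[~profiles["excluded"], "rho"].dropna()
    if len(rho) < 2:
        raise ValueError("median split needs >= 2 usable samples")
    med = float(rho.median())
    labels = pd.Series(np.where(rho > med, "high", "low"), index=rho.index)
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValueError("degenerate median split (constant concordance)")
    return labels


def compare_groups(profiles: pd.DataFrame, grouping) -> TestResult:
    """Mann-Whitney comparison of rho between two groups.

    ``grouping`` is a per-sample label Series (aligned on sample ID) with
    exactly two levels after dropping samples with unknown labels.
    """
    grouping = pd.Series(grouping)
    joined = profiles.join(grouping.rename("g")).dropna(subset=["rho", "g"])
    levels = sorted(joined["g"].unique())
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly two levels, got {levels}")
    a = joined.loc[joined["g"] == levels[1], "rho"]
    b = joined.loc[joined["g"] == levels[0], "rho"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one side of the grouping is empty")
    return stats_core.mann_whitney_u(a, b)


def correlate_with(profiles: pd.DataFrame, covariate) -> TestResult:
    """Pearson correlation of rho with a numeric per-sample covariate."""
    covariate = pd.Series(covariate)
    joined = profiles.join(covariate.rename("cov")).dropna(subset=["rho", "cov"])
    if len(joined) < 3:
        raise ValueError("need >= 3 complete (rho, covariate) pairs")
    return stats_core.pearson_r(joined["rho"], joined["cov"])


@dataclass
class SurvivalResult:
    endpoint: str
    split: pd.Series                  # high/low per sample
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    logrank: TestResult
    cox: TestResult                   # continuous rho
    n_events: int


def concordance_survival(profiles: pd.DataFrame, meta: SampleMeta,
                         endpoint: str = "DRFS") -> SurvivalResult:
    """Median-split KM + log-rank and continuous-rho Cox for one endpoint."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    tum = profiles[(profiles["arm"] == "tumor") & ~profiles["excluded"]]
    surv = meta.endpoint(endpoint)
    common = tum.index.intersection(surv.index)
    if len(common) < 4:
        raise ValueError(f"too few tumor samples with known {endpoint}")
    tum = tum.loc[common]
    surv = surv.loc[common]
    labels = median_split(tum)
    times = surv["time"].to_numpy()
    events = surv["event"].to_numpy()
    n_events = int(events.sum())
    hi = labels == "high"
    km_high = stats_core.km_curve(times[hi.to_numpy()], events[hi.to_numpy()])
    km_low = stats_core.km_curve(times[~hi.to_numpy()], events[~hi.to_numpy()])
    if n_events == 0:
        lr = TestResult(math.nan, math.nan, math.nan, n_used=len(common),
                        method="logrank", flags=("no-events",))
        cox = TestResult(math.nan, math.nan, math.nan, n_used=len(common),
                         method="cox-efron", flags=("no-events",))
    else:
        lr = stats_core.logrank(times, events, labels.to_numpy())
        cox = stats_core.cox_fit(pd.DataFrame({"rho": tum["rho"].to_numpy()}),
                                 times, events)["rho"]
    return SurvivalResult(endpoint, labels, km_high, km_low, lr, cox, n_events)


def concordance_geneset_ranking(profiles: pd.DataFrame,
                                set_scores: pd.DataFrame,
                                top_k: int | None = None) -> pd.DataFrame:
    """Rank gene sets by Pearson correlation of per-sample scores with rho.

    ``set_scores`` is sets x samples (e.g. from geneset_scoring.ssgsea_matrix)
    and must cover the profile samples. Returns the full ranking (or top_k
    head; a k beyond the number of sets returns everything).
    """
    usable = profiles[~profiles["excluded"]].dropna(subset=["rho"])
    missing = [s for s in usable.index if s not in set_scores.columns]
    if missing:
        raise ValueError(f"score matrix lacks samples: {missing[:5]}")
    rho = usable["rho"]
    rows = []
    for name in set_scores.index:
        res = stats_core.pearson_r(set_scores.loc[name, usable.index], rho)
        rows.append({"gene_set": name, "r": res.estimate, "p_value": res.p_value})
    out = pd.DataFrame(rows).set_index("gene_set")
    out = out.sort_values("r", ascending=False, kind="mergesort")
    if top_k is not None:
        out = out.head(top_k)
    return out
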