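"""Synthetic three-arm cohorts (normal / inflammation / tumor) with planted
ground truth for every downstream stage.

The generator produces matched protein and mRNA matrices whose *per-sample*
protein-mRNA Spearman correlation is controlled by a Gaussian copula, plants
differential genes following the nine two-step trend patterns, splice events
whose inclusion levels shift in tumors and co-vary with a designated
regulator protein, survival endpoints whose hazard is tied to concordance
(DRFS analog) and to event inclusion (PFS analog), and one diagnostic marker
protein elevated in tumors.

Rank coupling: for a sample with target Spearman rho the latent bivariate-
normal correlation is r = 2 sin(pi * rho / 6) (the exact inversion of the
Gaussian-copula Spearman formula rho_s = (6/pi) asin(r/2)); the protein
z-scores are r * z(mRNA ranks) + sqrt(1-r^2) * noise, so the realized
per-sample rho converges to the target as the gene count grows.

Inclusion levels are simulated on the logit scale with Gaussian noise and
squashed back to (0,1), so PSI bounds are respected while effects stay
linear where they are planted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

from .omics_io import (ASE_TYPES, OmicsMatrix, PairedCohort, SampleMeta,
                       ENDPOINTS)
from .splicing_landscape import SpliceEventTable

__all__ = ["SynthConfig", "GroundTruth", "simulate_cohort", "write_cohort",
           "synthetic_gene_sets", "STEPS", "PATTERNS"]

STEPS = ("up", "down", "flat")
#: the nine (normal->inflammation, inflammation->tumor) trend patterns
PATTERNS = tuple(f"{s1}_{s2}" for s1 in STEPS for s2 in STEPS)
_STEP_DELTA = {"up": 1.0, "down": -1.0, "flat": 0.0}
ARMS = ("normal", "inflammation", "tumor")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the motivating cohort: arm sizes 13 / 18 / 40, per-arm
    concordance targets matching the reported subgroup medians (normal 0.16,
    inflammation ~0.23, tumor 0.36), a strong regulator coupled to 30
    aberrant events, and one diagnostic protein shifted 1.5 log2 units in
    tumors. Effect switches set to 0 turn a planting off entirely.
    """

    n_per_group: dict = field(default_factory=lambda: {
        "normal": 13, "inflammation": 18, "tumor": 40})
    n_genes: int = 3000
    target_rho: dict = field(default_factory=lambda: {
        "normal": 0.16, "inflammation": 0.23, "tumor": 0.36})
    rho_noise_sd: float = 0.05          # sd of per-sample planted rho around the arm target
    n_pattern_genes: int = 25           # per each of the nine trend patterns
    pattern_effect: float = 1.0         # log2 step size of planted trends
    n_events: int = 120                 # splice events per ASE type
    aberrant_frac: float = 0.25         # fraction of events with a planted tumor shift
    psi_effect: float = 0.2             # planted |delta IncLevel| of aberrant events
    psi_noise_sd: float = 0.3           # logit-scale inclusion noise
    n_sf: int = 20                      # annotated regulator proteins
    sf_coupling: float = 0.8            # regulator->event correlation strength
    events_per_sf: int = 30             # aberrant events coupled to each active regulator
    n_active_sf: int = 1
    marker_effect: float = 1.5          # log2 tumor shift of the diagnostic protein
    mki67_coupling: float = 0.5         # proliferation-proxy vs rho coupling, tumor arm only
    hazard_rho: float = 2.0             # DRFS log-hazard per SD of concordance
    event_hazard_beta: float = 1.5      # PFS log-hazard per SD of a hazard event's PSI
    n_hazard_events: int = 3
    censor_rate: float = 0.15
    missing_rate: float = 0.10          # MCAR missingness, protein layer only
    protein_noise_scale: float = 0.30   # log2-scale sd of the protein copula layer
                                        # (TMT-style ratio-compressed variability)
    mrna_baseline_mean: float = 5.0     # log2(FPKM+1) gene baselines
    mrna_baseline_sd: float = 2.0
    mrna_noise_sd: float = 0.5
    baseline_hazard: float = 1.0 / 24.0  # per month; baseline median survival ~17 months
    seed: int = 0

    def __post_init__(self) -> None:
        for arm in ARMS:
            if arm not in self.n_per_group or self.n_per_group[arm] <= 0:
                raise ValueError(f"n_per_group[{arm!r}] must be a positive count")
            if arm not in self.target_rho:
                raise ValueError(f"target_rho missing arm {arm!r}")
            if not -1.0 <= self.target_rho[arm] <= 1.0:
                raise ValueError("target_rho values must be in [-1,1]")
            if abs(self.target_rho[arm]) >= 1.0 and self.rho_noise_sd > 0:
                raise ValueError(
                    f"infeasible coupling: |target_rho|=1 for arm {arm!r} with "
                    f"nonzero rho noise; the attainable bound with noise is < 1.0")
        for name in ("n_genes", "n_pattern_genes", "n_events", "n_sf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.psi_effect < 1.0:
            raise ValueError("psi_effect must be in (0,1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0,1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if not 0.0 <= self.sf_coupling < 1.0:
            raise ValueError("sf_coupling must be in [0,1)")
        if 9 * self.n_pattern_genes + self.n_sf + 2 > self.n_genes:
            raise ValueError("n_genes too small for the requested plantings")


@dataclass
class GroundTruth:
    """Everything that was planted, keyed the way the matrices emit it."""

    pattern_genes: dict                 # gene -> "up_flat" etc.
    marker_gene: str
    proliferation_gene: str
    sf_genes: list
    active_sfs: list
    coupled_events: dict                # sf -> [event keys]
    aberrant_events: dict               # event key -> planted delta IncLevel
    hazard_events: dict                 # event key -> log-hazard beta (per SD PSI)
    sample_rho: dict                    # sample -> planted per-sample rho
    target_rho: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def spearman_to_pearson(rho: float) -> float:
    """Latent bivariate-normal correlation giving Spearman rho under a
    Gaussian copula: r = 2 sin(pi rho / 6)."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def _uniform_censor_max(rate: float, lam: float) -> float:
    """Upper bound of the U(0, c_max) censoring law giving the requested
    censoring fraction against an Exp(lam) event time."""
    if rate <= 0:
        return math.inf
    # P(censored) = (1 - exp(-a)) / a with a = lam * c_max
    f = lambda a: (1.0 - math.exp(-a)) / a - rate
    a = brentq(f, 1e-9, 1e6)
    return a / lam


def _assign_groups(cfg: SynthConfig, rng: np.random.Generator):
    samples, arms, groups, subtypes = [], [], [], []
    for arm, prefix in (("normal", "N"), ("inflammation", "I"), ("tumor", "T")):
        n = cfg.n_per_group[arm]
        for i in range(n):
            samples.append(f"{prefix}{i + 1:03d}")
            arms.append(arm)
            if arm == "normal":
                groups.append("normal")
                subtypes.append("none")
            elif arm == "inflammation":
                # IOI:RLH roughly 2:1, as in the motivating cohort (12:6)
                groups.append("IOI" if i % 3 != 2 else "RLH")
                subtypes.append("none")
            else:
                groups.append("tumor")
                subtypes.append(rng.choice(
                    ["EMZL", "DLBCL", "MCL", "SLL"], p=[0.70, 0.20, 0.05, 0.05]))
    return samples, np.array(arms), groups, subtypes


def simulate_cohort(cfg: SynthConfig) -> tuple[PairedCohort, SpliceEventTable, GroundTruth]:
    """Simulate one cohort; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(cfg.seed)
    G, width = cfg.n_genes, len(str(cfg.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(G)]
    samples, arms, groups, subtypes = _assign_groups(cfg, rng)
    n_samples = len(samples)
    arm_idx = {a: np.where(arms == a)[0] for a in ARMS}

    # ----- planted gene roles -------------------------------------------------
    perm = rng.permutation(G)
    cursor = 0
    pattern_genes: dict[str, str] = {}
    for pat in PATTERNS:
        for j in range(cfg.n_pattern_genes):
            pattern_genes[genes[perm[cursor]]] = pat
            cursor += 1
    marker_gene = genes[perm[cursor]]; cursor += 1
    prolif_gene = genes[perm[cursor]]; cursor += 1
    sf_genes = [genes[perm[cursor + j]] for j in range(cfg.n_sf)]
    cursor += cfg.n_sf

    # per-gene, per-arm log2 shifts (applied to both layers)
    shift = np.zeros((G, 3))  # columns follow ARMS order
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, pat in pattern_genes.items():
        s1, s2 = pat.split("_")
        d1 = _STEP_DELTA[s1] * cfg.pattern_effect
        d2 = d1 + _STEP_DELTA[s2] * cfg.pattern_effect
        shift[gene_pos[g]] = (0.0, d1, d2)
    arm_col = {a: k for k, a in enumerate(ARMS)}
    sample_arm_col = np.array([arm_col[a] for a in arms])

    # ----- mRNA layer (log2(FPKM+1) scale) -----------------------------------
    baseline = rng.normal(cfg.mrna_baseline_mean, cfg.mrna_baseline_sd, G)
    mrna = (baseline[:, None]
            + shift[:, sample_arm_col]
            + rng.normal(0.0, cfg.mrna_noise_sd, (G, n_samples)))
    mrna = np.maximum(mrna, 0.0)  # log2(FPKM+1) cannot go below 0

    # ----- protein layer via per-sample Gaussian-copula rank coupling --------
    rho_s = np.empty(n_samples)
    for a in ARMS:
        idx = arm_idx[a]
        rho_s[idx] = cfg.target_rho[a] + rng.normal(0.0, cfg.rho_noise_sd, len(idx))
    rho_s = np.clip(rho_s, -1.0, 1.0)
    protein = np.empty((G, n_samples))
    for j in range(n_samples):
        r = spearman_to_pearson(rho_s[j])
        z_m = norm.ppf((rankdata(mrna[:, j]) - 0.5) / G)
        z_p = r * z_m + math.sqrt(max(0.0, 1.0 - r * r)) * rng.normal(0.0, 1.0, G)
        protein[:, j] = cfg.protein_noise_scale * z_p
    protein += shift[:, sample_arm_col]
    protein[gene_pos[marker_gene], arms == "tumor"] += cfg.marker_effect

    # proliferation proxy: couple to planted rho within the tumor arm only
    t_idx = arm_idx["tumor"]
    if len(t_idx) >= 3 and cfg.mki67_coupling > 0:
        z_rho_t = (rho_s[t_idx] - rho_s[t_idx].mean())
        sd = z_rho_t.std()
        z_rho_t = z_rho_t / sd if sd > 0 else z_rho_t
        c = cfg.mki67_coupling
        protein[gene_pos[prolif_gene], t_idx] = (
            cfg.protein_noise_scale
            * (c * z_rho_t + math.sqrt(1 - c * c) * rng.normal(0.0, 1.0, len(t_idx))))
    mki67 = protein[gene_pos[prolif_gene]].copy()

    # ----- splice events ------------------------------------------------------
    tumor_mask = arms == "tumor"
    event_keys, ev_type, ev_gene = [], [], []
    aberrant: dict[str, float] = {}
    theta0_all, theta1_all = [], []
    for t in ASE_TYPES:
        n_ab = int(round(cfg.aberrant_frac * cfg.n_events))
        which_ab = set(range(n_ab))  # first n_ab of each type are aberrant
        for i in range(cfg.n_events):
            key = f"{t}:{i + 1}"
            event_keys.append(key)
            ev_type.append(t)
            ev_gene.append(genes[int(rng.integers(0, G))])
            psi0 = float(rng.uniform(0.2, 0.8))
            if i in which_ab:
                up_ok = psi0 + cfg.psi_effect <= 0.92
                dn_ok = psi0 - cfg.psi_effect >= 0.08
                if up_ok and dn_ok:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                else:
                    sign = 1.0 if up_ok else -1.0
                psi1 = psi0 + sign * cfg.psi_effect
                aberrant[key] = psi1 - psi0
            else:
                psi1 = psi0
            theta0_all.append(logit(psi0))
            theta1_all.append(logit(psi1))
    theta0_all = np.array(theta0_all)
    theta1_all = np.array(theta1_all)
    n_ev_total = len(event_keys)

    # regulator coupling: active SFs drive a block of aberrant events
    active_sfs = sf_genes[:cfg.n_active_sf]
    ab_keys = [k for k in event_keys if k in aberrant]
    # SE events first (the dominant type in real landscapes), then the rest
    ab_sorted = ([k for k in ab_keys if k.startswith("SE:")]
                 + [k for k in ab_keys if not k.startswith("SE:")])
    coupled: dict[str, list[str]] = {}
    pos = 0
    for sf in active_sfs:
        coupled[sf] = ab_sorted[pos:pos + cfg.events_per_sf]
        pos += cfg.events_per_sf
    key_pos = {k: i for i, k in enumerate(event_keys)}

    logit_psi = np.where(tumor_mask[None, :], theta1_all[:, None], theta0_all[:, None])
    logit_psi = logit_psi + rng.normal(0.0, cfg.psi_noise_sd, (n_ev_total, n_samples))
    if cfg.sf_coupling > 0:
        # loading c*sigma with residual sd sigma*sqrt(1-c^2) gives logit-scale
        # regulator-event correlation exactly c at unchanged total variance
        lam = cfg.psi_noise_sd * cfg.sf_coupling
        for sf, evs in coupled.items():
            sfv = protein[gene_pos[sf], t_idx]
            z_sf = (sfv - sfv.mean()) / sfv.std() if sfv.std() > 0 else sfv * 0
            # residual noise shrunk so the total logit variance stays psi_noise_sd^2
            resid_sd = cfg.psi_noise_sd * math.sqrt(1.0 - cfg.sf_coupling ** 2)
            for k in evs:
                sgn = 1.0 if rng.random() < 0.5 else -1.0
                row = key_pos[k]
                logit_psi[row, t_idx] = (
                    theta1_all[row]
                    + sgn * lam * z_sf
                    + rng.normal(0.0, resid_sd, len(t_idx)))
    psi = expit(logit_psi)

    # ----- survival endpoints (tumor arm only) --------------------------------
    hazard_events = {k: cfg.event_hazard_beta
                     for k in ab_sorted[:cfg.n_hazard_events]} if cfg.event_hazard_beta else {}
    z_rho = rho_s[t_idx] - rho_s[t_idx].mean()
    sd = z_rho.std()
    z_rho = z_rho / sd if sd > 0 else z_rho
    lp = {ep: np.zeros(len(t_idx)) for ep in ENDPOINTS}
    lp["DRFS"] = cfg.hazard_rho * z_rho
    for k, beta in hazard_events.items():
        x = psi[key_pos[k], t_idx]
        zx = (x - x.mean()) / x.std() if x.std() > 0 else x * 0
        lp["PFS"] = lp["PFS"] + beta * zx
    meta_rows = {}
    lam0 = cfg.baseline_hazard
    c_max = _uniform_censor_max(cfg.censor_rate, lam0)
    times = {ep: np.full(n_samples, math.nan) for ep in ENDPOINTS}
    events = {ep: np.full(n_samples, math.nan) for ep in ENDPOINTS}
    for ep in ENDPOINTS:
        T = rng.exponential(1.0, len(t_idx)) / (lam0 * np.exp(lp[ep]))
        C = (rng.uniform(0.0, c_max, len(t_idx)) if math.isfinite(c_max)
             else np.full(len(t_idx), math.inf))
        times[ep][t_idx] = np.minimum(T, C)
        events[ep][t_idx] = (T <= C).astype(float)

    # ----- assemble -----------------------------------------------------------
    ldh, ipi, ann = [], [], []
    for a in arms:
        if a == "tumor":
            ldh.append("high" if rng.random() < 0.3 else "normal")
            ipi.append(int(rng.integers(0, 5)))
            ann.append(int(rng.integers(1, 5)))
        else:
            ldh.append("unknown")
            ipi.append(np.nan)
            ann.append(np.nan)
    meta_rows = {
        "group": groups, "subtype": subtypes, "LDH": ldh,
        "IPI": ipi, "AnnArbor": ann, "mki67_protein": mki67,
    }
    for ep in ENDPOINTS:
        meta_rows[f"{ep}_time"] = times[ep]
        meta_rows[f"{ep}_event"] = events[ep]
    meta = SampleMeta(pd.DataFrame(meta_rows, index=pd.Index(samples, name="sample")))

    if cfg.missing_rate > 0:
        miss = rng.random((G, n_samples)) < cfg.missing_rate
        protein = np.where(miss, np.nan, protein)

    cohort = PairedCohort(
        protein=OmicsMatrix("protein", pd.DataFrame(protein, index=genes, columns=samples)),
        mrna=OmicsMatrix("mrna", pd.DataFrame(mrna, index=genes, columns=samples)),
        meta=meta,
    )
    table = SpliceEventTable(
        events=pd.DataFrame({"ase_type": ev_type, "gene": ev_gene}, index=event_keys),
        inc=pd.DataFrame(psi, index=event_keys, columns=samples),
        groups=pd.Series(dict(zip(samples, arms))),
    )
    truth = GroundTruth(
        pattern_genes=pattern_genes,
        marker_gene=marker_gene,
        proliferation_gene=prolif_gene,
        sf_genes=sf_genes,
        active_sfs=active_sfs,
        coupled_events=coupled,
        aberrant_events=aberrant,
        hazard_events=hazard_events,
        sample_rho=dict(zip(samples, rho_s.tolist())),
        target_rho=dict(cfg.target_rho),
    )
    return cohort, table, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def _fmt(v: float) -> str:
    return "NA" if not np.isfinite(v) else _FLOAT_FMT % v


def write_cohort(cohort: PairedCohort, table: SpliceEventTable,
                 truth: GroundTruth, dir_path) -> dict[str, Path]:
    """Write the cohort as the plain-text file set the readers consume.

    Protein is written as positive abundance (2**log2), mRNA as FPKM
    (2**log2(FPKM+1) - 1), so the reader transforms invert exactly up to
    float formatting. One rMATS-dialect table is written per ASE type with
    tumor samples as group 1 and controls as group 2.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    prot = np.power(2.0, cohort.protein.values)
    out["protein"] = d / "protein.tsv"
    prot.to_csv(out["protein"], sep="\t", float_format=_FLOAT_FMT,
                na_rep="NA", index_label="gene")
    mrna = np.power(2.0, cohort.mrna.values) - 1.0
    mrna[mrna < 0] = 0.0
    out["mrna"] = d / "mrna.tsv"
    mrna.to_csv(out["mrna"], sep="\t", float_format=_FLOAT_FMT,
                na_rep="NA", index_label="gene")
    out["metadata"] = d / "metadata.tsv"
    cohort.meta.table.to_csv(out["metadata"], sep="\t", float_format=_FLOAT_FMT,
                             na_rep="NA", index_label="sample")

    tumor = [s for s in table.samples if table.groups[s] == "tumor"]
    control = [s for s in table.samples if table.groups[s] != "tumor"]
    for t in ASE_TYPES:
        rows = []
        sub = table.events[table.events["ase_type"] == t]
        for key in sub.index:
            v1 = table.inc.loc[key, tumor].to_numpy(dtype=float)
            v2 = table.inc.loc[key, control].to_numpy(dtype=float)
            diff = (np.nanmean(v1) - np.nanmean(v2)
                    if np.isfinite(v1).any() and np.isfinite(v2).any() else math.nan)
            rows.append({
                "ID": key.split(":", 1)[1],
                "GeneID": sub.loc[key, "gene"],
                "geneSymbol": sub.loc[key, "gene"],
                "IncLevel1": ",".join(_fmt(v) for v in v1),
                "IncLevel2": ",".join(_fmt(v) for v in v2),
                "IncLevelDifference": _fmt(diff),
                "PValue": "NA",
                "FDR": "NA",
            })
        out[t] = d / f"{t}.MATS.JC.txt"
        pd.DataFrame(rows, columns=["ID", "GeneID", "geneSymbol", "IncLevel1",
                                    "IncLevel2", "IncLevelDifference",
                                    "PValue", "FDR"]).to_csv(out[t], sep="\t", index=False)
    out["ground_truth"] = d / "ground_truth.json"
    out["ground_truth"].write_text(truth.to_json())
    out["sf_list"] = d / "sf_list.txt"
    out["sf_list"].write_text("\n".join(truth.sf_genes) + "\n")
    return out


def synthetic_gene_sets(truth: GroundTruth, genes, n_random: int = 10,
                        set_size: int = 25, seed: int = 0) -> dict[str, list[str]]:
    """Gene sets for enrichment exercises: one set per planted trend pattern
    plus random sets drawn from the gene universe."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets: dict[str, list[str]] = {}
    by_pattern: dict[str, list[str]] = {}
    for g, pat in truth.pattern_genes.items():
        by_pattern.setdefault(pat, []).append(g)
    for pat, members in sorted(by_pattern.items()):
        sets[f"planted_{pat}"] = sorted(members)
    for i in range(n_random):
        sets[f"random_{i + 1}"] = sorted(
            rng.choice(genes, size=min(set_size, len(genes)), replace=False).tolist())
    return sets
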