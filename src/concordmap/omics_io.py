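"""Reading, validation, filtering, imputation and pairing of the omics layers.

The on-disk formats are deliberately plain: TSV abundance matrices with gene
IDs in the first column, a TSV sample-metadata table, rMATS-style junction
tables (one per splice-event type), GMT gene-set collections and one-symbol-
per-line splicing-factor lists.

Abundance conventions: the mRNA layer is stored as nonnegative FPKM and
transformed to log2(FPKM + 1) on read; the protein layer is stored as
positive relative abundance and transformed to log2 on read (TMT-style
relative quantification is ratio-like, so the transformed values are signed).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

ASE_TYPES = ("A3", "A5", "MX", "RI", "SE")
GROUPS = ("normal", "IOI", "RLH", "tumor")
SUBTYPES = ("EMZL", "DLBCL", "MCL", "SLL", "none")
ENDPOINTS = ("PFS", "OS", "RFS", "LRFS", "DRFS")

#: groups collapsed to the three analysis arms
ARM_OF_GROUP = {"normal": "normal", "IOI": "inflammation",
                "RLH": "inflammation", "tumor": "tumor"}


@dataclass
class OmicsMatrix:
    """One abundance layer: genes x samples, NaN marks a missing cell."""

    layer: str                 # "protein" or "mrna"
    values: pd.DataFrame       # float, index = gene IDs, columns = sample IDs

    def __post_init__(self) -> None:
        if self.layer not in ("protein", "mrna"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass
class SampleMeta:
    """Per-sample clinical annotation.

    ``table`` is indexed by sample ID with columns: group (normal/IOI/RLH/
    tumor), subtype, LDH (normal/high/unknown), IPI (int or NaN), AnnArbor
    (int or NaN), mki67_protein (float or NaN) and, per endpoint E in
    PFS/OS/RFS/LRFS/DRFS, columns ``E_time`` (>= 0 or NaN) and ``E_event``
    (0/1 or NaN). IOI and RLH together form the "inflammation" arm.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        bad = set(t["subtype"].dropna()) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")
        for ep in ENDPOINTS:
            tc, ec = f"{ep}_time", f"{ep}_event"
            if tc in t.columns:
                tt = t[tc].dropna()
                if (tt < 0).any():
                    raise ValueError(f"{tc} has negative times")
                ev = t.loc[tt.index, ec].dropna()
                if not ev.isin([0, 1]).all():
                    raise ValueError(f"{ec} must be 0/1")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def arm(self) -> pd.Series:
        """normal / inflammation / tumor per sample."""
        return self.table["group"].map(ARM_OF_GROUP)

    def endpoint(self, name: str) -> pd.DataFrame:
        """(time, event) for one endpoint, restricted to known values."""
        if name not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {name!r}")
        sub = self.table[[f"{name}_time", f"{name}_event"]].dropna()
        sub.columns = ["time", "event"]
        sub["event"] = sub["event"].astype(int)
        return sub


@dataclass
class PairedCohort:
    """Matched protein and mRNA matrices over shared genes and samples."""

    protein: OmicsMatrix
    mrna: OmicsMatrix
    meta: SampleMeta
    n_dropped_genes: int = 0
    n_dropped_samples: int = 0

    def __post_init__(self) -> None:
        if not self.protein.genes.equals(self.mrna.genes):
            raise ValueError("protein and mrna gene indices differ")
        if not self.protein.samples.equals(self.mrna.samples):
            raise ValueError("protein and mrna sample indices differ")
        if len(self.protein.genes) == 0:
            raise ValueError("empty shared gene set")

    @property
    def genes(self) -> pd.Index:
        return self.protein.genes

    @property
    def samples(self) -> pd.Index:
        return self.protein.samples


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _check_rectangular(path: Path) -> None:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        widths = {len(row) for row in reader if row}
    if len(widths) > 1:
        raise ValueError(f"{path}: ragged rows (field counts {sorted(widths)})")


def read_matrix(path, layer: str, transform: bool = True) -> OmicsMatrix:
    """Read a genes-x-samples TSV abundance matrix.

    Blank and "NA" cells become missing; duplicate gene IDs and non-numeric
    cells are rejected. With ``transform`` (default) the layer transform is
    applied: log2(x+1) for mRNA (after a nonnegativity check), log2(x) for
    protein.
    """
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dups}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transform:
        if layer == "mrna":
            if (df < 0).any().any():
                raise ValueError("mRNA abundance must be nonnegative pre-log")
            df = np.log2(df + 1.0)
        elif layer == "protein":
            if (df <= 0).any().any():
                raise ValueError("protein abundance must be positive pre-log")
            df = np.log2(df)
    return OmicsMatrix(layer=layer, values=df)


def filter_low_abundance(m: OmicsMatrix, min_median: float | None = None) -> OmicsMatrix:
    """Drop features whose median (observed) abundance is below a cutoff.

    The cutoff is on the transformed scale. Defaults: mRNA keeps genes with
    median log2(FPKM+1) >= 1 (i.e. FPKM >= 1); protein keeps genes above the
    lowest decile of per-gene medians. Both are configurable because no
    standard exists.
    """
    med = m.values.median(axis=1, skipna=True)
    if min_median is None:
        min_median = 1.0 if m.layer == "mrna" else float(med.quantile(0.10))
    keep = med >= min_median
    if keep.sum() == 0:
        raise ValueError("low-abundance filter removed every feature")
    return OmicsMatrix(layer=m.layer, values=m.values.loc[keep])


def filter_and_impute(m: OmicsMatrix, max_missing_frac: float = 0.2,
                      k_neighbors: int = 10) -> OmicsMatrix:
    """Drop high-missingness features, then KNN-impute the remainder.

    Features missing in more than ``max_missing_frac`` of samples are
    removed; each remaining missing cell is filled with the mean of the
    ``k_neighbors`` nearest samples (Euclidean distance over jointly observed
    features). Idempotent on complete matrices.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0,1]")
    n_samples = m.values.shape[1]
    if k_neighbors < 1 or k_neighbors >= n_samples:
        raise ValueError(f"k_neighbors must be in [1, n_samples-1], got {k_neighbors}")
    frac = m.values.isna().mean(axis=1)
    vals = m.values.loc[frac <= max_missing_frac]
    if vals.isna().all(axis=0).any():
        bad = vals.columns[vals.isna().all(axis=0)].tolist()
        raise ValueError(f"samples with zero observed features: {bad}")
    if not vals.isna().any().any():
        return OmicsMatrix(layer=m.layer, values=vals.copy())
    imputer = KNNImputer(n_neighbors=k_neighbors, weights="uniform",
                         metric="nan_euclidean")
    filled = imputer.fit_transform(vals.to_numpy().T).T  # samples are rows
    return OmicsMatrix(layer=m.layer,
                       values=pd.DataFrame(filled, index=vals.index,
                                           columns=vals.columns))


def build_paired_cohort(protein: OmicsMatrix, mrna: OmicsMatrix,
                        meta: SampleMeta) -> PairedCohort:
    """Intersect genes and samples across layers into a PairedCohort."""
    genes = protein.genes.intersection(mrna.genes)
    samples = protein.samples.intersection(mrna.samples)
    samples = samples.intersection(meta.samples)
    if len(genes) == 0:
        raise ValueError("no shared genes between layers")
    if len(samples) == 0:
        raise ValueError("no shared samples between layers and metadata")
    genes = genes.sort_values()
    samples = samples.sort_values()
    dropped_g = (len(protein.genes) - len(genes)) + (len(mrna.genes) - len(genes))
    dropped_s = (len(protein.samples) - len(samples)) + (len(mrna.samples) - len(samples))
    return PairedCohort(
        protein=OmicsMatrix("protein", protein.values.loc[genes, samples]),
        mrna=OmicsMatrix("mrna", mrna.values.loc[genes, samples]),
        meta=SampleMeta(meta.table.loc[samples].copy()),
        n_dropped_genes=dropped_g,
        n_dropped_samples=dropped_s,
    )


def read_metadata(path) -> SampleMeta:
    """Read the sample-metadata TSV (first column = sample ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMeta(df)


# ---------------------------------------------------------------------------
# rMATS-style junction tables
# ---------------------------------------------------------------------------

_RMATS_COLS = ("ID", "GeneID", "geneSymbol", "IncLevel1", "IncLevel2",
               "IncLevelDifference", "PValue", "FDR")


def _parse_inclevels(cell: str, n_expected: int | None, path, row_id) -> list[float]:
    if not isinstance(cell, str):
        cell = "" if cell is None or (isinstance(cell, float) and math.isnan(cell)) else str(cell)
    parts = cell.split(",") if cell != "" else []
    out = []
    for tok in parts:
        tok = tok.strip()
        if tok in ("NA", "", "nan"):
            out.append(math.nan)
            continue
        try:
            v = float(tok)
        except ValueError as exc:
            raise ValueError(f"{path} event {row_id}: malformed IncLevel list {cell!r}") from exc
        if not -1e-9 <= v <= 1 + 1e-9:
            raise ValueError(f"{path} event {row_id}: IncLevel {v} outside [0,1]")
        out.append(min(max(v, 0.0), 1.0))
    if n_expected is not None and len(out) != n_expected:
        raise ValueError(f"{path} event {row_id}: expected {n_expected} IncLevels, got {len(out)}")
    return out


def read_rmats_table(path, ase_type: str, samples_group1=None,
                     samples_group2=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read one rMATS junction-count table for a single event type.

    Returns ``(events, inc)``: event annotation (ase_type, gene, the file's
    IncLevelDifference/PValue/FDR) indexed by a ``"{type}:{ID}"`` key, and the
    per-sample inclusion-level matrix (events x samples). Sample names for the
    two comma-joined IncLevel columns may be supplied; defaults are generated
    as ``g1_0..`` / ``g2_0..``.
    """
    if ase_type not in ASE_TYPES:
        raise ValueError(f"unknown ASE type {ase_type!r}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _RMATS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing rMATS columns {missing}")
    keys = [f"{ase_type}:{i}" for i in df["ID"]]
    if len(set(keys)) != len(keys):
        raise ValueError(f"{path}: duplicate event IDs within type {ase_type}")
    n1 = len(samples_group1) if samples_group1 is not None else None
    n2 = len(samples_group2) if samples_group2 is not None else None
    rows1, rows2 = [], []
    for key, (_, row) in zip(keys, df.iterrows()):
        v1 = _parse_inclevels(row["IncLevel1"], n1, path, row["ID"])
        v2 = _parse_inclevels(row["IncLevel2"], n2, path, row["ID"])
        if rows1 and (len(v1) != len(rows1[0]) or len(v2) != len(rows2[0])):
            raise ValueError(f"{path} event {row['ID']}: inconsistent IncLevel list length")
        rows1.append(v1)
        rows2.append(v2)
    w1 = len(rows1[0]) if rows1 else (n1 or 0)
    w2 = len(rows2[0]) if rows2 else (n2 or 0)
    if samples_group1 is None:
        samples_group1 = [f"g1_{i}" for i in range(w1)]
    if samples_group2 is None:
        samples_group2 = [f"g2_{i}" for i in range(w2)]
    cols = list(samples_group1) + list(samples_group2)
    inc = pd.DataFrame([a + b for a, b in zip(rows1, rows2)],
                       index=keys, columns=cols, dtype=float)
    events = pd.DataFrame({
        "ase_type": ase_type,
        "gene": df["geneSymbol"].astype(str).to_numpy(),
        "gene_id": df["GeneID"].astype(str).to_numpy(),
        "inc_level_difference": pd.to_numeric(df["IncLevelDifference"], errors="coerce").to_numpy(),
        "p_value": pd.to_numeric(df["PValue"], errors="coerce").to_numpy(),
        "fdr": pd.to_numeric(df["FDR"], errors="coerce").to_numpy(),
    }, index=keys)
    return events, inc


# ---------------------------------------------------------------------------
# gene sets and splicing-factor lists
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name, description, members per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: gene set with 0 members")
            name, _desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if not members:
                raise ValueError(f"{path}:{ln}: gene set {name!r} with 0 members")
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na"] + list(members)) + "\n")


def read_sf_list(path) -> list[str]:
    """Read a splicing-factor list (one gene symbol per line), deduplicated."""
    seen: list[str] = []
    dup = 0
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g:
                continue
            if g in seen:
                dup += 1
            else:
                seen.append(g)
    if dup:
        warnings.warn(f"splicing-factor list contained {dup} duplicate entries",
                      stacklevel=2)
    return seen
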