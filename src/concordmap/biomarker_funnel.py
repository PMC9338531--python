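"""Multi-stage diagnostic-marker funnel on the protein layer.

Stage 1 runs two parallel screens of tumor vs control: differential
expression (proteome thresholds) and per-protein univariate logistic
regression (Wald p < 0.05). Stage 2 intersects the two survivor sets.
Stage 3 repeats cross-validated L1-penalized logistic regression
(n_iterations independent fold splits, lambda by the 1-SE rule) and keeps
proteins whose selection frequency reaches ``freq_min``. Stage 4 refines by
bidirectional BIC-stepwise logistic regression; the retained covariates are
the final markers, benchmarked by rank-based AUC against user-named
reference markers.

Each stage's output is a subset of its input, so the funnel is monotone by
construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffexp, stats_core

__all__ = ["FunnelReport", "univariate_screen", "lasso_select",
           "stepwise_refine", "benchmark_auc", "run_funnel"]


@dataclass
class FunnelReport:
    stage1_de: list[str]
    stage1_logistic: list[str]
    stage2_overlap: list[str]
    frequencies: pd.Series            # selection frequency per overlap protein
    lasso_selected: list[str]
    final_markers: list[str]
    auc_table: pd.DataFrame
    n_iterations: int
    freq_min: float
    seed: int


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (X - X.mean(axis=0)) / sd


def univariate_screen(values: pd.DataFrame, is_tumor, alpha: float = 0.05
                      ) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate logistic screen per protein (Wald p < alpha).

    Proteins with (quasi-)complete separation are refit with Firth's
    bias-reduced likelihood (the documented fallback) so that perfectly
    discriminating markers are not silently lost to diverging Wald tests;
    constant proteins are excluded with a warning.
    """
    y = np.asarray(is_tumor, dtype=float)
    rows = []
    n_constant = 0
    for g in values.index:
        x = values.loc[g].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0.0:
            n_constant += 1
            continue
        xz = (x - x.mean()) / sd
        fit = stats_core.logistic_fit(xz[:, None], y)
        flags = fit.flags
        if "separation" in flags:
            fit = stats_core.logistic_fit(xz[:, None], y, firth=True)
            flags = ("separation", "firth-fallback")
        rows.append({"protein": g, "beta": fit.coef.iloc[1],
                     "p_value": fit.p_values.iloc[1],
                     "flags": ";".join(flags)})
    if n_constant:
        warnings.warn(f"{n_constant} constant proteins excluded from the "
                      f"logistic screen", stacklevel=2)
    detail = pd.DataFrame(rows).set_index("protein")
    kept = detail.index[detail["p_value"] < alpha].tolist()
    return kept, detail


def lasso_select(X: pd.DataFrame, is_tumor, n_iterations: int = 200,
                 freq_min: float = 0.5, seed: int = 0, n_folds: int = 10,
                 lambdas=None) -> tuple[pd.Series, list[str]]:
    """Repeated CV-lasso selection frequencies over fresh fold splits.

    ``X`` is samples x proteins (standardized internally). Each iteration
    re-runs n_folds-fold CV to choose lambda (1-SE rule), refits at that
    lambda on the full data and records the nonzero support; the selected
    set is the proteins whose frequency reaches ``freq_min`` (with
    freq_min = 0, any protein ever selected).
    """
    if X.shape[1] == 0:
        raise ValueError("empty candidate set")
    y = np.asarray(is_tumor, dtype=float)
    Xz = _standardize(X)
    Xm = Xz.to_numpy(dtype=float)
    if lambdas is None:
        lambdas = stats_core.default_lambda_grid(Xm, y)
    # full-data support per grid lambda is iteration-independent: fit once
    path = stats_core.lasso_logistic_path(Xm, y, lambdas)
    support = (path.drop(columns="(Intercept)").to_numpy() != 0.0)
    lam_row = {lam: i for i, lam in enumerate(path.index)}
    counts = np.zeros(X.shape[1])
    for it in range(n_iterations):
        it_seed = (seed * 1_000_003 + it) % (2 ** 31 - 1)
        lam, _ = stats_core.cv_lambda(Xm, y, n_folds=n_folds, seed=it_seed,
                                      lambdas=lambdas)
        counts += support[lam_row[lam]]
    freq = pd.Series(counts / n_iterations, index=X.columns, name="frequency")
    if freq_min > 0:
        selected = freq.index[freq >= freq_min].tolist()
    else:
        selected = freq.index[freq > 0].tolist()
    return freq, selected


def _ic(X: pd.DataFrame, y: np.ndarray, cols: list[str], penalty: float) -> float:
    if cols:
        fit = stats_core.logistic_fit(X[cols].to_numpy(dtype=float), y)
        if "separation" in fit.flags:
            fit = stats_core.logistic_fit(X[cols].to_numpy(dtype=float), y,
                                          ridge=1e-2)
        dev = fit.deviance
    else:
        p1 = y.mean()
        dev = -2.0 * (np.sum(y) * math.log(p1) + np.sum(1 - y) * math.log(1 - p1))
    return dev + penalty * (len(cols) + 1)


def stepwise_refine(selected: list[str], X: pd.DataFrame, is_tumor,
                    criterion: str = "bic") -> list[str]:
    """Bidirectional information-criterion stepwise logistic refinement.

    Starts from the full selected model; at each step the single add (from
    the selected pool) or drop that most lowers the criterion is taken,
    until no move improves. Reaching the empty model is a legitimate
    outcome.

    The default criterion is BIC: with AIC's fixed penalty of 2, a pure
    noise covariate survives whenever its in-sample deviance gain exceeds 2
    — probability P(chi2_1 > 2) ~ 0.16 at *any* sample size — so a handful
    of noise covariates would slip through one run in three. The BIC
    penalty log(n) drives that retention probability to zero as the cohort
    grows. AIC is available via ``criterion="aic"``.
    """
    if not selected:
        raise ValueError("stepwise_refine needs a nonempty selected set")
    y = np.asarray(is_tumor, dtype=float)
    if criterion == "bic":
        penalty = math.log(len(y))
    elif criterion == "aic":
        penalty = 2.0
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    Xz = _standardize(X[selected])
    current = list(selected)
    best = _ic(Xz, y, current, penalty)
    while True:
        moves: list[tuple[float, list[str]]] = []
        for c in current:
            cand = [x for x in current if x != c]
            moves.append((_ic(Xz, y, cand, penalty), cand))
        for c in selected:
            if c not in current:
                cand = current + [c]
                moves.append((_ic(Xz, y, cand, penalty), cand))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], len(m[1])))
        if moves[0][0] < best - 1e-9:
            best, current = moves[0][0], moves[0][1]
        else:
            break
    return sorted(current, key=lambda c: selected.index(c))


def benchmark_auc(final_markers: list[str], reference_markers: list[str],
                  values: pd.DataFrame, is_tumor) -> pd.DataFrame:
    """Rank-based AUC per candidate and reference marker (abundance as score)."""
    y = np.asarray(is_tumor, dtype=int)
    rows = []
    for role, names in (("candidate", final_markers),
                        ("reference", reference_markers)):
        for g in names:
            if g not in values.index:
                raise KeyError(f"marker {g!r} absent from the protein matrix")
            rows.append({"marker": g, "role": role,
                         "auc": stats_core.roc_auc(values.loc[g], y)})
    out = pd.DataFrame(rows, columns=["marker", "role", "auc"])
    return out.sort_values("auc", ascending=False, kind="mergesort").set_index("marker")


def run_funnel(values: pd.DataFrame, is_tumor, reference_markers=(),
               n_iterations: int = 200, freq_min: float = 0.5,
               seed: int = 0, alpha: float = 0.05) -> FunnelReport:
    """The full four-stage funnel on a log-scale protein matrix."""
    is_tumor = np.asarray(is_tumor, dtype=bool)
    de = diffexp.run_de(values, is_tumor, "protein")
    stage1_de = de.index[de["status"] != "ns"].tolist()
    stage1_logit, _ = univariate_screen(values, is_tumor, alpha=alpha)
    overlap = sorted(set(stage1_de) & set(stage1_logit))
    if not overlap:
        raise ValueError("empty overlap set: nothing to feed the lasso stage")
    X = values.loc[overlap].T  # samples x proteins
    freq, selected = lasso_select(X, is_tumor, n_iterations=n_iterations,
                                  freq_min=freq_min, seed=seed)
    final = stepwise_refine(selected, X, is_tumor) if selected else []
    auc = benchmark_auc(final, list(reference_markers), values, is_tumor)
    return FunnelReport(stage1_de=sorted(stage1_de),
                        stage1_logistic=sorted(stage1_logit),
                        stage2_overlap=overlap,
                        frequencies=freq, lasso_selected=selected,
                        final_markers=final, auc_table=auc,
                        n_iterations=n_iterations, freq_min=freq_min,
                        seed=seed)
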