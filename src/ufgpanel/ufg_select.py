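"""Three-stage drug-specificity cascade selecting unique fingerprint genes.

A unique fingerprint gene (UFG) for a drug is a gene that
(1) is quartile-significant (p < 0.0025) for that drug but not for either
    noncognate drug,
(2) shows at least 2-fold quartile-level expression separation
    (|log2fc| >= 1), and
(3) after reintroducing the middle two quartiles, is significant
    (p < 0.05) in a full-panel linear regression of log10 IC50 on
    expression for the cognate drug while nonsignificant for both
    noncognates.

Every stage only removes genes, so UFG sets are nested inside the
stage-1 unique sets and disjoint between drugs by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PanelStudy

__all__ = [
    "RegressionResult",
    "univariate_regression",
    "regress_many",
    "drug_unique_genes",
    "fold_change_filter",
    "select_ufgs",
    "UFG_COLUMNS",
]

UFG_COLUMNS = [
    "gene",
    "cognate_drug",
    "direction",
    "log2fc",
    "p_quartile",
    "slope",
    "intercept",
    "r_squared",
    "p_regression",
]


@dataclass(frozen=True)
class RegressionResult:
    """Univariate OLS line mapping expression to log10 IC50."""

    slope: float
    intercept: float
    r_squared: float
    p: float


def univariate_regression(expr_gene, log10_ic50) -> RegressionResult:
    """OLS of log10 IC50 on one gene's expression with the slope t-test.

    Two-sided p on n-2 degrees of freedom; requires >= 3 points and a
    non-constant predictor.
    """
    x = np.asarray(expr_gene, dtype=float)
    y = np.asarray(log10_ic50, dtype=float)
    if x.size != y.size:
        raise ValueError("expression and IC50 vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 cell lines for regression")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
    )


def regress_many(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Vectorised per-row OLS of ``y`` on each row of ``X``.

    Returns columns slope, intercept, r_squared, p (slope t-test, n-2 df).
    Rows with a constant predictor get NaN statistics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[1] != n:
        raise ValueError("X columns must match y length")
    xm = X.mean(axis=1, keepdims=True)
    ym = y.mean()
    xc = X - xm
    yc = y - ym
    sxx = (xc**2).sum(axis=1)
    syy = float((yc**2).sum())
    sxy = xc @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym - slope * xm[:, 0]
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), np.nan)
        # slope t-test via the correlation form
        t2 = r2 * (n - 2) / np.maximum(1.0 - r2, np.finfo(float).tiny)
        p = 2.0 * stats.t.sf(np.sqrt(t2), n - 2)
    bad = sxx == 0
    for arr in (slope, intercept, r2, p):
        arr[bad] = np.nan
    p[r2 >= 1.0] = 0.0
    return pd.DataFrame({"slope": slope, "intercept": intercept, "r_squared": r2, "p": p})


def drug_unique_genes(
    tables: Mapping[str, pd.DataFrame], alpha_strict: float = 0.0025
) -> dict[str, set[str]]:
    """Stage 1: genes quartile-significant for exactly one drug.

    ``tables`` maps drug -> per-gene differential-expression frame (indexed
    or keyed by gene, with a ``p`` column).  A gene is unique to drug d iff
    p < alpha_strict for d and p >= alpha_strict for every other drug,
    irrespective of direction.
    """
    frames = {}
    for drug, tab in tables.items():
        t = tab.set_index("gene") if "gene" in tab.columns else tab
        frames[drug] = t["p"]
    universes = {frozenset(s.index) for s in frames.values()}
    if len(universes) != 1:
        raise ValueError("differential-expression tables have mismatched gene universes")
    drugs = list(frames)
    sig = pd.DataFrame({d: frames[d] < alpha_strict for d in drugs})
    unique = {}
    for d in drugs:
        others = [o for o in drugs if o != d]
        mask = sig[d] & ~sig[others].any(axis=1)
        unique[d] = set(sig.index[mask])
    return unique


def fold_change_filter(
    genes, table: pd.DataFrame, drug: str, fc_min_log2: float = 1.0
) -> set[str]:
    """Stage 2: keep genes with |log2fc| >= fc_min_log2 for the cognate drug.

    The boundary is inclusive: exactly 2-fold separation passes.
    """
    t = table.set_index("gene") if "gene" in table.columns else table
    if "drug" in t.columns:
        t = t[t["drug"] == drug]
    missing = [g for g in genes if g not in t.index]
    if missing:
        raise KeyError(f"genes missing from table: {missing}")
    return {g for g in genes if abs(t.loc[g, "log2fc"]) >= fc_min_log2}


def select_ufgs(
    tables: Mapping[str, pd.DataFrame],
    panel: PanelStudy,
    alpha_strict: float = 0.0025,
    fc_min_log2: float = 1.0,
    alpha_regression: float = 0.05,
) -> pd.DataFrame:
    """Run the full cascade; returns one UFG record per (gene, cognate drug).

    Stage 3 regresses log10 molar IC50 on expression over the whole panel
    (middle quartiles reintroduced); censored IC50s participate at their
    surrogate values.  A drug may legitimately end with no UFGs.
    """
    expr, potency = panel.joint()
    drugs = list(tables)
    unique = drug_unique_genes(tables, alpha_strict)
    indexed = {
        d: (t.set_index("gene") if "gene" in t.columns else t) for d, t in tables.items()
    }
    log_ic50 = {d: np.log10(potency.drug_ic50(d).to_numpy(float)) for d in drugs}

    records = []
    for drug in drugs:
        candidates = sorted(
            fold_change_filter(unique[drug], tables[drug], drug, fc_min_log2)
        )
        if not candidates:
            continue
        X = expr.data.loc[candidates].to_numpy(float)
        fits = {d: regress_many(X, log_ic50[d]) for d in drugs}
        noncognate = [d for d in drugs if d != drug]
        for i, gene in enumerate(candidates):
            cog = fits[drug].iloc[i]
            if not cog["p"] < alpha_regression:
                continue
            if any(fits[d].iloc[i]["p"] < alpha_regression for d in noncognate):
                continue
            row = indexed[drug].loc[gene]
            records.append(
                {
                    "gene": gene,
                    "cognate_drug": drug,
                    "direction": "up" if row["log2fc"] > 0 else "down",
                    "log2fc": float(row["log2fc"]),
                    "p_quartile": float(row["p"]),
                    "slope": float(cog["slope"]),
                    "intercept": float(cog["intercept"]),
                    "r_squared": float(cog["r_squared"]),
                    "p_regression": float(cog["p"]),
                }
            )
    return pd.DataFrame(records, columns=UFG_COLUMNS)
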