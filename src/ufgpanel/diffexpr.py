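"""Quartile differential expression with an empirical-Bayes moderated t.

Each gene is contrasted between a drug's most and least sensitive cell-line
quartiles on the log2 expression scale, so the effect estimate is a
difference of quartile means of log2 values — a log2 fold-change (ratio of
geometric means on the raw scale); ``|log2fc| >= 1`` is the 2-fold boundary.

Per-gene residual variances are shrunk toward a common prior with the
standard two-group empirical-Bayes scheme: with residual variance ``s2`` on
``d`` degrees of freedom and prior ``(d0, s0_sq)``, the posterior variance is

    s2_tilde = (d0*s0_sq + d*s2) / (d0 + d)

and the moderated t is the mean difference over ``s2_tilde``-based standard
error, referred to a t distribution on ``d0 + d`` degrees of freedom.  The
prior is estimated across genes by method of moments on ``log s2``;
``d0 = 0`` recovers the ordinary pooled two-sample t exactly, ``d0 = inf``
shrinks every gene to the common variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix
from .potency import QuartileAssignment

__all__ = [
    "ModerationHyperparams",
    "estimate_moderation",
    "quartile_log2fc",
    "moderated_t_test",
    "bh_adjust",
    "diffexpr_table",
    "count_significant",
    "zscore_matrix",
]


@dataclass(frozen=True)
class ModerationHyperparams:
    """Prior degrees of freedom and prior variance for variance shrinkage."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if not (self.s0_sq > 0) and self.d0 > 0:
            raise ValueError("prior variance must be positive when d0 > 0")


def _trigamma_inverse(x: float, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationHyperparams:
    """Method-of-moments fit of the variance prior across genes.

    Matches moments of ``log s2`` against the scaled-F model for gene-wise
    sample variances: ``e_g = log(s2_g) - digamma(df/2) + log(df/2)`` has
    mean ``log(s0_sq) + digamma(d0/2) - log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond the sampling term ``trigamma(df/2)``.  If the
    observed spread does not exceed the sampling term, d0 is infinite and
    every gene shares the common variance.

    Genes with zero sample variance are excluded from estimation (their
    log is undefined) but still receive shrinkage downstream.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two genes with positive variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return ModerationHyperparams(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationHyperparams(d0=d0, s0_sq=s0_sq)


def _two_group_arrays(
    expr: ExpressionMatrix, assignment: QuartileAssignment
) -> tuple[np.ndarray, np.ndarray]:
    top = sorted(assignment.top)
    bottom = sorted(assignment.bottom)
    missing = [l for l in top + bottom if l not in expr.data.columns]
    if missing:
        raise KeyError(f"quartile lines missing from expression matrix: {missing}")
    return expr.data[top].to_numpy(float), expr.data[bottom].to_numpy(float)


def quartile_log2fc(
    expr: ExpressionMatrix, assignment: QuartileAssignment, gene: str | None = None
):
    """Mean log2 expression in the top quartile minus the bottom quartile.

    Returns a Series over all genes, or a float when ``gene`` is given.
    """
    x_top, x_bot = _two_group_arrays(expr, assignment)
    fc = pd.Series(x_top.mean(axis=1) - x_bot.mean(axis=1), index=expr.data.index)
    if gene is not None:
        if gene not in fc.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return float(fc[gene])
    return fc


def moderated_t_test(
    expr: ExpressionMatrix,
    assignment: QuartileAssignment,
    hyper: ModerationHyperparams | str = "auto",
) -> pd.DataFrame:
    """Two-group (moderated) t-test of every gene between quartiles.

    ``hyper='auto'`` estimates the variance prior across genes,
    ``hyper='off'`` (or ``ModerationHyperparams(0, ...)``) gives the
    ordinary pooled-variance two-sample t.  Returns a frame with columns
    log2fc, t, p indexed by gene; p is NaN only for an all-constant gene
    tested without moderation.
    """
    x_top, x_bot = _two_group_arrays(expr, assignment)
    n1, n2 = x_top.shape[1], x_bot.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each quartile needs at least 2 lines")
    d = n1 + n2 - 2
    diff = x_top.mean(axis=1) - x_bot.mean(axis=1)
    ss = x_top.var(axis=1, ddof=1) * (n1 - 1) + x_bot.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d

    if hyper == "auto":
        hyper = estimate_moderation(s2, d)
    elif hyper == "off":
        hyper = ModerationHyperparams(d0=0.0, s0_sq=1.0)
    elif not isinstance(hyper, ModerationHyperparams):
        raise TypeError("hyper must be 'auto', 'off' or ModerationHyperparams")

    if np.isinf(hyper.d0):
        s2_tilde = np.full_like(s2, hyper.s0_sq)
        df_total = np.inf
    elif hyper.d0 == 0:
        s2_tilde = s2
        df_total = float(d)
    else:
        s2_tilde = (hyper.d0 * hyper.s0_sq + d * s2) / (hyper.d0 + d)
        df_total = hyper.d0 + d

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[~np.isfinite(t)] = np.nan  # all-constant gene without moderation
    return pd.DataFrame({"log2fc": diff, "t": t, "p": p}, index=expr.data.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diffexpr_table(
    expr: ExpressionMatrix,
    assignment: QuartileAssignment,
    hyper: ModerationHyperparams | str = "auto",
) -> pd.DataFrame:
    """Full per-gene table: gene, drug, log2fc, t, p, q, direction."""
    res = moderated_t_test(expr, assignment, hyper)
    out = res.reset_index(names="gene")
    out.insert(1, "drug", assignment.drug)
    if out["p"].isna().any():
        raise ValueError("undefined p-values; use moderation for constant genes")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def count_significant(table: pd.DataFrame, drug: str, alpha: float) -> tuple[int, int, int]:
    """(n_total, n_up, n_down) genes with p < alpha for one drug."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sub = table[(table["drug"] == drug) & (table["p"] < alpha)]
    n_up = int((sub["direction"] == "up").sum())
    n_down = int((sub["direction"] == "down").sum())
    return n_up + n_down, n_up, n_down


def zscore_matrix(expr: ExpressionMatrix, gene_subset=None) -> pd.DataFrame:
    """Per-gene standardization across lines (mean 0, sample SD 1)."""
    df = expr.data if gene_subset is None else expr.data.loc[list(gene_subset)]
    sd = df.std(axis=1, ddof=1)
    zero = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero:
        raise ValueError(f"zero-variance genes cannot be z-scored: {zero}")
    return df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
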