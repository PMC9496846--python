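"""Ensemble-of-univariate-regressions IC50 prediction ("MVR" models).

An MVR model is not a joint multiple regression: each member gene carries
its own univariate OLS line mapping expression to log10 molar IC50, the
ensemble's raw prediction for a line is the arithmetic mean of the member
predictions, and a final calibration regression of measured on predicted
supplies both the model's significance and its usable equation.  Subset
models are built by ranking members by univariate R^2 and taking the
smallest prefix whose calibration is significant for the cognate drug but
not for either noncognate drug.

Two model families are kept as distinct types to avoid unit confusion:
fitted ensembles operate on log2(RPKM) expression, while published
fixed-coefficient models take raw RPKM (terms of the form
``sign * expression/divisor`` plus an intercept, output in log10[M]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, PanelStudy
from .potency import QuartileAssignment
from .ufg_select import univariate_regression

__all__ = [
    "UnivariateModel",
    "CalibrationResult",
    "EnsembleModel",
    "PublishedModel",
    "fit_univariate_models",
    "ensemble_predict",
    "calibrate",
    "fit_ensemble",
    "prioritize_subset",
    "evaluate_published_model",
    "load_published_model",
    "quartile_mean_prediction",
]


@dataclass(frozen=True)
class UnivariateModel:
    """One gene's line: log10 IC50 = slope * log2(RPKM) + intercept."""

    gene: str
    slope: float
    intercept: float
    r_squared: float
    p: float

    def predict(self, expression) -> np.ndarray:
        return self.slope * np.asarray(expression, dtype=float) + self.intercept


@dataclass(frozen=True)
class CalibrationResult:
    """OLS of measured on predicted log10 IC50."""

    slope: float
    intercept: float
    r_squared: float
    p: float


def fit_univariate_models(
    genes: Sequence[str], panel: PanelStudy, drug: str
) -> list[UnivariateModel]:
    """Fit one OLS line per gene against a drug's log10 molar IC50s."""
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if list(genes).count(g) > 1})
        raise ValueError(f"duplicate genes in model input: {dups}")
    expr, potency = panel.joint()
    y = np.log10(potency.drug_ic50(drug).to_numpy(float))
    models = []
    for gene in genes:
        fit = univariate_regression(expr.gene_values(gene).to_numpy(float), y)
        models.append(
            UnivariateModel(gene, fit.slope, fit.intercept, fit.r_squared, fit.p)
        )
    return models


def ensemble_predict(
    members: Sequence[UnivariateModel], expr: ExpressionMatrix
) -> pd.Series:
    """Per-line arithmetic mean of member predictions (log10 M)."""
    if not members:
        raise ValueError("ensemble has no members")
    missing = [m.gene for m in members if m.gene not in expr.data.index]
    if missing:
        raise KeyError(f"member genes missing from expression matrix: {missing}")
    preds = np.stack([m.predict(expr.gene_values(m.gene)) for m in members])
    return pd.Series(preds.mean(axis=0), index=expr.lines)


def calibrate(predicted, measured) -> CalibrationResult:
    """Regress measured log10 IC50 on predicted; slope t-test p-value."""
    pred = np.asarray(predicted, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if pred.size != meas.size:
        raise ValueError("predicted and measured vectors differ in length")
    if pred.size < 3:
        raise ValueError("need at least 3 lines to calibrate")
    if np.ptp(pred) == 0:
        raise ValueError("constant predicted vector cannot be calibrated")
    res = stats.linregress(pred, meas)
    return CalibrationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
    )


@dataclass(frozen=True)
class EnsembleModel:
    """A fitted MVR ensemble for one drug, with its calibration line.

    ``predict`` returns calibrated predictions by default (raw ensemble mean
    passed through the measured-on-predicted calibration line), which puts
    predictions on the measured log10 IC50 scale.
    """

    drug: str
    members: tuple[UnivariateModel, ...]
    calibration: CalibrationResult

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble has no members")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(m.gene for m in self.members)

    def predict(self, expr: ExpressionMatrix, calibrated: bool = True) -> pd.Series:
        raw = ensemble_predict(self.members, expr)
        if not calibrated:
            return raw
        return self.calibration.slope * raw + self.calibration.intercept


def fit_ensemble(
    genes: Sequence[str], panel: PanelStudy, drug: str
) -> EnsembleModel:
    """Fit member lines and the calibration regression on the same panel."""
    members = fit_univariate_models(genes, panel, drug)
    expr, potency = panel.joint()
    raw = ensemble_predict(members, expr)
    measured = np.log10(potency.drug_ic50(drug).to_numpy(float))
    cal = calibrate(raw.to_numpy(), measured)
    return EnsembleModel(drug=drug, members=tuple(members), calibration=cal)


def prioritize_subset(
    models: Sequence[UnivariateModel],
    panel: PanelStudy,
    cognate_drug: str,
    noncognate_drugs: Sequence[str],
    alpha: float = 0.05,
) -> tuple[EnsembleModel, bool]:
    """Smallest R^2-ranked prefix ensemble that is cognate-specific.

    Members are ordered by descending univariate R^2 (ties by gene symbol);
    for k = 1..K the k-member ensemble is calibrated against the cognate and
    both noncognate measured IC50s, and the first k with cognate p < alpha
    and noncognate p >= alpha for both comparators is returned with
    ``drug_specific=True``.  If no prefix qualifies the full ensemble is
    returned flagged ``drug_specific=False``.
    """
    if not models:
        raise ValueError("no candidate models to prioritize")
    ranked = sorted(models, key=lambda m: (-m.r_squared, m.gene))
    expr, potency = panel.joint()
    measured = {
        d: np.log10(potency.drug_ic50(d).to_numpy(float))
        for d in [cognate_drug, *noncognate_drugs]
    }
    for k in range(1, len(ranked) + 1):
        members = tuple(ranked[:k])
        raw = ensemble_predict(members, expr).to_numpy()
        if np.ptp(raw) == 0:
            continue
        cal = calibrate(raw, measured[cognate_drug])
        if not cal.p < alpha:
            continue
        if all(calibrate(raw, measured[d]).p >= alpha for d in noncognate_drugs):
            return (
                EnsembleModel(drug=cognate_drug, members=members, calibration=cal),
                True,
            )
    members = tuple(ranked)
    raw = ensemble_predict(members, expr).to_numpy()
    cal = calibrate(raw, measured[cognate_drug])
    return EnsembleModel(drug=cognate_drug, members=members, calibration=cal), False


# ---------------------------------------------------------------------------
# published fixed-coefficient models (RPKM in, log10[M] out)


@dataclass(frozen=True)
class PublishedModel:
    """Fixed-coefficient linear panel: sum of sign*(RPKM/divisor) + intercept."""

    drug: str
    terms: tuple[tuple[str, int, float], ...]  # (gene, sign, divisor)
    intercept: float
    expression_units: str = "RPKM"

    def __post_init__(self):
        for gene, sign, divisor in self.terms:
            if divisor == 0:
                raise ValueError(f"zero divisor for gene {gene!r}")
            if sign not in (-1, 1):
                raise ValueError(f"sign must be +/-1 for gene {gene!r}")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _, _ in self.terms)

    def evaluate(self, expression: Mapping[str, float]) -> float:
        """Predicted log10 molar IC50 from per-gene RPKM values."""
        missing = [g for g in self.genes if g not in expression]
        if missing:
            raise KeyError(f"expression missing for model genes: {missing}")
        total = self.intercept
        for gene, sign, divisor in self.terms:
            value = float(expression[gene])
            if value < 0:
                raise ValueError(f"negative RPKM for gene {gene!r}")
            total += sign * value / divisor
        return float(total)

    def predict_lines(self, rpkm: pd.DataFrame) -> pd.Series:
        """Evaluate on a genes x lines RPKM frame."""
        return pd.Series(
            {line: self.evaluate(rpkm[line]) for line in rpkm.columns}
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "drug": self.drug,
                "terms": [
                    {"gene": g, "sign": s, "divisor": d} for g, s, d in self.terms
                ],
                "intercept": self.intercept,
                "expression_units": self.expression_units,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PublishedModel":
        obj = json.loads(text)
        return cls(
            drug=obj["drug"],
            terms=tuple(
                (t["gene"], int(t["sign"]), float(t["divisor"])) for t in obj["terms"]
            ),
            intercept=float(obj["intercept"]),
            expression_units=obj.get("expression_units", "RPKM"),
        )


def evaluate_published_model(
    model: PublishedModel, expression: Mapping[str, float]
) -> float:
    """Functional form of :meth:`PublishedModel.evaluate`."""
    return model.evaluate(expression)


def load_published_model(name: str) -> PublishedModel:
    """Load a shipped model by name (``eribulin_4gene``, ``vinorelbine_5gene``)
    or from a JSON file path."""
    ref = resources.files("ufgpanel").joinpath("models", f"{name}.json")
    if ref.is_file():
        return PublishedModel.from_json(ref.read_text())
    path = Path(name)
    if path.is_file():
        return PublishedModel.from_json(path.read_text())
    raise FileNotFoundError(f"no shipped or on-disk model named {name!r}")


def quartile_mean_prediction(
    predicted: pd.Series,
    measured: pd.Series,
    assignment: QuartileAssignment,
) -> pd.DataFrame:
    """Predicted vs measured quartile means (log10 M) with Welch t-tests.

    For each of the top and bottom sensitivity quartiles, reports mean and
    SEM (sample SD / sqrt(q)) of predicted and measured log10 IC50s plus the
    Welch two-sample p-value comparing them; an accurate model shows no
    significant difference in either quartile.  With predicted identical to
    measured the t statistic is 0 and p is 1.
    """
    missing = [l for l in assignment.lines if l not in predicted.index or l not in measured.index]
    if missing:
        raise KeyError(f"quartile lines missing from predictions: {missing}")
    rows = []
    for side in ("top", "bottom"):
        lines = sorted(getattr(assignment, side))
        pred = predicted[lines].to_numpy(float)
        meas = measured[lines].to_numpy(float)
        if np.ptp(pred) == 0 and np.ptp(meas) == 0:
            p = 1.0 if np.allclose(pred, meas) else 0.0
            tstat = 0.0 if p == 1.0 else np.inf
        else:
            tstat, p = stats.ttest_ind(pred, meas, equal_var=False)
        q = len(lines)
        rows.append(
            {
                "quartile": side,
                "n": q,
                "predicted_mean": float(pred.mean()),
                "predicted_sem": float(pred.std(ddof=1) / np.sqrt(q)),
                "measured_mean": float(meas.mean()),
                "measured_sem": float(meas.std(ddof=1) / np.sqrt(q)),
                "t": float(tstat),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
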