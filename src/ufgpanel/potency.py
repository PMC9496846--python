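"""Potency summaries, censoring surrogates, sensitivity quartiles and overlaps.

For each drug the cell-line panel is split into sensitivity quartiles: the
``q = floor(n/4)`` lines with the lowest IC50s (most sensitive, "top") and
the ``q`` with the highest (least sensitive, "bottom").  These quartiles are
the responder/nonresponder surrogates every downstream stage conditions on.

Measured IC50s exceeding a drug's top tested concentration are replaced by a
surrogate of top concentration + 1 nM and flagged censored; the surrogate
keeps bottom-quartile membership and medians intact while only slightly
underestimating means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import PotencyTable

__all__ = [
    "NM",
    "apply_censoring",
    "summarize_potency",
    "potency_ratio",
    "QuartileAssignment",
    "assign_quartiles",
    "quartile_overlap",
]

NM = 1e-9  # molar per nanomolar


def apply_censoring(
    raw_ic50: float, top_conc: float, out_of_range: bool = False
) -> tuple[float, bool]:
    """Return (ic50, censored) applying the top-concentration surrogate rule.

    A measurement above ``top_conc`` (or explicitly marked out-of-range) is
    replaced by ``top_conc + 1 nM``: a 300 nM top concentration yields a
    301 nM surrogate, a 1000 nM top yields 1001 nM.
    """
    if top_conc <= 0:
        raise ValueError("top concentration must be positive")
    if raw_ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {raw_ic50!r}")
    if out_of_range or raw_ic50 > top_conc:
        return top_conc + NM, True
    return float(raw_ic50), False


def summarize_potency(table: PotencyTable, drug: str | None = None) -> pd.DataFrame:
    """Mean/SD/SEM/median of IC50s per drug, reported in nM.

    SD is the sample (n-1) standard deviation and SEM = SD/sqrt(n); for a
    single line both are undefined (NaN).  Censored surrogates enter as
    values.
    """
    drugs = [drug] if drug is not None else table.drugs
    rows = []
    for d in drugs:
        x = table.drug_ic50(d).to_numpy(dtype=float) / NM
        n = x.size
        sd = float(np.std(x, ddof=1)) if n >= 2 else np.nan
        rows.append(
            {
                "drug": d,
                "n": n,
                "mean_nM": float(np.mean(x)),
                "sd_nM": sd,
                "sem_nM": sd / np.sqrt(n) if n >= 2 else np.nan,
                "median_nM": float(np.median(x)),
            }
        )
    return pd.DataFrame(rows).set_index("drug")


def potency_ratio(summary: pd.DataFrame, drug_a: str, drug_b: str) -> tuple[float, float]:
    """(mean ratio, median ratio) of drug_a over drug_b from a summary table."""
    for d in (drug_a, drug_b):
        if d not in summary.index:
            raise KeyError(f"drug {d!r} not summarized")
    return (
        float(summary.loc[drug_a, "mean_nM"] / summary.loc[drug_b, "mean_nM"]),
        float(summary.loc[drug_a, "median_nM"] / summary.loc[drug_b, "median_nM"]),
    )


@dataclass(frozen=True)
class QuartileAssignment:
    """Sensitivity quartiles for one drug.

    ``ordering`` is the full panel sorted by ascending IC50 (ties broken by
    line identifier); ``top`` holds the q most sensitive lines, ``bottom``
    the q least sensitive.
    """

    drug: str
    ordering: tuple[str, ...]
    q: int

    @property
    def top(self) -> frozenset[str]:
        return frozenset(self.ordering[: self.q])

    @property
    def bottom(self) -> frozenset[str]:
        return frozenset(self.ordering[-self.q:])

    @property
    def middle(self) -> frozenset[str]:
        return frozenset(self.ordering[self.q: -self.q])

    @property
    def lines(self) -> frozenset[str]:
        return frozenset(self.ordering)


def assign_quartiles(table: PotencyTable, drug: str) -> QuartileAssignment:
    """Split a drug's panel into sensitivity quartiles of size floor(n/4).

    Requires n >= 8 so each quartile has at least two lines.  Ordering is
    ascending IC50 with lexicographic line-identifier tie-break, which makes
    the split deterministic and invariant to any strictly monotone transform
    of the IC50 scale.
    """
    ic50 = table.drug_ic50(drug)
    n = len(ic50)
    if n < 8:
        raise ValueError(f"need at least 8 lines to form quartiles, got {n}")
    order = sorted(ic50.index, key=lambda l: (ic50[l], l))
    return QuartileAssignment(drug=drug, ordering=tuple(order), q=n // 4)


def quartile_overlap(
    assignments: list[QuartileAssignment], side: str = "top"
) -> dict[tuple[str, ...], int]:
    """Venn region counts for the top (or bottom) quartiles of several drugs.

    Returns one count per non-empty membership pattern, keyed by the sorted
    tuple of drugs whose quartile contains the lines in that region
    (singletons are the drug-unique counts, the full tuple the shared core).
    Counts over all regions sum to the size of the union.
    """
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    universes = {a.lines for a in assignments}
    if len(universes) != 1:
        raise ValueError("quartile assignments do not share a line universe")
    sets = {a.drug: (a.top if side == "top" else a.bottom) for a in assignments}
    drugs = [a.drug for a in assignments]
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(drugs) + 1):
        for members in itertools.combinations(drugs, r):
            inside = set.intersection(*(set(sets[d]) for d in members))
            for other in drugs:
                if other not in members:
                    inside -= sets[other]
            counts[tuple(sorted(members))] = len(inside)
    return counts
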