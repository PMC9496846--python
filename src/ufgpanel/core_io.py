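"""Typed containers and readers/writers for panel data.

The pipeline works on two joined tables: a genes x cell-lines expression
matrix (log2 RPKM) and a drugs x cell-lines IC50 table in molar units with
per-drug top test concentrations and censoring flags.  All joint analyses
run on the intersection of the cell-line sets.

Units: IC50s are molar everywhere inside the package; nanomolar appears
only at presentation boundaries (summary tables).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PotencyTable",
    "PanelStudy",
    "read_expression_matrix",
    "read_alias_map",
    "read_potency_table",
    "write_expression_matrix",
    "write_potency_table",
    "write_results",
    "write_manifest",
    "read_manifest",
]


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Baseline expression, genes in rows, cell lines in columns, log2(RPKM)."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        _check_unique(df.index, "gene symbols")
        _check_unique(df.columns, "cell-line identifiers")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {df.index[bad[0]]!r}, "
                f"line {df.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def lines(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.data.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return self.data.loc[gene]

    def subset_lines(self, lines) -> "ExpressionMatrix":
        missing = [l for l in lines if l not in self.data.columns]
        if missing:
            raise KeyError(f"lines not in expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(lines)])


@dataclass(frozen=True)
class PotencyTable:
    """Per-drug per-line IC50s (molar) with censoring flags.

    ``ic50``/``censored`` are drugs x lines frames; ``top_conc`` maps each
    drug to its top tested molar concentration.  Censored entries carry the
    surrogate value (top concentration + 1 nM) substituted for an
    out-of-range measurement.
    """

    ic50: pd.DataFrame
    censored: pd.DataFrame
    top_conc: pd.Series

    def __post_init__(self):
        _check_unique(self.ic50.index, "drug names")
        _check_unique(self.ic50.columns, "cell-line identifiers")
        if not self.ic50.index.equals(self.censored.index) or not self.ic50.columns.equals(
            self.censored.columns
        ):
            raise ValueError("ic50 and censored frames must share index/columns")
        vals = self.ic50.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError("IC50 values must be finite and strictly positive")
        missing = [d for d in self.ic50.index if d not in self.top_conc.index]
        if missing:
            raise ValueError(f"top_conc missing for drugs: {missing}")
        if (self.top_conc.loc[self.ic50.index] <= 0).any():
            raise ValueError("top concentrations must be positive")

    @property
    def drugs(self) -> list[str]:
        return list(self.ic50.index)

    @property
    def lines(self) -> list[str]:
        return list(self.ic50.columns)

    def drug_ic50(self, drug: str) -> pd.Series:
        if drug not in self.ic50.index:
            raise KeyError(f"drug {drug!r} not in potency table")
        return self.ic50.loc[drug]

    def subset_lines(self, lines) -> "PotencyTable":
        lines = list(lines)
        missing = [l for l in lines if l not in self.ic50.columns]
        if missing:
            raise KeyError(f"lines not in potency table: {missing}")
        return PotencyTable(
            self.ic50.loc[:, lines], self.censored.loc[:, lines], self.top_conc
        )


@dataclass(frozen=True)
class PanelStudy:
    """An expression matrix joined to a potency table on shared cell lines."""

    expression: ExpressionMatrix
    potency: PotencyTable
    lines: list[str] = field(init=False)

    def __post_init__(self):
        shared = [l for l in self.expression.lines if l in set(self.potency.lines)]
        if not shared:
            raise ValueError("expression and potency tables share no cell lines")
        object.__setattr__(self, "lines", shared)

    def joint(self) -> tuple[ExpressionMatrix, PotencyTable]:
        """Both components restricted to the shared line set, same order."""
        return self.expression.subset_lines(self.lines), self.potency.subset_lines(self.lines)


# ---------------------------------------------------------------------------
# readers


def read_alias_map(path) -> dict[str, str]:
    """Two-column TSV mapping legacy gene symbols to current ones."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"alias map must have exactly 2 columns, got {df.shape[1]}")
    return dict(zip(df[0].str.strip(), df[1].str.strip()))


def apply_alias_map(genes, alias_map: Mapping[str, str]) -> list[str]:
    """Replace legacy symbols; idempotent when the map's targets are current."""
    return [alias_map.get(g, g) for g in genes]


def read_expression_matrix(path, alias_map: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read a genes x lines TSV (first column gene symbols, header line IDs).

    Symbol aliasing (e.g. SEPT10 -> SEPTIN10) is applied before the duplicate
    check, so a collision introduced by aliasing is a hard error naming the
    offending symbols.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if alias_map:
        df.index = pd.Index(apply_alias_map(df.index, alias_map))
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        # locate the first offending cell for the error message
        for col in non_numeric:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()]
            if len(bad_rows):
                raise ValueError(
                    f"non-numeric expression value at gene {bad_rows[0]!r}, line {col!r}"
                )
        raise ValueError(f"non-numeric expression columns: {non_numeric}")
    return ExpressionMatrix(df.astype(float))


def read_potency_table(path, top_conc: Mapping[str, float]) -> PotencyTable:
    """Read a long-format potency TSV with columns line, drug, ic50_molar.

    An ``ic50_molar`` entry is either a positive molar concentration or a
    ``>``-prefixed concentration marking an out-of-range measurement, which
    is replaced by the censoring surrogate (top concentration + 1 nM).
    """
    from .potency import apply_censoring  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"line", "drug", "ic50_molar"}
    if not required.issubset(df.columns):
        raise ValueError(f"potency TSV must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        line = row["line"].strip()
        drug = row["drug"].strip()
        if drug not in top_conc:
            raise ValueError(f"no top concentration supplied for drug {drug!r}")
        raw = row["ic50_molar"].strip()
        if raw.startswith(">"):
            value, censored = apply_censoring(float(raw[1:]), top_conc[drug], out_of_range=True)
        else:
            value, censored = apply_censoring(float(raw), top_conc[drug])
        records.append((drug, line, value, censored))
    rec = pd.DataFrame(records, columns=["drug", "line", "ic50", "censored"])
    if rec.duplicated(["drug", "line"]).any():
        dup = rec[rec.duplicated(["drug", "line"])][["drug", "line"]].iloc[0]
        raise ValueError(f"duplicate potency entry for {tuple(dup)}")
    ic50 = rec.pivot(index="drug", columns="line", values="ic50")
    censored = rec.pivot(index="drug", columns="line", values="censored").astype(bool)
    if ic50.isna().any().any():
        raise ValueError("potency table is not complete over drugs x lines")
    tc = pd.Series({d: float(v) for d, v in top_conc.items()})
    return PotencyTable(ic50.astype(float), censored, tc)


# ---------------------------------------------------------------------------
# writers


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def write_potency_table(table: PotencyTable, path) -> None:
    """Long-format writer; censored entries round-trip as ">top_conc" tokens."""
    rows = []
    for drug in table.drugs:
        for line in table.lines:
            if table.censored.loc[drug, line]:
                token = f">{table.top_conc[drug]:.6g}"
            else:
                token = f"{table.ic50.loc[drug, line]:.10g}"
            rows.append((line, drug, token))
    pd.DataFrame(rows, columns=["line", "drug", "ic50_molar"]).to_csv(
        path, sep="\t", index=False
    )


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each named table as ``<name>.tsv`` with stable column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def write_manifest(out_dir, config: dict, seed: int | None = None) -> Path:
    """JSON run manifest: config, seed and library versions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
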