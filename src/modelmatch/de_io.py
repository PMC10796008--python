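"""Reading, validation, harmonization and writing of differential-expression tables.

A DE table holds one record per gene: a direction of change (+1 up, -1 down),
a p-value, and the derived ranking statistic ``signed_sig``::

    signed_sig = -log10(max(p, p_floor)) * direction

so that strongly significant upregulated genes take large positive values and
strongly significant downregulated genes large negative ones. Gene symbols are
harmonized (uppercased, optionally mapped through an alias table such as an
HGNC-approved-symbol map) so that tables from different species and platforms
can be compared on a shared universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_P_FLOOR = 1e-300

#: canonical column order of a normalized DE table
COLUMNS = ["gene", "direction", "p", "signed_sig"]


class ConfigurationError(ValueError):
    """A required column is missing or a parameter is malformed."""


class EmptyInputError(ValueError):
    """No usable records remain after validation."""


def signed_significance(p: np.ndarray, direction: np.ndarray, p_floor: float = DEFAULT_P_FLOOR) -> np.ndarray:
    """-log10(max(p, p_floor)) * direction, elementwise and always finite."""
    p = np.maximum(np.asarray(p, dtype=float), p_floor)
    return -np.log10(p) * np.asarray(direction, dtype=float)


@dataclass
class DETable:
    """One dataset's differential-expression result, unique by gene.

    ``data`` is a DataFrame with columns gene, direction, p, signed_sig.
    Uniqueness by gene is only guaranteed after :func:`harmonize_symbols`.
    """

    dataset_id: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"DETable missing columns: {missing}")
        if len(self.data) == 0:
            raise EmptyInputError(f"DETable {self.dataset_id!r} has no records")
        self.data = self.data[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene"])

    def signed_sig_by_gene(self) -> pd.Series:
        return self.data.set_index("gene")["signed_sig"]


@dataclass
class SymbolMap:
    """Mapping old symbol -> approved symbol. Identity entries are allowed;
    approved symbols are stored uppercase. Lookup is case-insensitive on the
    old symbol, matching the convention of HGNC alias tables."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        self.entries = {str(k).upper(): str(v).upper() for k, v in self.entries.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SymbolMap":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ConfigurationError(f"symbol map {path} needs two columns")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    @classmethod
    def identity(cls) -> "SymbolMap":
        return cls({})

    def resolve(self, symbol: str) -> str:
        s = str(symbol).upper()
        return self.entries.get(s, s)


def read_de_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    p_floor: float = DEFAULT_P_FLOOR,
    dataset_id: str | None = None,
    sep: str | None = None,
) -> DETable:
    """Read a DE table from delimited text and compute signed significance.

    Parameters
    ----------
    path
        TSV or CSV file with a header row.
    column_map
        Maps the roles ``gene``, ``p`` and one of ``fc`` (signed fold change)
        or ``direction`` (explicit +1/-1) to the file's column names. Default:
        ``{"gene": "gene", "fc": "log2fc", "p": "p"}``. When both ``fc`` and
        ``direction`` are mapped, the fold-change sign wins (single source of
        truth).
    p_floor
        Lower clamp applied to p before the log transform, so p values printed
        as 0 yield a finite statistic.

    Rows with a missing gene symbol or unparseable/out-of-range p are dropped
    and counted in the log. Duplicate gene symbols are retained here; they are
    resolved by :func:`harmonize_symbols`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if p_floor <= 0 or p_floor > 1:
        raise ConfigurationError(f"p_floor must be in (0, 1], got {p_floor}")
    cmap = dict(column_map or {"gene": "gene", "fc": "log2fc", "p": "p"})
    if "gene" not in cmap or "p" not in cmap or not ({"fc", "direction"} & cmap.keys()):
        raise ConfigurationError("column_map must name 'gene', 'p' and 'fc' or 'direction'")

    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep)
    for role, col in cmap.items():
        if col not in raw.columns:
            raise ConfigurationError(f"column {col!r} (role {role!r}) not found in {path}")

    n_in = len(raw)
    gene = raw[cmap["gene"]].astype("string").str.strip()
    p = pd.to_numeric(raw[cmap["p"]], errors="coerce")
    if "fc" in cmap:
        basis = pd.to_numeric(raw[cmap["fc"]], errors="coerce")
    else:
        basis = pd.to_numeric(raw[cmap["direction"]], errors="coerce")

    ok = gene.notna() & (gene != "") & p.notna() & (p >= 0) & (p <= 1) & basis.notna() & (basis != 0)
    dropped = n_in - int(ok.sum())
    if dropped:
        logger.info("%s: dropped %d of %d rows (missing gene/p or zero direction)", path.name, dropped, n_in)
    if not ok.any():
        raise EmptyInputError(f"{path}: all {n_in} rows invalid")

    direction = np.sign(basis[ok].to_numpy(dtype=float)).astype(int)
    pv = p[ok].to_numpy(dtype=float)
    df = pd.DataFrame(
        {
            "gene": gene[ok].to_numpy(dtype=object),
            "direction": direction,
            "p": np.maximum(pv, p_floor),
            "signed_sig": signed_significance(pv, direction, p_floor),
        }
    )
    return DETable(dataset_id=dataset_id or path.stem, data=df)


def write_de_table(t: DETable, path: str | Path, precision: int = 10) -> None:
    """Write a normalized DE table as TSV (gene, direction, p, signed_sig)."""
    t.data.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}g")


def harmonize_symbols(t: DETable, m: SymbolMap | None = None) -> DETable:
    """Uppercase symbols, apply the alias map, and collapse duplicates.

    Duplicates (several probes/transcripts mapping to one symbol) are
    collapsed to the record with the largest ``|signed_sig|``; ties break on
    direction then p for determinism. Unmapped symbols pass through
    uppercased. Idempotent.
    """
    m = m or SymbolMap.identity()
    df = t.data.copy()
    df["gene"] = [m.resolve(g) for g in df["gene"]]
    n_before = len(df)
    df = (
        df.assign(_abs=df["signed_sig"].abs())
        .sort_values(["gene", "_abs", "direction", "p"], ascending=[True, False, True, True], kind="mergesort")
        .drop_duplicates("gene", keep="first")
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    collapsed = n_before - len(df)
    if collapsed:
        logger.info("%s: collapsed %d duplicate symbols", t.dataset_id, collapsed)
    return DETable(dataset_id=t.dataset_id, data=df, metadata=dict(t.metadata))
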