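"""Typed I/O for tissue parameter tables.

A tissue parameter table collects, per cancer type, the gene-expression-space
geometry (tumor-cloud center ``xbar1``, normal radius ``rn``, tumor radius
``rt``, minimal walk length ``r_walk``, fluctuation scale ``d_scale``) together
with stem-cell demography (``n_sc`` stem cells, turnover rate ``m_sc`` per
year) and the observed mean lifetime risk of cancer (``risk``, with standard
deviation ``dev`` across registries).

The package ships a reference table of 15 cancer types (``table2_tissues.tsv``)
compiled from published TCGA principal-component geometry and stem-cell
compilations; 8 of its rows (BRCA, COAD, ESCA, HNSC, LIHC, LUAD, PRAD, THCA)
carry the full set of columns and drive the regression tests.

Column-name mapping to the usual symbols: ``xbar1`` = x̄₁, ``rn`` = Rₙ,
``rt`` = Rₜ, ``r_walk`` = R, ``d_scale`` = D, ``n_sc`` = N_sc, ``m_sc`` = m_sc.
``risk`` and ``dev`` are stored as probabilities (0.04264), never percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "TissueRecord",
    "TissueTable",
    "TissueTableError",
    "read_tissue_table",
    "write_tissue_table",
    "complete_rows",
    "load_reference_table",
    "REFERENCE_TABLE_NAME",
]

REFERENCE_TABLE_NAME = "table2_tissues.tsv"

#: mandatory columns on read
_MANDATORY = ("tissue", "xbar1", "rn", "rt", "d_scale")
_OPTIONAL = ("r_walk", "n_sc", "m_sc", "risk", "dev")

#: |r_walk - (xbar1 - rn - rt)| must not exceed this (printed-precision check)
R_WALK_TOLERANCE = 0.01 + 1e-9


class TissueTableError(ValueError):
    """Raised for malformed or inconsistent tissue tables."""


@dataclass(frozen=True)
class TissueRecord:
    """Model parameters for one tissue.

    Optional fields are ``None`` when absent — never zero, since a zero
    stem-cell count or risk would be a (wrong) number, not a missing one.
    """

    tissue: str
    xbar1: float
    rn: float
    rt: float
    d_scale: float
    r_walk: float | None = None
    n_sc: float | None = None
    m_sc: float | None = None
    risk: float | None = None
    dev: float | None = None

    def __post_init__(self) -> None:
        if not self.tissue:
            raise TissueTableError("tissue label must be non-empty")
        for name in ("xbar1", "rn", "rt", "d_scale"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise TissueTableError(
                    f"{self.tissue}: {name} must be a positive finite number, got {v!r}"
                )
        if self.r_walk is not None:
            derived = self.xbar1 - self.rn - self.rt
            if abs(self.r_walk - derived) > R_WALK_TOLERANCE:
                raise TissueTableError(
                    f"{self.tissue}: r_walk={self.r_walk} inconsistent with "
                    f"xbar1-rn-rt={derived:.4f} (tolerance {R_WALK_TOLERANCE:.3g})"
                )
        if self.risk is not None and not (0.0 < self.risk < 1.0):
            raise TissueTableError(f"{self.tissue}: risk must lie in (0, 1), got {self.risk}")
        if self.n_sc is not None and self.n_sc < 1:
            raise TissueTableError(f"{self.tissue}: n_sc must be >= 1, got {self.n_sc}")
        if self.m_sc is not None and self.m_sc <= 0:
            raise TissueTableError(f"{self.tissue}: m_sc must be > 0, got {self.m_sc}")
        if self.dev is not None and self.dev < 0:
            raise TissueTableError(f"{self.tissue}: dev must be >= 0, got {self.dev}")

    @property
    def minimal_walk_length(self) -> float:
        """R = xbar1 - rn - rt, derived when r_walk was not stored."""
        return self.r_walk if self.r_walk is not None else self.xbar1 - self.rn - self.rt

    @property
    def is_complete(self) -> bool:
        """True when stem-cell demography and observed risk are all present."""
        return self.n_sc is not None and self.m_sc is not None and self.risk is not None


@dataclass(frozen=True)
class TissueTable:
    """Ordered, label-unique collection of :class:`TissueRecord`."""

    records: tuple[TissueRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        labels = [r.tissue for r in self.records]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TissueTableError(f"duplicate tissue labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TissueRecord]:
        return iter(self.records)

    def __getitem__(self, tissue: str) -> TissueRecord:
        for r in self.records:
            if r.tissue == tissue:
                return r
        raise KeyError(tissue)

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(r.tissue for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame; absent values become NaN."""
        cols = [f.name for f in fields(TissueRecord)]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records], columns=cols
        )


def _parse_cell(raw: object) -> float | None:
    """Empty cells and dot-runs ('.', '..', '....') encode a missing value."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or set(s) == {"."} or s.lower() in ("na", "nan"):
        return None
    return float(s)


def read_tissue_table(path: str | Path, dialect: str = "tsv") -> TissueTable:
    """Read a tissue parameter table from TSV (canonical) or CSV.

    Rows that fail numeric parsing are rejected with their 0-based row index
    in the error message; a missing mandatory column is a format error naming
    the column; a duplicated tissue label is a validation error.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise TissueTableError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[TissueRecord] = []
    for idx, row in df.iterrows():
        kwargs: dict[str, object] = {"tissue": str(row["tissue"]).strip()}
        try:
            for col in _MANDATORY[1:]:
                val = _parse_cell(row[col])
                if val is None:
                    raise TissueTableError(f"mandatory field {col} is empty")
                kwargs[col] = val
            for col in _OPTIONAL:
                kwargs[col] = _parse_cell(row[col]) if col in df.columns else None
            records.append(TissueRecord(**kwargs))  # type: ignore[arg-type]
        except (ValueError, TypeError) as exc:
            raise TissueTableError(f"row {idx} ({kwargs.get('tissue', '?')}): {exc}") from exc
    return TissueTable(records=tuple(records), provenance=str(path))


def write_tissue_table(table: TissueTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write a table; absent values are written as empty cells.

    Uses ``repr`` formatting so a read/write round trip reproduces every
    numeric field to full stored precision.
    """
    sep = "\t" if dialect == "tsv" else ","
    cols = [f.name for f in fields(TissueRecord)]
    lines = [sep.join(cols)]
    for r in table.records:
        cells = []
        for c in cols:
            v = getattr(r, c)
            cells.append("" if v is None else (v if isinstance(v, str) else repr(float(v))))
        lines.append(sep.join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def complete_rows(table: TissueTable) -> TissueTable:
    """Subset of records with n_sc, m_sc and risk all present, order preserved."""
    return TissueTable(
        records=tuple(r for r in table.records if r.is_complete),
        provenance=table.provenance + " [complete rows]",
    )


def load_reference_table() -> TissueTable:
    """Load the packaged 15-tissue reference table."""
    ref = resources.files("levyrisk.data") / REFERENCE_TABLE_NAME
    with resources.as_file(ref) as path:
        table = read_tissue_table(path)
    return replace(table, provenance=f"packaged {REFERENCE_TABLE_NAME}")
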