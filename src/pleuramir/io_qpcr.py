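"""Reading and writing Ct matrices, sample sheets and result tables.

Dialect: UTF-8 CSV or TSV with a header row. For the Ct matrix the first
column holds probe identifiers and the header row holds sample identifiers.
Undetected wells may be encoded as ``Undetermined``, ``NA``, an empty cell,
or any numeric above the 40-cycle ceiling; all of these normalize to exactly
40 on read. Probe identifiers are opaque strings — the instrument's
``hsa-miR-1-3p_477820_mir`` style needs no parsing.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CT_CEILING",
    "FormatError",
    "read_ct_matrix",
    "read_sample_sheet",
    "write_ct_matrix",
    "write_sample_sheet",
    "write_de_results",
    "write_marker_evaluations",
]

log = logging.getLogger("pleuramir")

CT_CEILING = 40.0
#: tokens that mean "undetected"; compared case-insensitively
UNDETECTED_TOKENS = {"undetermined", "na", "nan", ""}
GROUP_LABELS = ("control", "cancer")

DE_COLUMNS = ["probe", "logFC", "t", "p", "adj_p", "candidate"]


class FormatError(ValueError):
    """Input file violates the documented dialect."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise FormatError(f"duplicate {what} IDs: {sorted(set(dups))}")


def _parse_ct(token: str, row: str, col: str) -> float:
    s = token.strip()
    if s.lower() in UNDETECTED_TOKENS:
        return CT_CEILING
    try:
        v = float(s)
    except ValueError:
        raise FormatError(
            f"unparseable Ct value {token!r} at probe {row!r}, sample {col!r}"
        ) from None
    if np.isnan(v):
        return CT_CEILING
    if v <= 0 or not np.isfinite(v):
        raise FormatError(
            f"Ct value {v} out of range (0, inf) at probe {row!r}, sample {col!r}")
    if v > CT_CEILING:
        log.warning("clamping Ct %s > %s to ceiling at probe %r, sample %r",
                    v, CT_CEILING, row, col)
        return CT_CEILING
    return v


def read_ct_matrix(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a probes x samples Ct matrix.

    Sentinel tokens and values above the ceiling map to exactly 40; values
    <= 0 and unparseable tokens raise :class:`FormatError` with coordinates.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "probe")
    _check_unique(raw.columns, "sample")
    values = np.empty(raw.shape)
    for j, col in enumerate(raw.columns):
        for i, probe in enumerate(raw.index):
            values[i, j] = _parse_ct(raw.iat[i, j], probe, col)
    out = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    out.index.name = "probe_id"
    return out


def read_sample_sheet(path: str | Path,
                      matrix_sample_ids=None,
                      delimiter: str | None = None) -> pd.DataFrame:
    """Read a sample sheet with mandatory columns ``sample_id`` and ``group``.

    Group labels fold case-insensitively to {control, cancer}. If
    ``matrix_sample_ids`` is given, sheet samples absent from the matrix
    produce a warning and matrix samples absent from the sheet an error.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    sheet = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = {"sample_id", "group"} - set(sheet.columns)
    if missing_cols:
        raise FormatError(f"sample sheet missing columns: {sorted(missing_cols)}")
    _check_unique(sheet["sample_id"], "sample")
    groups = sheet["group"].str.strip().str.lower()
    bad = sorted(set(groups) - set(GROUP_LABELS))
    if bad:
        raise FormatError(
            f"unknown group labels {bad}; accepted labels are {list(GROUP_LABELS)}")
    sheet = sheet.assign(group=groups)
    if matrix_sample_ids is not None:
        matrix_ids = list(matrix_sample_ids)
        extra = [s for s in sheet["sample_id"] if s not in set(matrix_ids)]
        if extra:
            warnings.warn(f"samples in sheet but not in matrix: {extra}",
                          stacklevel=2)
        absent = [s for s in matrix_ids if s not in set(sheet["sample_id"])]
        if absent:
            raise FormatError(f"matrix samples missing from sheet: {absent}")
    return sheet.reset_index(drop=True)


def write_ct_matrix(ct: pd.DataFrame, path: str | Path,
                    delimiter: str = ",") -> None:
    ct.to_csv(path, sep=delimiter)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path,
                       delimiter: str = ",") -> None:
    sheet.to_csv(path, sep=delimiter, index=False)


def write_de_results(results: pd.DataFrame, path: str | Path,
                     delimiter: str = ",") -> None:
    """Write a differential-expression table with the fixed column order
    (probe, logFC, t, p, adj_p, candidate). An empty table writes the header
    only."""
    out = results.rename(columns={"probe_id": "probe", "t_mod": "t"})
    out = out.loc[:, DE_COLUMNS]
    out.to_csv(path, sep=delimiter, index=False)


def write_marker_evaluations(report: pd.DataFrame, path: str | Path,
                             delimiter: str = ",") -> None:
    report.to_csv(path, sep=delimiter, index=False)
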