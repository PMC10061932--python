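"""GROMACS XVG columnar text: '#' comments, '@' grace directives, whitespace
separated numeric columns.  Legend directives name the data columns; the
first column is conventionally the abscissa (named from the xaxis label when
present, else ``x``)."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_xvg", "write_xvg"]

_LEGEND_RE = re.compile(r'@\s*s(\d+)\s+legend\s+"([^"]*)"')
_XAXIS_RE = re.compile(r'@\s*xaxis\s+label\s+"([^"]*)"')


class XvgParseError(ValueError):
    pass


def read_xvg(path: str | Path) -> pd.DataFrame:
    """Parse an XVG file into a DataFrame.

    Columns are named from ``@ s<i> legend`` directives when present,
    positionally (``x``, ``y1``, ``y2``, ...) otherwise.

    Raises
    ------
    XvgParseError
        on ragged rows (with the offending row index) or when no numeric
        rows are present.
    """
    legends: dict[int, str] = {}
    xlabel = "x"
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.startswith("@"):
                m = _LEGEND_RE.match(stripped)
                if m:
                    legends[int(m.group(1))] = m.group(2)
                m = _XAXIS_RE.match(stripped)
                if m and m.group(1):
                    xlabel = m.group(1).split("(")[0].strip() or "x"
                continue
            try:
                values = [float(tok) for tok in stripped.split()]
            except ValueError:
                raise XvgParseError(f"{path}: non-numeric data on line {lineno}") from None
            if rows and len(values) != len(rows[0]):
                raise XvgParseError(
                    f"{path}: ragged row {len(rows)} (line {lineno}): expected "
                    f"{len(rows[0])} columns, got {len(values)}"
                )
            rows.append(values)

    if not rows:
        raise XvgParseError(f"{path}: no numeric data rows found")

    data = np.asarray(rows)
    n_data_cols = data.shape[1] - 1
    names = [xlabel]
    for i in range(n_data_cols):
        names.append(legends.get(i, f"y{i + 1}"))
    return pd.DataFrame(data, columns=names)


def write_xvg(path: str | Path, table: pd.DataFrame, title: str = "monofilm output") -> None:
    """Write a DataFrame as XVG: first column abscissa, the rest legends."""
    if table.shape[1] < 1 or len(table) < 1:
        raise ValueError("cannot write an empty table as XVG")
    cols = list(table.columns)
    with open(path, "w") as fh:
        fh.write(f"# {title}\n")
        fh.write(f'@    title "{title}"\n')
        fh.write(f'@    xaxis  label "{cols[0]}"\n')
        for i, name in enumerate(cols[1:]):
            fh.write(f'@ s{i} legend "{name}"\n')
        for _, row in table.iterrows():
            fh.write(" ".join(f"{v:.10g}" for v in row.to_numpy()) + "\n")
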