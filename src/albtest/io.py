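"""Delimited-text sample readers and JSON/CSV report writers.

Inputs are plain delimited text, one observation per row, 1 or 2 numeric
columns; the dialect (comma / tab / whitespace) and an optional header row
are sniffed.  Missing or non-numeric cells raise with their location —
observations are never silently dropped.  Coordinates are used as given: the
statistic and the LCV bandwidth are jointly scale-equivariant, so no
standardization is applied by default.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["read_sample", "write_report", "load_sonar", "SONAR_URL"]

SONAR_URL = (
    "https://archive.ics.uci.edu/ml/machine-learning-databases/"
    "undocumented/connectionist-bench/sonar/sonar.all-data"
)


def _sniff_sep(text: str) -> str | None:
    try:
        return csv.Sniffer().sniff(text, delimiters=",;\t").delimiter
    except csv.Error:
        return None  # whitespace-delimited


def read_sample(path, columns: Sequence[int | str] | None = None) -> np.ndarray:
    """Read a sample: (k,) for univariate files, (k, 2) for bivariate.

    ``columns`` selects columns by index or header name; by default all
    columns are used and the file must have 1 or 2 of them.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    sep = _sniff_sep(text.splitlines()[0])
    kwargs: dict[str, Any] = (
        {"sep": sep} if sep else {"sep": r"\s+", "engine": "python"}
    )
    first = pd.read_csv(_io.StringIO(text), header=None, nrows=1, **kwargs)
    has_header = not np.issubdtype(first.dtypes.iloc[0], np.number)
    df = pd.read_csv(
        _io.StringIO(text), header=0 if has_header else None, **kwargs
    )
    if columns is not None:
        cols = [
            df.columns[c] if isinstance(c, int) else c for c in columns
        ]
        df = df[cols]
    if df.shape[1] not in (1, 2):
        raise ValueError(
            f"{path}: expected 1 or 2 numeric columns, found {df.shape[1]}"
        )
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at row {r + 1}, "
            f"column {df.columns[c]!r} ({df.iat[r, c]!r})"
        )
    return values[:, 0] if values.shape[1] == 1 else values


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(result: Any, config: dict[str, Any], path) -> None:
    """Write a result artifact with its full config echo and package version.

    DataFrames go to CSV (config echoed in ``#``-prefixed header lines);
    everything else to JSON under ``{"config": …, "result": …}``.
    """
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        with path.open("w") as fh:
            meta = {"version": __version__, **config}
            for key, value in meta.items():
                fh.write(f"# {key}: {value}\n")
            result.to_csv(fh, index=False)
        return
    payload = {
        "version": __version__,
        "config": _jsonable(config),
        "result": _jsonable(result),
    }
    path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")


def load_sonar(
    path=None, *, download: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Connectionist-bench sonar data, first two variables per class.

    Returns (metal, rock) arrays of shape (111, 2) and (97, 2): the energies
    at the two smallest aspect angles for signals bounced off metal cylinders
    and rocks.  ``path`` points at a local copy of ``sonar.all-data``;
    ``download=True`` fetches it from the UCI repository (explicit opt-in —
    nothing in this package touches the network otherwise).
    """
    if path is None:
        if not download:
            raise FileNotFoundError(
                "no local sonar.all-data given; pass path= or download=True"
            )
        import urllib.request

        with urllib.request.urlopen(SONAR_URL, timeout=30) as resp:
            text = resp.read().decode()
    else:
        text = Path(path).read_text()
    rows = [line.split(",") for line in text.strip().splitlines()]
    if any(len(r) != 61 for r in rows):
        raise ValueError("expected 60 numeric columns plus a class label per row")
    values = np.array([[float(r[0]), float(r[1])] for r in rows])
    labels = np.array([r[60].strip() for r in rows])
    metal, rock = values[labels == "M"], values[labels == "R"]
    if len(metal) != 111 or len(rock) != 97:
        raise ValueError(
            f"unexpected class sizes: {len(metal)} metal, {len(rock)} rock"
        )
    return metal, rock
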