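"""Readers and writers for feature tables, label files and model bundles.

Feature tables follow the UCI-HAR on-disk layout: one fixed-length window per
line, whitespace-separated real features (``X_train.txt``).  Labels are one
integer activity per line (``y_train.txt``), 1-based.  CSV is accepted with an
auto-detected header row.  Model bundles are directories of JSON files so that
they are human-inspectable and round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError


def load_feature_table(path, dialect: str = "whitespace") -> np.ndarray:
    """Load a T x p feature table, preserving file row order.

    Parameters
    ----------
    path : str or Path
    dialect : {"whitespace", "csv"}
        ``whitespace``: space-separated reals, no header.  ``csv``: comma
        separated; a non-numeric first row is treated as a header and skipped.

    Returns
    -------
    ndarray of shape (T, p), float64.
    """
    path = Path(path)
    if dialect not in ("whitespace", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = r"\s+" if dialect == "whitespace" else ","
    kwargs = dict(sep=sep, dtype=np.float64, float_precision="round_trip")
    try:
        df = pd.read_csv(path, header=None, **kwargs)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged rows ({exc})") from None
    except ValueError:
        if dialect == "csv":
            # retry assuming a header row
            try:
                df = pd.read_csv(path, header=0, **kwargs)
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell ({exc})") from None
        else:
            raise FormatError(f"{path}: non-numeric cell") from None
    if df.isna().to_numpy().any():
        bad = int(df.isna().any(axis=1).to_numpy().argmax()) + 1
        raise FormatError(f"{path}: ragged or missing values at data line {bad}")
    X = df.to_numpy(dtype=np.float64)
    if not np.isfinite(X).all():
        raise FormatError(f"{path}: non-finite value in feature table")
    return X


def load_labels(path, n_classes: int | None = None) -> tuple[np.ndarray, int]:
    """Load a 1-based integer label sequence, one label per line.

    Returns ``(labels, n_classes)`` where ``n_classes`` defaults to the
    maximum label observed.
    """
    path = Path(path)
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                val = int(line)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer label {line!r} at line {lineno}"
                ) from None
            labels.append(val)
    if not labels:
        raise FormatError(f"{path}: file is empty")
    y = np.asarray(labels, dtype=np.int64)
    if y.min() < 1:
        raise ValueError(f"{path}: labels are 1-based; found {y.min()}")
    if n_classes is None:
        n_classes = int(y.max())
    elif y.max() > n_classes:
        raise ValueError(f"{path}: label {y.max()} exceeds n_classes={n_classes}")
    return y, n_classes


def save_labels(path, labels) -> None:
    """Write one integer label per line."""
    labels = np.asarray(labels, dtype=np.int64)
    Path(path).write_text("".join(f"{v}\n" for v in labels))


def save_feature_table(path, X, dialect: str = "whitespace") -> None:
    """Write a feature table in the layout `load_feature_table` reads."""
    X = np.asarray(X, dtype=np.float64)
    sep = " " if dialect == "whitespace" else ","
    with open(path, "w") as fh:
        for row in X:
            fh.write(sep.join(repr(float(v)) for v in row) + "\n")


# --------------------------------------------------------------------------
# JSON round-tripping for fitted models.  float repr round-trips exactly in
# Python 3, so serialize -> load reproduces every parameter bit-for-bit.

def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def dump_json(path, payload: dict) -> None:
    """Serialize a parameter dictionary deterministically."""
    with open(path, "w") as fh:
        json.dump(_to_jsonable(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
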