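"""Reading data matrices and writing run outputs.

Supported inputs: delimited text (CSV/TSV; samples as rows, header row and
index column) and Matrix Market (.mtx) triplet files with optional separate
row/column name files.  MTX input is densified behind a memory guard.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .model import DataMatrix

__all__ = [
    "read_matrix",
    "write_labels",
    "write_similarity",
    "write_kn_distribution",
    "write_trace",
    "write_draws",
    "write_manifest",
    "read_manifest",
]

_MAX_DENSE_ENTRIES = 2_000_000_000


def _check_finite(Y: np.ndarray, names_r, names_c) -> None:
    bad = np.argwhere(~np.isfinite(Y))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-finite entry at row '{names_r[i]}' (index {i}), column '{names_c[j]}' (index {j})"
        )


def read_matrix(
    path: str | Path,
    fmt: str | None = None,
    transpose: bool = False,
    row_names_file: str | Path | None = None,
    col_names_file: str | Path | None = None,
) -> DataMatrix:
    """Read a samples x variables matrix from CSV, TSV, or Matrix Market.

    ``fmt`` is inferred from the extension when omitted; ``transpose``
    flips a variables x samples file (common for expression matrices).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        ext = path.suffix.lower().lstrip(".")
        fmt = {"csv": "csv", "tsv": "tsv", "txt": "tsv", "mtx": "mtx"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from extension '.{ext}'; pass fmt explicitly")
    if fmt in {"csv", "tsv"}:
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"malformed {fmt.upper()} file {path}: {exc}") from exc
        Y = df.to_numpy(dtype=float)
        rows = [str(r) for r in df.index]
        cols = [str(c) for c in df.columns]
    elif fmt == "mtx":
        M = mmread(str(path))
        if M.shape[0] * M.shape[1] > _MAX_DENSE_ENTRIES:
            raise ValueError(
                f"matrix of shape {M.shape} would densify to more than {_MAX_DENSE_ENTRIES} entries"
            )
        Y = np.asarray(M.todense() if hasattr(M, "todense") else M, dtype=float)
        rows = _read_names(row_names_file, Y.shape[0], "row")
        cols = _read_names(col_names_file, Y.shape[1], "col")
    else:
        raise ValueError(f"unknown format '{fmt}' (expected csv, tsv, or mtx)")
    if transpose:
        Y = Y.T
        rows, cols = cols, rows
    _check_finite(Y, rows, cols)
    return DataMatrix(Y=Y, row_names=rows, col_names=cols)


def _read_names(path, size: int, prefix: str) -> list[str]:
    if path is None:
        return [f"{prefix}{i}" for i in range(size)]
    names = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if len(names) != size:
        raise ValueError(f"{prefix}-name file has {len(names)} entries for {size} {prefix}s")
    return names


def write_labels(path: str | Path, labels: np.ndarray, row_names=None) -> None:
    names = row_names if row_names is not None else [f"row{i}" for i in range(len(labels))]
    pd.DataFrame({"sample": names, "cluster": np.asarray(labels, dtype=int)}).to_csv(path, index=False)


def write_similarity(path: str | Path, P: np.ndarray, row_names=None) -> None:
    names = row_names if row_names is not None else [f"row{i}" for i in range(P.shape[0])]
    pd.DataFrame(P, index=names, columns=names).to_csv(path)


def write_kn_distribution(path: str | Path, values: np.ndarray, probs: np.ndarray) -> None:
    pd.DataFrame({"kn": values, "probability": probs}).to_csv(path, index=False)


def write_trace(path: str | Path, kn_trace: np.ndarray, alpha_trace: np.ndarray) -> None:
    pd.DataFrame(
        {"iteration": np.arange(len(kn_trace)), "kn": kn_trace, "alpha": alpha_trace}
    ).to_csv(path, index=False)


def write_draws(path: str | Path, draws: np.ndarray, iteration_index=None) -> None:
    m, n = draws.shape
    df = pd.DataFrame(draws, columns=[f"row{i}" for i in range(n)])
    df.insert(0, "iteration", iteration_index if iteration_index is not None else np.arange(m))
    df.to_csv(path, index=False)


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
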