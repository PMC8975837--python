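"""Plain-text readers and writers for pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import TimeSeriesData

__all__ = [
    "save_series_tsv",
    "load_series_tsv",
    "save_matrix_tsv",
    "load_matrix_tsv",
    "save_partition_tsv",
    "load_partition_tsv",
]


def save_series_tsv(ts: TimeSeriesData, path: str | Path) -> None:
    """Frames as rows, one column per region (header row of region ids)."""
    df = pd.DataFrame(ts.values.T, columns=ts.region_ids)
    df.to_csv(path, sep="\t", index=False)


def load_series_tsv(path: str | Path, tr_seconds: float = 0.72) -> TimeSeriesData:
    df = pd.read_csv(path, sep="\t")
    return TimeSeriesData(
        df.to_numpy().T, tr_seconds=tr_seconds, region_ids=list(df.columns)
    )


def save_matrix_tsv(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t")


def load_matrix_tsv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def save_partition_tsv(
    region_ids: list[str], modules: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame({"region_id": region_ids, "module_id": modules}).to_csv(
        path, sep="\t", index=False
    )


def load_partition_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
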