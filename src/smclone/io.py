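"""Readers and writers for count matrices and result bundles.

Count matrices are delimited text (tab by default, comma auto-detected) with
a header row of sample identifiers and a first column of locus identifiers —
the shape gene-by-sample mutation tables come in.  Loci carry no genomic
coordinates here; the row order of the input file is the order in which the
sequential sampler processes loci.

Result and ground-truth bundles are directories of TSV matrices plus a JSON
sidecar holding scalars, the configuration echo and the seed, so every run
is self-describing and exactly repeatable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .observation import ReadCountData, success_probability_matrix
from .simulate import GroundTruth, SimConfig
from .smc import PosteriorSummary, SMCConfig

__all__ = [
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "load_read_counts",
    "write_results",
    "load_results",
    "write_simulation",
    "load_truth",
]


class FormatError(ValueError):
    """An input table violates the expected count-matrix format."""


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled integer matrix (loci x samples) from delimited text."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"input file is empty: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # ragged rows, undecodable bytes, ...
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path} contains no data rows/columns")
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != np.floor(values))
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise FormatError(
                f"{path}: non-integer cell at row {row!r}, column {col!r}"
            )
        df[col] = values.astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def load_read_counts(y_path: str | Path, v_path: str | Path) -> ReadCountData:
    """Load and cross-validate the variant (Y) and total (V) count tables."""
    y_df = read_count_matrix(y_path)
    v_df = read_count_matrix(v_path)
    if y_df.shape != v_df.shape:
        raise FormatError(
            f"Y is {y_df.shape} but V is {v_df.shape}; shapes must match"
        )
    if list(y_df.index) != list(v_df.index) or list(y_df.columns) != list(
        v_df.columns
    ):
        raise FormatError("Y and V row/column labels do not match")
    try:
        return ReadCountData(
            Y=y_df.to_numpy(),
            V=v_df.to_numpy(),
            locus_ids=list(y_df.index),
            sample_ids=list(y_df.columns),
        )
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def _matrix_frame(
    M: np.ndarray, index: list[str], columns: list[str]
) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(M), index=index, columns=columns)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(
    summary: PosteriorSummary,
    outdir: str | Path,
    config: SMCConfig | None = None,
    data: ReadCountData | None = None,
) -> None:
    """Write Z_hat.tsv, W_hat.tsv and summary.json for one inference run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c = summary.Z_hat.shape[1]
    loci = data.locus_ids if data is not None else [
        f"locus_{t + 1:04d}" for t in range(summary.Z_hat.shape[0])
    ]
    samples = data.sample_ids if data is not None else [
        f"sample_{s + 1:02d}" for s in range(summary.W_hat.shape[1])
    ]
    subclones = [f"subclone_{k + 1}" for k in range(c)]
    _matrix_frame(summary.Z_hat, loci, subclones).to_csv(
        outdir / "Z_hat.tsv", sep="\t"
    )
    _matrix_frame(summary.W_hat, ["noise"] + subclones, samples).to_csv(
        outdir / "W_hat.tsv", sep="\t"
    )
    payload = {
        "c_pmf": {str(k): v for k, v in sorted(summary.c_pmf.items())},
        "c_map": summary.c_map,
        "p_hat": summary.p_hat,
        "ess_trace": summary.ess_trace,
        "seed": config.seed if config is not None else None,
        "config": _jsonable(config) if config is not None else None,
    }
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2))


def load_results(outdir: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read back (Z_hat, W_hat, p_hat) from a result bundle directory."""
    outdir = Path(outdir)
    Z_hat = pd.read_csv(outdir / "Z_hat.tsv", sep="\t", index_col=0).to_numpy(
        dtype=float
    )
    W_hat = pd.read_csv(outdir / "W_hat.tsv", sep="\t", index_col=0).to_numpy(
        dtype=float
    )
    summary = json.loads((outdir / "summary.json").read_text())
    return Z_hat, W_hat, float(summary["p_hat"])


def write_simulation(
    outdir: str | Path,
    data: ReadCountData,
    truth: GroundTruth,
    config: SimConfig,
) -> None:
    """Write Y/V count tables and the ground-truth bundle for a simulation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    y_df = _matrix_frame(data.Y, data.locus_ids, data.sample_ids)
    v_df = _matrix_frame(data.V, data.locus_ids, data.sample_ids)
    write_count_matrix(y_df, outdir / "Y.tsv")
    write_count_matrix(v_df, outdir / "V.tsv")
    subclones = [f"subclone_{k + 1}" for k in range(truth.Z_true.shape[1])]
    _matrix_frame(truth.Z_true, data.locus_ids, subclones).to_csv(
        outdir / "Z_true.tsv", sep="\t"
    )
    _matrix_frame(truth.W_true, ["noise"] + subclones, data.sample_ids).to_csv(
        outdir / "W_true.tsv", sep="\t"
    )
    payload = {"p_true": truth.p_true, "config": _jsonable(config)}
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2))


def load_truth(outdir: str | Path) -> GroundTruth:
    """Read back a ground-truth bundle written by :func:`write_simulation`."""
    outdir = Path(outdir)
    Z = pd.read_csv(outdir / "Z_true.tsv", sep="\t", index_col=0).to_numpy(
        dtype=float
    )
    W = pd.read_csv(outdir / "W_true.tsv", sep="\t", index_col=0).to_numpy(
        dtype=float
    )
    meta = json.loads((outdir / "truth.json").read_text())
    p = float(meta["p_true"])
    return GroundTruth(
        Z_true=Z, W_true=W, p_true=p,
        P_true=success_probability_matrix(Z, W, p),
    )
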