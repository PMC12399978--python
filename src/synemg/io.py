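"""File formats: CSV and STO/MOT-dialect time series, dataset directories.

Time-series files carry one time column (seconds, strictly increasing) plus
one column per channel.  The STO/MOT dialect is the tab-delimited layout
used by musculoskeletal-simulation exports: free-form header lines
(``name``, ``nRows=``, ``nColumns=``, ``inDegrees=``) terminated by a line
reading ``endheader``, then a column-label row and the data block.

A synthetic dataset is persisted as a directory of such files plus a
``meta.yaml`` with grid/labels/nominal parameters, so the command-line
stages can hand data to each other through the filesystem.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SyntheticDataset

__all__ = ["read_timeseries", "write_timeseries", "save_dataset", "load_dataset"]

TIME = "time"


class ParseError(ValueError):
    pass


def _check_frame(df: pd.DataFrame, path, line_offset: int = 0) -> pd.DataFrame:
    if TIME not in df.columns:
        # first column is the time column by convention
        df = df.rename(columns={df.columns[0]: TIME})
    t = df[TIME].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ParseError(f"{path}: non-monotone time at data line {bad[0] + 2 + line_offset}")
    return df


def read_timeseries(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a labelled time series (CSV or STO/MOT dialect).

    ``dialect`` is inferred from the suffix when omitted ('.sto'/'.mot' ->
    sto_mot, else csv).  Returns a DataFrame whose first column is 'time'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect is None:
        dialect = "sto_mot" if path.suffix.lower() in (".sto", ".mot") else "csv"
    if dialect == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as err:
            raise ParseError(f"{path}: {err}") from err
        return _check_frame(df, path)
    if dialect == "sto_mot":
        return _read_sto(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_sto(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    n_rows = n_cols = None
    for k, line in enumerate(lines):
        s = line.strip()
        if s.lower() == "endheader":
            break
        if s.lower().startswith("nrows="):
            n_rows = int(s.split("=", 1)[1])
        if s.lower().startswith("ncolumns="):
            n_cols = int(s.split("=", 1)[1])
    else:
        raise ParseError(f"{path}: no 'endheader' sentinel found")
    body = "\n".join(lines[k + 1:])
    df = pd.read_csv(_io.StringIO(body), sep="\t")
    if n_cols is not None and df.shape[1] != n_cols:
        raise ParseError(f"{path}: header declares nColumns={n_cols}, "
                         f"found {df.shape[1]}")
    if n_rows is not None and df.shape[0] != n_rows:
        raise ParseError(f"{path}: header declares nRows={n_rows}, "
                         f"found {df.shape[0]}")
    return _check_frame(df, path, line_offset=k + 1)


def write_timeseries(df: pd.DataFrame, path, dialect: str | None = None,
                     name: str | None = None) -> Path:
    """Write a labelled time series; the inverse of :func:`read_timeseries`."""
    path = Path(path)
    if dialect is None:
        dialect = "sto_mot" if path.suffix.lower() in (".sto", ".mot") else "csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "csv":
        df.to_csv(path, index=False, float_format="%.10g")
        return path
    if dialect == "sto_mot":
        header = [name or path.stem, "version=1", f"nRows={df.shape[0]}",
                  f"nColumns={df.shape[1]}", "inDegrees=no", "endheader"]
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# dataset directories
# ---------------------------------------------------------------------------

def _stack_to_frame(arr: np.ndarray, dt: float, labels) -> pd.DataFrame:
    """(C, n, k) -> flat frame with a global time column."""
    C, n, k = arr.shape
    t = np.arange(C * n) * dt
    return pd.DataFrame({TIME: t, **{lab: arr.reshape(C * n, k)[:, j]
                                     for j, lab in enumerate(labels)}})


def _frame_to_stack(df: pd.DataFrame, n_cycles: int, labels) -> np.ndarray:
    vals = df[list(labels)].to_numpy(dtype=float)
    n = vals.shape[0] // n_cycles
    return vals.reshape(n_cycles, n, len(labels))


def save_dataset(dataset: SyntheticDataset, out_dir, meta_extra: dict | None = None) -> Path:
    """Write a dataset directory (STO-dialect series + meta.yaml)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dt, mlab, dlab = dataset.dt, dataset.muscle_labels, dataset.dof_labels
    write_timeseries(_stack_to_frame(dataset.envelopes, dt, mlab),
                     out / "envelopes.sto")
    write_timeseries(_stack_to_frame(dataset.lmt, dt, mlab), out / "lmt.sto")
    write_timeseries(_stack_to_frame(dataset.ref_moments, dt, dlab),
                     out / "ref_moments.sto")
    write_timeseries(_stack_to_frame(dataset.activations_true, dt, mlab),
                     out / "activations_true.sto")
    for i, dof in enumerate(dlab):
        write_timeseries(_stack_to_frame(dataset.moment_arms[:, :, i, :], dt, mlab),
                         out / f"moment_arms_{dof}.sto")
    meta = {"n_cycles": int(dataset.n_cycles), "dt": float(dt),
            "muscles": list(mlab), "dofs": list(dlab)}
    if meta_extra:
        meta.update(meta_extra)
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return out


def load_dataset(in_dir) -> tuple[SyntheticDataset, dict]:
    """Read a dataset directory back into cycle-stacked arrays."""
    d = Path(in_dir)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    C = meta["n_cycles"]
    mlab, dlab = meta["muscles"], meta["dofs"]
    env = _frame_to_stack(read_timeseries(d / "envelopes.sto"), C, mlab)
    lmt = _frame_to_stack(read_timeseries(d / "lmt.sto"), C, mlab)
    mom = _frame_to_stack(read_timeseries(d / "ref_moments.sto"), C, dlab)
    act = _frame_to_stack(read_timeseries(d / "activations_true.sto"), C, mlab)
    arms = np.stack([_frame_to_stack(read_timeseries(d / f"moment_arms_{dof}.sto"),
                                     C, mlab) for dof in dlab], axis=2)
    ds = SyntheticDataset(env, lmt, arms, mom, act, env.copy(), mom.copy(),
                          meta["dt"], list(mlab), list(dlab))
    return ds, meta
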