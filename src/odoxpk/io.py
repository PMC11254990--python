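"""Dataset and report I/O.

PKDataset round-trips through CSV with NONMEM-convention columns
(ID, OCC, ROUTE, EVID, TIME, AMT, RATE, DV, OBS, BLQ, LLOQ, L2, MDV).
Lines starting with ``#`` are metadata comments (seed, config hash) and are
ignored on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .decision import PTAGrid
from .synthetic_data import COLUMNS, PKDataset

__all__ = ["read_dataset", "write_dataset", "read_pta_grid", "write_pta_grid",
           "config_hash"]

_NUMERIC = ["ID", "OCC", "EVID", "TIME", "AMT", "RATE", "DV", "BLQ", "LLOQ", "L2", "MDV"]


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration mapping, for provenance lines."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_dataset(data: PKDataset, path: str | Path,
                  metadata: Mapping[str, Any] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        data.df.to_csv(fh, index=False, na_rep="NA")


def read_dataset(path: str | Path) -> PKDataset:
    """Read and validate a PKDataset CSV; errors name the offending column/row."""
    path = Path(path)
    # "." is a legitimate OBS placeholder, so NA parsing is restricted to the
    # numeric columns
    df = pd.read_csv(path, comment="#", keep_default_na=False,
                     na_values={c: ["NA", "", "."] for c in _NUMERIC})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if col in ("ID", "OCC", "EVID", "TIME", "MDV") and (coerced.isna().any()):
            rows = list((np.flatnonzero(coerced.isna()) + 2)[:5])
            raise ValueError(f"{path}: non-numeric or missing {col} at file row(s) {rows}")
        if bad.any():
            rows = list((np.flatnonzero(bad) + 2)[:5])
            raise ValueError(f"{path}: non-numeric {col} at file row(s) {rows}")
        df[col] = coerced
    obs = df[df.EVID == 0]
    doses = df[df.EVID == 1]
    for (sid, occ), grp in obs.groupby(["ID", "OCC"]):
        d = doses[(doses.ID == sid) & (doses.OCC == occ)]
        if d.empty or grp.TIME.min() < d.TIME.min():
            raise ValueError(
                f"{path}: subject {sid:g} occasion {occ:g} has observation rows "
                "before (or without) a dose record"
            )
    return PKDataset(df)


def write_pta_grid(grid: PTAGrid, path: str | Path,
                   metadata: Mapping[str, Any] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        grid.df.to_csv(fh, index=False)


def read_pta_grid(path: str | Path) -> PTAGrid:
    df = pd.read_csv(path, comment="#")
    required = {"arm", "dose_mg", "n_doses", "ec_ng_ml", "pta_pct", "n_sim"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing PTA grid column(s) {sorted(missing)}")
    return PTAGrid(df)
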