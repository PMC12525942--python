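"""Readers/writers for the event-table CSV dialect, YAML configs, metadata.

Event tables use a NONMEM-style dialect, one row per dose or observation:

    id,time_h,evid,amt_ug,dv_nmol_L
    1,0.0,0,,64.7        <- observation (evid 0): dv set, amt empty
    1,0.0,1,250,         <- dose (evid 1): amt > 0, dv empty

Times are hours since each child's baseline visit, sorted within id.
Covariates travel in a sibling table: id,sex,age,wt0,wt_final,zbmi.
Numeric fields are written with repr-level precision so a write/read
round-trip is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, SchemaError
from .records import ChildRecord

__all__ = [
    "EVENT_COLUMNS",
    "COVARIATE_COLUMNS",
    "children_to_tables",
    "read_event_table",
    "write_event_table",
    "artifact_metadata",
    "load_yaml",
]

EVENT_COLUMNS = ["id", "time_h", "evid", "amt_ug", "dv_nmol_L"]
COVARIATE_COLUMNS = ["id", "sex", "age", "wt0", "wt_final", "zbmi"]

#: assay lower limit of quantification used to flag observations (nmol/L);
#: 14.2 nmol/L is the enzyme-linked assay limit of the sister trial
DEFAULT_LLOQ = 14.2


def children_to_tables(children: list[ChildRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten ChildRecords into (event table, covariate table)."""
    rows = []
    for ch in children:
        for t, dv in zip(ch.obs_times_h, ch.obs_dv):
            rows.append((ch.id, t, 0, np.nan, dv))
        for t, amt in zip(ch.dose_times_h, ch.dose_amounts_ug):
            rows.append((ch.id, t, 1, amt, np.nan))
    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    ev = ev.sort_values(["id", "time_h", "evid"], kind="stable").reset_index(drop=True)
    cov = pd.DataFrame(
        [
            (ch.id, ch.sex, ch.age, ch.wt0, ch.wt_final, ch.zbmi)
            for ch in children
        ],
        columns=COVARIATE_COLUMNS,
    )
    return ev, cov


def write_event_table(
    children: list[ChildRecord],
    events_path: str | Path,
    covariates_path: str | Path | None = None,
) -> None:
    """Write the dataset as CSV (full-precision decimal text)."""
    ev, cov = children_to_tables(children)
    # pandas' default float repr is shortest-round-trip, so numeric fields
    # survive a write/read cycle bit-exactly
    ev.to_csv(events_path, index=False)
    if covariates_path is not None:
        cov.to_csv(covariates_path, index=False)


def _schema_fail(problems: list[str]):
    raise SchemaError("event table schema violations:\n  " + "\n  ".join(problems))


def read_event_table(
    events_path: str | Path,
    covariates_path: str | Path | None = None,
    lloq: float | None = None,
) -> list[ChildRecord]:
    """Parse and validate an event table (+ optional covariate table).

    Validation failures raise :class:`SchemaError` listing the offending
    CSV row numbers (1-based, excluding the header). Observations below
    ``lloq`` are flagged, not dropped. The baseline 25(OH)D anchor is the
    observation at time 0 (falling back to the earliest observation).
    """
    ev = pd.read_csv(events_path, float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise SchemaError(f"event table missing columns: {sorted(missing)}")
    problems = []
    rowno = ev.index + 1
    bad_evid = ~ev["evid"].isin([0, 1])
    for r in rowno[bad_evid]:
        problems.append(f"row {r}: evid must be 0 or 1")
    neg_t = ev["time_h"] < 0
    for r in rowno[neg_t]:
        problems.append(f"row {r}: negative time")
    doses = ev["evid"] == 1
    obs = ev["evid"] == 0
    bad_dose = doses & (ev["amt_ug"].isna() | (ev["amt_ug"] <= 0) | ev["dv_nmol_L"].notna())
    for r in rowno[bad_dose]:
        problems.append(f"row {r}: dose rows need amt_ug > 0 and empty dv_nmol_L")
    bad_obs = obs & (ev["dv_nmol_L"].isna() | (ev["dv_nmol_L"] < 0) | ev["amt_ug"].notna())
    for r in rowno[bad_obs]:
        problems.append(f"row {r}: observation rows need dv_nmol_L >= 0 and empty amt_ug")
    unsorted = ev.groupby("id")["time_h"].apply(lambda s: bool((s.diff().dropna() < 0).any()))
    for cid in unsorted[unsorted].index:
        problems.append(f"id {cid}: times not sorted")
    if problems:
        _schema_fail(problems)

    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, float_precision="round_trip").set_index("id")

    children = []
    for cid, grp in ev.groupby("id", sort=True):
        o = grp[grp["evid"] == 0]
        d = grp[grp["evid"] == 1]
        obs_t = o["time_h"].to_numpy(dtype=float)
        obs_v = o["dv_nmol_L"].to_numpy(dtype=float)
        flags = (
            obs_v < lloq if lloq is not None else np.zeros(obs_v.size, dtype=bool)
        )
        if obs_t.size == 0:
            raise DataError(f"id {cid}: no observations")
        at0 = obs_t == 0
        baseline = float(obs_v[at0][0]) if at0.any() else float(obs_v[0])
        kw = {}
        if cov is not None:
            if cid not in cov.index:
                raise DataError(f"id {cid}: missing covariate row")
            row = cov.loc[cid]
            kw = dict(
                sex=str(row["sex"]),
                age=float(row["age"]),
                wt0=float(row["wt0"]),
                wt_final=(None if pd.isna(row["wt_final"]) else float(row["wt_final"])),
                zbmi=float(row["zbmi"]),
            )
        children.append(
            ChildRecord(
                id=cid,
                baseline_c25=baseline,
                dose_times_h=d["time_h"].to_numpy(dtype=float),
                dose_amounts_ug=d["amt_ug"].to_numpy(dtype=float),
                obs_times_h=obs_t,
                obs_dv=obs_v,
                lloq_flags=flags,
                **kw,
            )
        )
    return children


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def artifact_metadata(seed: int | None, config) -> dict:
    """Provenance block written into every artifact: seed + config hash."""
    from . import __version__

    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return {
        "package": "vitd-pbpk",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
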