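"""Delimited-text readers and writers.

Raw input is a long-format CSV of per-well values (``well,time_h,value``)
plus a plate map (``well,chemical_id,concentration,role,label``) where
``role`` is ``treated`` or ``negative_control`` and ``label`` is optional.
Processed TCRC sets round-trip through a single long-format CSV with one
row per (chemical, curve, hour).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ShapeError
from .preprocess import (
    CellIndexSeries,
    N_CONCENTRATIONS,
    TCRC,
    TCRCSet,
    make_tcrc,
)
from .wavelets import FeatureVector

ROLE_TREATED = "treated"
ROLE_NC = "negative_control"

_NC_SENTINEL = "negative control"


def read_raw_wells(
    values_path: str | Path, platemap_path: str | Path
) -> dict[str, dict]:
    """Group raw well traces by chemical according to the plate map.

    Returns ``{chemical_id: {"label": ..., "treated": [(conc, series), ...],
    "negative_control": series}}`` with treated entries sorted from the
    highest concentration down. One well per (chemical, concentration) is
    expected; duplicates raise.
    """
    values = pd.read_csv(values_path)
    platemap = pd.read_csv(platemap_path)
    required = {"well", "time_h", "value"}
    if not required.issubset(values.columns):
        raise ConfigError(f"values file must have columns {sorted(required)}")
    required_map = {"well", "chemical_id", "concentration", "role"}
    if not required_map.issubset(platemap.columns):
        raise ConfigError(f"plate map must have columns {sorted(required_map)}")
    if platemap["well"].duplicated().any():
        raise ConfigError("plate map assigns some well twice")

    by_well = {
        well: group.sort_values("time_h")
        for well, group in values.groupby("well", sort=False)
    }
    chemicals: dict[str, dict] = {}
    for row in platemap.itertuples(index=False):
        if row.well not in by_well:
            raise ConfigError(f"well {row.well!r} in plate map but not in values file")
        group = by_well[row.well]
        series = CellIndexSeries(
            times=group["time_h"].to_numpy(float),
            values=group["value"].to_numpy(float),
        )
        label = getattr(row, "label", None)
        if label is not None and (pd.isna(label) or label == ""):
            label = None
        entry = chemicals.setdefault(
            row.chemical_id, {"label": label, "treated": [], "negative_control": None}
        )
        if label is not None:
            entry["label"] = label
        if row.role == ROLE_NC:
            if entry["negative_control"] is not None:
                raise ConfigError(f"duplicate negative control for {row.chemical_id!r}")
            entry["negative_control"] = series
        elif row.role == ROLE_TREATED:
            conc = float(row.concentration)
            if any(abs(c - conc) < 1e-12 for c, _ in entry["treated"]):
                raise ConfigError(
                    f"duplicate concentration {conc} for {row.chemical_id!r}"
                )
            entry["treated"].append((conc, series))
        else:
            raise ConfigError(f"unknown role {row.role!r} for well {row.well!r}")
    for entry in chemicals.values():
        entry["treated"].sort(key=lambda pair: -pair[0])
    return chemicals


def preprocess_raw(
    values_path: str | Path,
    platemap_path: str | Path,
    grid: np.ndarray | None = None,
) -> list[TCRCSet]:
    """Read, normalize and resample raw wells into validated TCRC sets."""
    chemicals = read_raw_wells(values_path, platemap_path)
    sets = []
    for chemical_id, entry in chemicals.items():
        if entry["negative_control"] is None:
            raise ConfigError(f"no negative control for {chemical_id!r}")
        if len(entry["treated"]) != N_CONCENTRATIONS:
            raise ShapeError(
                f"{chemical_id!r} has {len(entry['treated'])} treated wells, "
                f"expected {N_CONCENTRATIONS}"
            )
        curves = [
            make_tcrc(series, conc, chemical_id, grid)
            for conc, series in entry["treated"]
        ]
        nc = make_tcrc(entry["negative_control"], None, chemical_id, grid)
        tcrc_set = TCRCSet(
            chemical_id=chemical_id,
            curves=curves,
            negative_control=nc,
            label=entry["label"],
        )
        tcrc_set.validate()
        sets.append(tcrc_set)
    return sets


def write_tcrc_sets(tcrc_sets: Sequence[TCRCSet], path: str | Path) -> None:
    """One row per (chemical, curve, hour); NC rows carry a sentinel."""
    records = []
    for s in tcrc_sets:
        for curve in [*s.curves, s.negative_control]:
            conc = _NC_SENTINEL if curve.is_negative_control else repr(curve.concentration)
            for t, v in zip(curve.times, curve.nci):
                records.append(
                    {
                        "chemical_id": s.chemical_id,
                        "label": s.label if s.label is not None else "",
                        "concentration": conc,
                        "time_h": t,
                        "nci": repr(float(v)),
                    }
                )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_tcrc_sets(path: str | Path) -> list[TCRCSet]:
    """Inverse of :func:`write_tcrc_sets`, preserving chemical order."""
    frame = pd.read_csv(
        path, dtype={"concentration": str}, keep_default_na=False,
        float_precision="round_trip",
    )
    sets = []
    for chemical_id, group in frame.groupby("chemical_id", sort=False):
        labels = set(group["label"]) - {""}
        label = labels.pop() if labels else None
        curves, nc = [], None
        for conc, curve_rows in group.groupby("concentration", sort=False):
            curve_rows = curve_rows.sort_values("time_h")
            curve = TCRC(
                times=curve_rows["time_h"].to_numpy(float),
                nci=curve_rows["nci"].to_numpy(float),
                concentration=None if conc == _NC_SENTINEL else float(conc),
                chemical_id=str(chemical_id),
            )
            if curve.is_negative_control:
                nc = curve
            else:
                curves.append(curve)
        curves.sort(key=lambda c: -c.concentration)
        if nc is None:
            raise ConfigError(f"no negative-control rows for {chemical_id!r}")
        sets.append(
            TCRCSet(
                chemical_id=str(chemical_id),
                curves=curves,
                negative_control=nc,
                label=label,
            )
        )
    return sets


def write_features(
    features: Sequence[FeatureVector],
    chemical_ids: Sequence[str],
    labels: Sequence[str | None],
    path: str | Path,
) -> None:
    """Feature table: ``chemical_id,label,provenance,v1..vk``."""
    if not len(features) == len(chemical_ids) == len(labels):
        raise ShapeError("features, ids and labels must align")
    widths = {len(f) for f in features}
    if len(widths) > 1:
        raise ShapeError(f"inconsistent feature lengths: {sorted(widths)}")
    rows = []
    for f, cid, label in zip(features, chemical_ids, labels):
        row = {"chemical_id": cid, "label": label or "", "provenance": f.provenance}
        row.update({f"v{i + 1}": v for i, v in enumerate(f.values)})
        rows.append(row)
    pd.DataFrame.from_records(rows).to_csv(path, index=False)


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str], str]:
    """Returns (X, labels, chemical_ids, provenance)."""
    frame = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    value_cols = [c for c in frame.columns if c.startswith("v")]
    value_cols.sort(key=lambda c: int(c[1:]))
    X = frame[value_cols].to_numpy(float)
    labels = frame["label"].to_numpy(str)
    provenance = str(frame["provenance"].iloc[0]) if len(frame) else "raw"
    return X, labels, list(frame["chemical_id"]), provenance
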