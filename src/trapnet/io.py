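"""Delimited-text file formats for every pipeline stage.

All tables are plain CSV with fixed column orders; networks are additionally
exportable as a tab-delimited square matrix, an edge list, and GraphML for
interoperability with standard graph viewers.  Timestamps are strict ISO 8601
and must be timezone-aware; naive timestamps are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .events import AssociationMatrix, Event

__all__ = [
    "DETECTION_COLUMNS",
    "EVENT_COLUMNS",
    "read_detections",
    "write_detections",
    "read_videos",
    "write_events",
    "read_events",
    "write_edgelist",
    "read_edgelist",
    "write_matrix",
    "read_matrix",
    "write_graphml",
    "read_id_map",
    "write_id_map",
    "load_run_config",
]

DETECTION_COLUMNS = [
    "video_id",
    "camera_id",
    "start_timestamp",
    "channel",
    "clip_positions",
    "individual_id",
    "age_sex_class",
    "weaned",
    "token",
]

EVENT_COLUMNS = ["event_id", "camera_id", "t_start", "t_end", "video_ids"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


def _check_timestamps(df: pd.DataFrame, column: str, what: str) -> None:
    parsed = pd.to_datetime(df[column], format="ISO8601", errors="coerce", utc=False)
    bad = df.index[parsed.isna()].tolist()
    if bad:
        raise ValueError(f"{what}: unparseable {column} at rows {bad[:10]}")
    if getattr(parsed.dt, "tz", None) is None:
        raise ValueError(f"{what}: {column} must be timezone-aware ISO 8601")


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    _check_columns(df, DETECTION_COLUMNS[:-1], f"detections {path}")
    if "token" not in df.columns:
        df["token"] = ""
    if not df.empty:
        _check_timestamps(df, "start_timestamp", f"detections {path}")
        bad = df.index[~df["channel"].isin(["expert", "citizen"])].tolist()
        if bad:
            raise ValueError(f"detections {path}: bad channel at rows {bad[:10]}")
    df["weaned"] = df["weaned"].replace("", "0").astype(int)
    return df


def write_detections(df: pd.DataFrame, path: str | Path) -> None:
    df[DETECTION_COLUMNS].to_csv(path, index=False)


def read_videos(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    _check_columns(df, ["video_id", "camera_id", "start_timestamp"], f"videos {path}")
    if not df.empty:
        _check_timestamps(df, "start_timestamp", f"videos {path}")
    return df


def write_events(events: list[Event], path: str | Path) -> None:
    rows = [
        (
            ev.event_id,
            ev.camera_id,
            ev.t_start.isoformat(),
            ev.t_end.isoformat(),
            ";".join(ev.video_ids),
        )
        for ev in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, dtype=str).fillna("")
    _check_columns(df, EVENT_COLUMNS, f"events {path}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Event(
                event_id=row.event_id,
                camera_id=row.camera_id,
                video_ids=row.video_ids.split(";") if row.video_ids else [],
                t_start=pd.Timestamp(row.t_start),
                t_end=pd.Timestamp(row.t_end),
            )
        )
    return out


def write_edgelist(matrix: AssociationMatrix, path: str | Path) -> None:
    df = matrix.to_edgelist()
    df["weight"] = df["weight"].map(lambda w: f"{w:.6f}")
    df.to_csv(path, index=False)


def read_edgelist(path: str | Path) -> AssociationMatrix:
    df = pd.read_csv(path, dtype={"indiv_a": str, "indiv_b": str, "weight": float})
    _check_columns(df, ["indiv_a", "indiv_b", "weight"], f"edge list {path}")
    roster = sorted(set(df["indiv_a"]) | set(df["indiv_b"]))
    idx = {ind: i for i, ind in enumerate(roster)}
    w = np.zeros((len(roster), len(roster)))
    for row in df.itertuples(index=False):
        w[idx[row.indiv_a], idx[row.indiv_b]] = row.weight
        w[idx[row.indiv_b], idx[row.indiv_a]] = row.weight
    return AssociationMatrix(tuple(roster), w)


def write_matrix(matrix: AssociationMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.weights, index=list(matrix.roster), columns=list(matrix.roster)
    ).to_csv(path, sep="\t", float_format="%.6f")


def read_matrix(path: str | Path) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AssociationMatrix(tuple(str(c) for c in df.columns), df.to_numpy(float))


def write_graphml(matrix: AssociationMatrix, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(matrix.roster)
    for a, b, w in matrix.to_edgelist().itertuples(index=False):
        if w > 0:
            g.add_edge(a, b, weight=float(w))
    nx.write_graphml(g, path)


def read_id_map(path: str | Path) -> tuple[dict[str, str], set[str]]:
    """ID-standardization table: citizen -> expert, plus flagged chimeras.

    A citizen ID the expert associated with more than one expert ID is a
    chimera: it keeps its first mapping but is reported in the flag set.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    _check_columns(df, ["citizen_id", "expert_id"], f"id map {path}")
    mapping: dict[str, str] = {}
    chimeras: set[str] = set()
    for row in df.itertuples(index=False):
        if row.citizen_id in mapping and mapping[row.citizen_id] != row.expert_id:
            chimeras.add(row.citizen_id)
            continue
        mapping[row.citizen_id] = row.expert_id
    return mapping, chimeras


def write_id_map(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["citizen_id", "expert_id"]
    ).assign(note="").to_csv(path, index=False)


def load_run_config(path: str | Path) -> dict:
    """YAML key-value run configuration; CLI flags override these values."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a mapping")
    return cfg
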