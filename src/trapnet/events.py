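"""Event grouping and simple-ratio-index association networks.

Videos recorded at the same camera within 15 minutes of one another are
chained into a single *event*, the sampling unit for association.  Under the
gambit of the group, every individual identified anywhere in an event is
taken to be associating with every other — one party.  Dyadic association is
then the simple ratio index (SRI)

    SRI(A, B) = x / (x + yAB + yA + yB)

where, over the events containing at least one roster member in the chosen
channel, x counts events with both A and B, yA (yB) events with only A (B),
and yAB events where both were seen but apart — structurally zero for
single-camera events, kept for generality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "SRIComponents",
    "AssociationMatrix",
    "group_events",
    "gambit_party",
    "event_parties",
    "select_shared_roster",
    "sri_components",
    "simple_ratio_index",
    "build_network",
]

#: grouping window between consecutive video starts (inclusive boundary)
EVENT_WINDOW_MIN = 15.0


@dataclass
class Event:
    """All videos at one camera whose start times chain within the window."""

    event_id: str
    camera_id: str
    video_ids: list[str]
    t_start: pd.Timestamp
    t_end: pd.Timestamp


@dataclass(frozen=True)
class SRIComponents:
    x: int
    yA: int
    yB: int
    yAB: int = 0

    @property
    def weight(self) -> float:
        denom = self.x + self.yA + self.yB + self.yAB
        return self.x / denom if denom else 0.0


@dataclass
class AssociationMatrix:
    """Symmetric simple-ratio-index weights over a fixed roster."""

    roster: tuple[str, ...]
    weights: np.ndarray
    n_events_used: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.roster), len(self.roster)):
            raise ValueError("weights shape does not match roster")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    def index(self, node: str) -> int:
        try:
            return self.roster.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def dyad_vector(self) -> np.ndarray:
        """Strictly-lower-triangle weights as a 1-D vector."""
        i, j = np.tril_indices(len(self.roster), k=-1)
        return self.weights[i, j]

    def to_edgelist(self) -> pd.DataFrame:
        rows = []
        for a in range(len(self.roster)):
            for b in range(a + 1, len(self.roster)):
                rows.append((self.roster[a], self.roster[b], self.weights[a, b]))
        return pd.DataFrame(rows, columns=["indiv_a", "indiv_b", "weight"])


def _require_timestamps(videos: pd.DataFrame) -> pd.Series:
    ts = pd.to_datetime(
        videos["start_timestamp"], utc=False, format="ISO8601", errors="coerce"
    )
    missing = videos.loc[ts.isna(), "video_id"].tolist()
    if missing:
        raise ValueError(f"videos missing a valid start timestamp: {missing}")
    if getattr(ts.dt, "tz", None) is None:
        raise ValueError("start_timestamp must be timezone-aware ISO 8601")
    return ts


def group_events(
    videos: pd.DataFrame, window_minutes: float = EVENT_WINDOW_MIN
) -> list[Event]:
    """Chain each camera's time-sorted videos into events.

    A video joins the current event iff its start is at most ``window_minutes``
    (inclusive) after the previous member's start; chaining is transitive, so
    an event can span longer than one window.  Cameras never share events.
    """
    if videos.empty:
        return []
    vids = videos.copy()
    vids["ts"] = _require_timestamps(vids)
    events: list[Event] = []
    window = pd.Timedelta(minutes=window_minutes)
    for camera, grp in vids.sort_values(["camera_id", "ts", "video_id"]).groupby(
        "camera_id", sort=True
    ):
        current: list[tuple[str, pd.Timestamp]] = []
        for row in grp.itertuples(index=False):
            if current and row.ts - current[-1][1] > window:
                events.append(_make_event(camera, current, len(events)))
                current = []
            current.append((row.video_id, row.ts))
        if current:
            events.append(_make_event(camera, current, len(events)))
    return events


def _make_event(camera: str, members: list[tuple[str, pd.Timestamp]], k: int) -> Event:
    return Event(
        event_id=f"e{k + 1:05d}",
        camera_id=camera,
        video_ids=[vid for vid, _ in members],
        t_start=members[0][1],
        t_end=members[-1][1],
    )


def gambit_party(
    event: Event, detections: pd.DataFrame, channel: str
) -> set[str]:
    """Identified individuals over an event's videos = one party (per channel)."""
    mask = detections["video_id"].isin(event.video_ids) & (
        detections["channel"] == channel
    )
    ids = detections.loc[mask, "individual_id"]
    return {i for i in ids if i}


def event_parties(
    events: Sequence[Event], detections: pd.DataFrame, channel: str
) -> list[set[str]]:
    """Per-event identified parties for one channel, in event order."""
    ch = detections[detections["channel"] == channel]
    ch = ch[ch["individual_id"] != ""]
    by_video: dict[str, set[str]] = {}
    for vid, grp in ch.groupby("video_id"):
        by_video[vid] = set(grp["individual_id"])
    return [
        set().union(*(by_video.get(v, set()) for v in ev.video_ids))
        for ev in events
    ]


def select_shared_roster(
    detections: pd.DataFrame,
    weaned_flags: Mapping[str, bool],
    id_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Weaned individuals identified at least once in *each* channel.

    Citizen IDs are first standardized onto the expert namespace via
    ``id_map`` (identity if omitted); an unmapped citizen ID is an error.
    """
    expert_ids = {
        i for i in detections.loc[detections["channel"] == "expert", "individual_id"]
        if i
    }
    citizen_raw = {
        i for i in detections.loc[detections["channel"] == "citizen", "individual_id"]
        if i
    }
    if id_map is not None:
        orphans = sorted(citizen_raw - set(id_map))
        if orphans:
            raise ValueError(f"citizen IDs missing from the ID map: {orphans}")
        citizen_ids = {id_map[i] for i in citizen_raw}
    else:
        citizen_ids = citizen_raw
    roster = [
        ind
        for ind in sorted(expert_ids & citizen_ids)
        if weaned_flags.get(ind, False)
    ]
    return roster


def sri_components(
    parties: Iterable[set[str]], a: str, b: str, roster: set[str]
) -> SRIComponents:
    """Tally SRI counts for one dyad over qualifying events.

    Only events whose party contains at least one roster member qualify.
    """
    x = ya = yb = 0
    for party in parties:
        if not (party & roster):
            continue
        has_a, has_b = a in party, b in party
        if has_a and has_b:
            x += 1
        elif has_a:
            ya += 1
        elif has_b:
            yb += 1
    return SRIComponents(x=x, yA=ya, yB=yb, yAB=0)


def simple_ratio_index(
    events: Sequence[Event],
    detections: pd.DataFrame,
    pair: tuple[str, str],
    channel: str,
    roster: Sequence[str],
) -> float:
    """SRI weight for one pair of roster members."""
    a, b = pair
    roster_set = set(roster)
    if a not in roster_set or b not in roster_set:
        raise KeyError(f"pair {pair} not contained in roster")
    parties = event_parties(events, detections, channel)
    return sri_components(parties, a, b, roster_set).weight


def build_network(
    events: Sequence[Event],
    detections: pd.DataFrame,
    roster: Sequence[str],
    channel: str,
) -> AssociationMatrix:
    """SRI association matrix over all unordered roster pairs.

    ``n_events_used`` reports how many events contained at least one roster
    member in this channel (the qualifying sample size).
    """
    roster = tuple(roster)
    if not roster:
        raise ValueError("roster must be non-empty")
    if len(events) == 0:
        warnings.warn("no events supplied; returning an empty network")
        return AssociationMatrix(roster, np.zeros((len(roster), len(roster))), 0)
    parties = event_parties(events, detections, channel)
    roster_set = set(roster)
    qualifying = [p & roster_set for p in parties if p & roster_set]
    return network_from_parties(qualifying, roster)


def network_from_parties(
    parties: Sequence[set[str]], roster: Sequence[str]
) -> AssociationMatrix:
    """SRI matrix from pre-computed qualifying parties (vectorized tally)."""
    roster = tuple(roster)
    idx = {ind: i for i, ind in enumerate(roster)}
    n = len(roster)
    member = np.zeros((len(parties), n), dtype=np.int64)
    for e, party in enumerate(parties):
        for ind in party:
            if ind in idx:
                member[e, idx[ind]] = 1
    together = member.T @ member          # x per dyad
    appear = member.sum(axis=0)           # per-individual event counts
    denom = appear[:, None] + appear[None, :] - together
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(denom > 0, together / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(weights, 0.0)
    return AssociationMatrix(roster, weights, n_events_used=len(parties))
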