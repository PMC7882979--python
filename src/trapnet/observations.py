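"""Clip-level data model and the rules that turn raw annotations into data.

Three gatekeeping rules operate before any network is built:

* a clip counts as containing the focal species when at least two independent
  annotators said so (a single classification could be erroneous) or a
  moderator tagged it ``#chimp``; a moderator ``#omit`` tag overrides both;
* a 60-s video enters the detection comparison only when all four of its 15-s
  clips were viewed and every clip is either species-flagged or unanimously
  blank in three independent classifications;
* a proposed individual identity is *confirmed* only when at least three
  annotators agree, the individual was sighted in at least two temporally and
  spatially independent clips, and nobody dissents — otherwise it stays
  *prospective*.

Minute linking merges the four clips of a video back into one sampling unit,
using producer-supplied tokens to keep anonymous individuals distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ClipRecord",
    "VideoRecord",
    "DetectionRecord",
    "Sighting",
    "IDProposal",
    "chimp_clip_flag",
    "video_inclusion_filter",
    "link_minute",
    "confirm_id",
    "clips_from_frame",
]

#: two same-camera sightings closer than this are treated as consecutive
#: clips of one trigger, hence not independent
DEPENDENCE_WINDOW_S = 60.0


@dataclass
class ClipRecord:
    """One 15-s clip with its crowd classifications and moderator hashtags."""

    clip_id: str
    video_id: str
    position: int
    classifications: list[tuple[str, str]] = field(default_factory=list)
    hashtags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.position not in (1, 2, 3, 4):
            raise ValueError(
                f"clip {self.clip_id}: position must be in 1..4, got {self.position}"
            )
        annotators = [a for a, _ in self.classifications]
        if len(annotators) != len(set(annotators)):
            raise ValueError(
                f"clip {self.clip_id}: duplicate annotator in classifications"
            )


@dataclass
class VideoRecord:
    """One 60-s camera-trap video."""

    video_id: str
    camera_id: str
    start_timestamp: pd.Timestamp
    duration_s: int = 60


@dataclass
class DetectionRecord:
    """One animal instance in one video, as seen by one observer channel."""

    video_id: str
    channel: str
    individual_id: str | None = None
    age_sex_class: str = ""
    clip_positions: frozenset[int] = frozenset()
    token: str = ""


@dataclass(frozen=True)
class Sighting:
    clip_id: str
    camera_id: str
    timestamp: pd.Timestamp


@dataclass
class IDProposal:
    """A candidate individual identity awaiting crowd consensus."""

    candidate_id: str
    sightings: list[Sighting]
    agreeing_annotators: frozenset[str]
    dissenting_annotators: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.agreeing_annotators & self.dissenting_annotators:
            raise ValueError(
                f"proposal {self.candidate_id}: annotator cannot both agree and dissent"
            )


def chimp_clip_flag(clip: ClipRecord) -> bool:
    """Does this clip count as containing the focal species?

    True iff at least two distinct annotators classified it as such, or a
    ``#chimp`` hashtag is present.  ``#omit`` forces False regardless.
    """
    tags = {t.lower() for t in clip.hashtags}
    if "#omit" in tags:
        return False
    if "#chimp" in tags:
        return True
    n_chimp = len({a for a, verdict in clip.classifications if verdict == "chimp"})
    return n_chimp >= 2


def video_inclusion_filter(
    video_ids: Iterable[str],
    clips: Mapping[str, Sequence[ClipRecord]],
) -> set[str]:
    """Select videos fit for the cross-channel detection comparison.

    A video is included iff all four clips carry at least one classification,
    at least one clip is species-flagged, and every non-flagged clip is
    unanimously blank in at least three independent classifications.
    """
    included: set[str] = set()
    for vid in video_ids:
        vclips = clips.get(vid, [])
        if len(vclips) != 4 or {c.position for c in vclips} != {1, 2, 3, 4}:
            raise ValueError(
                f"video {vid}: expected exactly 4 clips at positions 1..4, "
                f"got {len(vclips)}"
            )
        if any(len(c.classifications) == 0 for c in vclips):
            continue
        flags = [chimp_clip_flag(c) for c in vclips]
        if not any(flags):
            continue
        ok = True
        for clip, flagged in zip(vclips, flags):
            if flagged:
                continue
            verdicts = [v for _, v in clip.classifications]
            if len(verdicts) < 3 or any(v != "blank" for v in verdicts):
                ok = False
                break
        if ok:
            included.add(vid)
    return included


def link_minute(
    detections: Iterable[DetectionRecord] | None = None,
    clip_counts: Sequence[int] | None = None,
) -> tuple[set[str], int]:
    """Merge one video's four clips into a single minute-level record.

    With token-linked detections the individual set is the union of distinct
    tokens (identified individuals reported under their ID, anonymous ones
    under their producer token) and the count is the size of that union.
    With only per-clip counts available the count falls back to the maximum
    over clips — a stated lower-bound convention — and the set is empty.
    """
    if detections is not None:
        identified: set[str] = set()
        tokens: set[str] = set()
        for det in detections:
            tokens.add(det.token or det.individual_id or str(id(det)))
            if det.individual_id:
                identified.add(det.individual_id)
        return identified, len(tokens)
    if clip_counts is not None:
        return set(), max(clip_counts, default=0)
    return set(), 0


def _independent(a: Sighting, b: Sighting) -> bool:
    if a.camera_id != b.camera_id:
        return True
    gap = abs((a.timestamp - b.timestamp).total_seconds())
    return gap > DEPENDENCE_WINDOW_S


def confirm_id(proposal: IDProposal) -> str:
    """Apply the consensus rule: returns ``"confirmed"`` or ``"prospective"``.

    Confirmation requires at least three agreeing annotators, no dissent, and
    two independent sightings.  Two sightings are independent when they come
    from different cameras or, at the same camera, from clips farther apart
    than one video length (consecutive clips of one trigger are dependent).
    """
    if proposal.dissenting_annotators:
        return "prospective"
    if len(proposal.agreeing_annotators) < 3:
        return "prospective"
    s = proposal.sightings
    has_independent_pair = any(
        _independent(s[i], s[j])
        for i in range(len(s))
        for j in range(i + 1, len(s))
    )
    return "confirmed" if has_independent_pair else "prospective"


def clips_from_frame(classifications: pd.DataFrame) -> dict[str, list[ClipRecord]]:
    """Group a long-format classification table into per-video ClipRecords.

    Expects columns clip_id, video_id, position, annotator_id, verdict,
    hashtags (hashtags may repeat per row; they are deduplicated).
    """
    out: dict[str, list[ClipRecord]] = {}
    for (vid, clip_id, pos), grp in sorted(
        classifications.groupby(["video_id", "clip_id", "position"], sort=False)
    ):
        tags: list[str] = []
        for raw in grp["hashtags"]:
            for tag in str(raw).split(";"):
                tag = tag.strip()
                if tag and tag not in tags:
                    tags.append(tag)
        clip = ClipRecord(
            clip_id=clip_id,
            video_id=vid,
            position=int(pos),
            classifications=list(
                zip(grp["annotator_id"].tolist(), grp["verdict"].tolist())
            ),
            hashtags=tags,
        )
        out.setdefault(vid, []).append(clip)
    for vid in out:
        out[vid].sort(key=lambda c: c.position)
    return out
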