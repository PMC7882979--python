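"""Between-channel detection and identification agreement statistics.

Summarizes how a consensus-based observer channel compares with an expert
channel on the same videos: per-video count agreement (with the under/over
split and mean absolute disagreement), per-channel ID assignment rates, ID
agreement among co-identified detections, roster undercoverage, resolution of
prospective IDs, and Cohen's kappa for inter-observer ID agreement.

The detection unit is one individual in one 1-min video (after minute
linking, not per clip).  All headline percentages are rounded half-up to
integers, the convention used when reporting them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .netstats import round_half_up

__all__ = [
    "AgreementSummary",
    "detection_agreement",
    "id_assignment_rate",
    "id_agreement",
    "underestimate_pct",
    "cohens_kappa",
    "prospective_id_resolution",
    "mismatch_pattern",
    "rate_pct",
]


def rate_pct(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("rate undefined for zero denominator")
    return round_half_up(100.0 * numerator / denominator)


@dataclass
class AgreementSummary:
    """Per-video count agreement between two channels (B relative to A)."""

    n_videos: int
    n_count_agree: int
    pct_count_agree: int
    n_under: int
    n_over: int
    pct_under: int          # share of disagreements that are undercounts
    mean_abs_disagreement: float

    def __post_init__(self) -> None:
        if self.n_count_agree + self.n_under + self.n_over != self.n_videos:
            raise ValueError("agree + under + over must equal n_videos")

    def to_dict(self) -> dict:
        return asdict(self)


def detection_agreement(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> AgreementSummary:
    """Compare per-video individual counts of channel B against channel A.

    Both mappings must cover the same videos.  ``n_under`` counts videos
    where B reported fewer individuals than A; swapping the channels swaps
    under and over.
    """
    if set(counts_a) != set(counts_b):
        diff = set(counts_a) ^ set(counts_b)
        raise ValueError(f"video sets differ between channels: {sorted(diff)}")
    n_agree = n_under = n_over = 0
    gaps = []
    for vid in counts_a:
        d = counts_b[vid] - counts_a[vid]
        if d == 0:
            n_agree += 1
        elif d < 0:
            n_under += 1
            gaps.append(-d)
        else:
            n_over += 1
            gaps.append(d)
    n_videos = len(counts_a)
    n_disagree = n_under + n_over
    return AgreementSummary(
        n_videos=n_videos,
        n_count_agree=n_agree,
        pct_count_agree=rate_pct(n_agree, n_videos) if n_videos else 0,
        n_under=n_under,
        n_over=n_over,
        pct_under=rate_pct(n_under, n_disagree) if n_disagree else 0,
        mean_abs_disagreement=float(np.mean(gaps)) if gaps else 0.0,
    )


def id_assignment_rate(n_with_id: int, n_total: int) -> tuple[int, int, int]:
    """(n_with_id, n_total, integer %) share of detections carrying an ID."""
    if n_total == 0:
        raise ValueError("ID assignment rate undefined with zero detections")
    if not 0 <= n_with_id <= n_total:
        raise ValueError("n_with_id must lie in [0, n_total]")
    return n_with_id, n_total, rate_pct(n_with_id, n_total)


def id_agreement(
    pairs: Sequence[tuple[str, str]] | None = None,
    n_agree: int | None = None,
    n_total: int | None = None,
) -> tuple[int, int, int]:
    """(n_agree, n_total, integer %) over co-identified detections.

    Pass either the (standardized-ID, expert-ID) pairs themselves or the
    pre-tallied counts.
    """
    if pairs is not None:
        n_total = len(pairs)
        n_agree = sum(1 for a, b in pairs if a == b)
    if n_total is None or n_agree is None:
        raise ValueError("provide pairs or both counts")
    if n_total == 0:
        return 0, 0, 0
    return n_agree, n_total, rate_pct(n_agree, n_total)


def mismatch_pattern(
    records: Sequence[tuple[str, str, str, str]],
) -> dict:
    """Classify ID disagreements by whether the age–sex class still matches.

    ``records`` are (expert_id, citizen_id, expert_class, citizen_class) for
    co-identified detections.  A disagreement on identity that preserves the
    age–sex class is a near-miss; one that crosses classes is not.
    """
    n_mismatch = n_same_class = 0
    for expert_id, citizen_id, expert_cls, citizen_cls in records:
        if expert_id == citizen_id:
            continue
        n_mismatch += 1
        if expert_cls == citizen_cls:
            n_same_class += 1
    return {
        "n_mismatch": n_mismatch,
        "n_same_class": n_same_class,
        "n_diff_class": n_mismatch - n_same_class,
    }


def underestimate_pct(n_identified_unique: int, n_known: int) -> int:
    """Integer % by which unique identified individuals undercount the roster."""
    if n_known == 0:
        raise ValueError("underestimate undefined: no known individuals")
    if not 0 <= n_identified_unique <= n_known:
        raise ValueError("need 0 <= n_identified_unique <= n_known")
    return round_half_up(100.0 * (1.0 - n_identified_unique / n_known))


def cohens_kappa(table) -> float:
    """Cohen's kappa from a square contingency table of category counts.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement (trace
    share) and p_e the chance agreement from the marginal products.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] < 2:
        raise ValueError("table must be square with at least 2 categories")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    total = t.sum()
    if total == 0:
        raise ValueError("empty table")
    p_o = np.trace(t) / total
    row = t.sum(axis=1) / total
    col = t.sum(axis=0) / total
    p_e = float(row @ col)
    if p_e == 1.0:
        raise ValueError("kappa undefined: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def prospective_id_resolution(
    resolved_to_confirmed: int,
    unresolvable_or_nonmember: int,
    unique_unconfirmed: int,
    n_prospective: int | None = None,
) -> dict:
    """Partition prospective IDs by their eventual expert resolution.

    Returns the three category counts plus the integer percent resolved to a
    confirmed individual.  The categories must partition the prospective set.
    """
    counts = (resolved_to_confirmed, unresolvable_or_nonmember, unique_unconfirmed)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if n_prospective is not None and total != n_prospective:
        raise ValueError(
            f"categories sum to {total}, expected {n_prospective}: not a partition"
        )
    return {
        "resolved_to_confirmed": resolved_to_confirmed,
        "unresolvable_or_nonmember": unresolvable_or_nonmember,
        "unique_unconfirmed": unique_unconfirmed,
        "n_prospective": total,
        "pct_resolved": rate_pct(resolved_to_confirmed, total) if total else 0,
    }
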