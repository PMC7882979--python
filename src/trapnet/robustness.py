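"""Sample-size robustness of an association network.

Asks whether the events actually collected suffice for a stable network: for
each sample size n on a grid (default 15, 20, ..., 170), draw n events at
random, rebuild the simple-ratio-index network, and rank-correlate its dyad
weights with the complete network's.  The mean and percentile 95% CI over
replicate draws trace how quickly the estimated network converges on the
complete one; a curve flat near its endpoint means additional sampling would
change little.

Draws are without replacement by default, so the full-sample endpoint is
exactly 1 — a clean anchor; a with-replacement mode is available.  The
correlation unit is the dyad (all unordered roster pairs, zero weights
included, ties mid-ranked), not the node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import AssociationMatrix, Event, event_parties, network_from_parties

__all__ = ["RobustnessCurve", "robustness_curve", "default_grid"]


def default_grid(start: int = 15, step: int = 5, stop: int = 170) -> list[int]:
    """The default 32-point sample-size grid 15, 20, ..., 170."""
    return list(range(start, stop + 1, step))


@dataclass
class RobustnessCurve:
    sample_sizes: list[int]
    mean_correlation: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_replicates: int
    seed: int | None = None

    def __post_init__(self) -> None:
        sizes = self.sample_sizes
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sample sizes must be strictly increasing")
        if np.any(self.ci_low > self.mean_correlation + 1e-12) or np.any(
            self.mean_correlation > self.ci_high + 1e-12
        ):
            raise ValueError("CI bounds must bracket the mean")

    def plateau_n(self, tolerance: float = 0.02) -> int:
        """Smallest grid size whose mean is within ``tolerance`` of the final mean."""
        final = self.mean_correlation[-1]
        for n, m in zip(self.sample_sizes, self.mean_correlation):
            if abs(m - final) <= tolerance:
                return n
        return self.sample_sizes[-1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n": self.sample_sizes,
                "mean": self.mean_correlation,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _dyad_spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(a, b):
        return 1.0
    if np.all(a == a[0]) or np.all(b == b[0]):
        return np.nan
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


def robustness_curve(
    events: list[Event],
    detections,
    roster: list[str],
    channel: str,
    grid: list[int] | None = None,
    n_replicates: int = 1000,
    seed: int | None = None,
    with_replacement: bool = False,
) -> RobustnessCurve:
    """Estimated-network robustness over a grid of event sample sizes.

    Only qualifying events (those containing at least one roster member in
    the chosen channel) are subsampled; the complete network is built from
    all of them.  Replicates whose subsampled network has constant dyad
    weights (possible at very small n) contribute NaN and are excluded from
    the mean and CI.
    """
    if len(roster) < 3:
        raise ValueError("need a roster of at least 3 individuals")
    if grid is None:
        grid = default_grid()
    grid = sorted(grid)
    roster_set = set(roster)
    parties = [
        p & roster_set
        for p in event_parties(events, detections, channel)
        if p & roster_set
    ]
    n_events = len(parties)
    if grid[-1] > n_events:
        raise ValueError(
            f"grid extends to {grid[-1]} but only {n_events} qualifying events exist"
        )
    complete = network_from_parties(parties, roster).dyad_vector()

    # one membership matrix up front; each replicate is then pure linear algebra
    idx_of = {ind: i for i, ind in enumerate(roster)}
    member = np.zeros((n_events, len(roster)), dtype=np.int64)
    for e, party in enumerate(parties):
        for ind in party:
            member[e, idx_of[ind]] = 1
    tri = np.tril_indices(len(roster), k=-1)

    def _dyads_for(rows: np.ndarray) -> np.ndarray:
        sub = member[rows]
        together = sub.T @ sub
        appear = sub.sum(axis=0)
        denom = appear[:, None] + appear[None, :] - together
        w = np.where(denom > 0, together / np.maximum(denom, 1), 0.0)
        return w[tri]

    rng = np.random.default_rng(seed)
    means, lows, highs = [], [], []
    for size in grid:
        corrs = np.empty(n_replicates)
        for r in range(n_replicates):
            idx = rng.choice(n_events, size=size, replace=with_replacement)
            corrs[r] = _dyad_spearman(_dyads_for(idx), complete)
        valid = corrs[~np.isnan(corrs)]
        if len(valid) == 0:
            means.append(np.nan)
            lows.append(np.nan)
            highs.append(np.nan)
            continue
        means.append(float(valid.mean()))
        lows.append(float(np.percentile(valid, 2.5)))
        highs.append(float(np.percentile(valid, 97.5)))
    return RobustnessCurve(
        sample_sizes=grid,
        mean_correlation=np.array(means),
        ci_low=np.array(lows),
        ci_high=np.array(highs),
        n_replicates=n_replicates,
        seed=seed,
    )
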