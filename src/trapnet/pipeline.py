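"""End-to-end pipeline: simulate, filter, compare channels, build networks.

`run_report` chains every stage on one synthetic dataset and returns a single
JSON-serializable summary: detection-count agreement, ID assignment and
agreement rates, the shared-roster networks for both channels, community
structure and cross-network membership agreement, MRQAP, node-metric rank
correlations, and (optionally) the robustness curve.  Every stochastic stage
is seeded from the simulation seed, so a fixed configuration yields a
byte-identical report.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import agreement as agr
from . import events as ev
from . import netstats as ns
from . import observations as obs
from .mrqap import mrqap_dsp
from .robustness import robustness_curve
from .synthetic import SimulationConfig, SyntheticDataset, simulate_community

__all__ = ["run_report", "report_json"]


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _per_video_counts(detections: pd.DataFrame, channel: str) -> dict[str, int]:
    ch = detections[detections["channel"] == channel]
    counts: dict[str, int] = {}
    for vid, grp in ch.groupby("video_id"):
        tokens = {
            t if t else i
            for t, i in zip(grp["token"], grp["individual_id"])
        }
        counts[vid] = len(tokens)
    return counts


def run_report(
    config: SimulationConfig | None = None,
    dataset: SyntheticDataset | None = None,
    n_permutations: int = 200,
    robustness_replicates: int = 100,
    robustness_grid: list[int] | None = None,
) -> dict:
    """Run the full pipeline and return the summary dictionary."""
    if dataset is None:
        if config is None:
            config = SimulationConfig()
        dataset = simulate_community(config)
    config = dataset.config
    seed_mrqap, seed_robust = _derived_seeds(config.seed, 2)

    det = dataset.detections
    truth = dataset.ground_truth

    # --- inclusion filter on the clip classifications -----------------------
    clips = obs.clips_from_frame(dataset.classifications)
    included = obs.video_inclusion_filter(dataset.videos["video_id"], clips)

    # --- per-video detection counts and agreement ---------------------------
    expert_counts = _per_video_counts(det, "expert")
    citizen_counts = _per_video_counts(det, "citizen")
    common = included & set(expert_counts) & set(citizen_counts)
    summary = agr.detection_agreement(
        {v: expert_counts[v] for v in common},
        {v: citizen_counts[v] for v in common},
    )

    # --- ID assignment rates and agreement over linked detections -----------
    rates = {}
    for channel in ("expert", "citizen"):
        ch = det[(det["channel"] == channel) & det["video_id"].isin(common)]
        n_id = int((ch["individual_id"] != "").sum())
        rates[channel] = agr.id_assignment_rate(n_id, len(ch))

    both = pd.merge(
        det[(det["channel"] == "expert") & (det["individual_id"] != "")],
        det[(det["channel"] == "citizen") & (det["individual_id"] != "")],
        on="token",
        suffixes=("_expert", "_citizen"),
    )
    id_pairs = list(zip(both["individual_id_citizen"], both["individual_id_expert"]))
    n_agree, n_both, pct_agree = agr.id_agreement(pairs=id_pairs)

    unique_ids = {
        channel: det.loc[
            (det["channel"] == channel) & (det["individual_id"] != ""),
            "individual_id",
        ].nunique()
        for channel in ("expert", "citizen")
    }
    under = {
        channel: agr.underestimate_pct(unique_ids[channel], config.n_individuals)
        for channel in ("expert", "citizen")
    }

    # --- events, shared roster, association networks ------------------------
    events = ev.group_events(dataset.videos)
    roster = ev.select_shared_roster(det, truth.weaned_flags)
    nets = {
        channel: ev.build_network(events, det, roster, channel)
        for channel in ("expert", "citizen")
    }

    # --- communities and cross-network comparison ---------------------------
    parts = {c: ns.leading_eigenvector_communities(m) for c, m in nets.items()}
    pct_same, n_moved = ns.membership_agreement(
        parts["expert"].labels, parts["citizen"].labels, roster
    )
    truth_labels = {n: truth.community_assignment[n] for n in roster}
    pct_truth, _ = ns.membership_agreement(parts["expert"].labels, truth_labels, roster)

    metric_corr = {}
    for name, fn in (("strength", ns.strengths), ("eigenvector", ns.eigenvector_centrality)):
        metric_corr[name] = ns.spearman_rank_correlation(
            fn(nets["expert"]), fn(nets["citizen"])
        )

    qap = mrqap_dsp(
        nets["expert"], [nets["citizen"]],
        n_permutations=n_permutations, seed=seed_mrqap,
    )

    report = {
        "config": {
            "seed": config.seed,
            "n_individuals": config.n_individuals,
            "n_communities": config.n_communities,
            "n_events": config.n_events,
            "expert_id_prob": config.expert_id_prob,
            "citizen_id_prob": config.citizen_id_prob,
        },
        "detection": {
            "n_videos_included": len(common),
            **summary.to_dict(),
        },
        "identification": {
            "expert": {
                "n_with_id": rates["expert"][0],
                "n_detections": rates["expert"][1],
                "pct_with_id": rates["expert"][2],
                "n_unique_ids": unique_ids["expert"],
                "roster_underestimate_pct": under["expert"],
            },
            "citizen": {
                "n_with_id": rates["citizen"][0],
                "n_detections": rates["citizen"][1],
                "pct_with_id": rates["citizen"][2],
                "n_unique_ids": unique_ids["citizen"],
                "roster_underestimate_pct": under["citizen"],
            },
            "id_agreement": {
                "n_agree": n_agree,
                "n_both_identified": n_both,
                "pct_agree": pct_agree,
            },
        },
        "network": {
            "roster_size": len(roster),
            "n_events_total": len(events),
            "n_events_used": {c: nets[c].n_events_used for c in nets},
            "communities": {
                "expert": parts["expert"].n_communities,
                "citizen": parts["citizen"].n_communities,
                "modularity_expert": parts["expert"].modularity,
                "modularity_citizen": parts["citizen"].modularity,
                "pct_same_community": pct_same,
                "n_in_different_community": n_moved,
                "pct_expert_matches_truth": pct_truth,
            },
            "metric_spearman": metric_corr,
            "mrqap_expert_on_citizen": qap.to_dict(),
        },
    }

    grid = robustness_grid
    if grid is None:
        m = nets["citizen"].n_events_used
        grid = [n for n in range(15, m + 1, 5)]
    if robustness_replicates > 0 and grid:
        curve = robustness_curve(
            events, det, roster, "citizen",
            grid=grid, n_replicates=robustness_replicates, seed=seed_robust,
        )
        report["robustness"] = {
            "channel": "citizen",
            "grid": curve.sample_sizes,
            "mean_correlation": [float(x) for x in curve.mean_correlation],
            "ci_low": [float(x) for x in curve.ci_low],
            "ci_high": [float(x) for x in curve.ci_high],
            "n_replicates": curve.n_replicates,
            "plateau_n": curve.plateau_n(),
        }
    return report


def report_json(report: dict) -> str:
    """Canonical serialization used for on-disk reports (determinism anchor)."""
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
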