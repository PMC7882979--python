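# trapnet

Association networks from camera-trap detections recorded by **two observer
channels** — typically an expert channel (observers with years of experience
identifying the animals) and a consensus-based citizen-science channel — over
the same deployment. The package answers two questions that recur whenever
individual identifications come from a crowd rather than specialists:

1. **How good are the crowd's data?** Per-video detection-count agreement
   (with the undercount/overcount split), ID assignment rates, ID agreement
   among co-identified detections, roster undercoverage, and Cohen's kappa.
2. **Are they good enough to study social structure?** Weighted social
   networks built from each channel under the gambit of the group, compared
   by community structure, matrix regression, node-metric rank correlations,
   and sample-size robustness.

It is aimed at behavioral ecologists working with individually identifiable
species in camera-trap video — fission–fusion societies (chimpanzees,
elephants, dolphins) especially — and ships a planted-structure community
simulator so the entire pipeline runs and is tested without any field data.

## The model

Videos recorded at one camera within 15 min of each other chain into an
*event*. All individuals identified in an event are taken to be one party
(gambit of the group). Dyadic association is the **simple ratio index**

```
SRI(A,B) = x / (x + yAB + yA + yB)
```

with `x` the number of events containing both A and B, `yA`/`yB` events with
only one of them, and `yAB` events where both were seen but apart
(structurally zero at a single camera). Over the roster of weaned individuals
identified in *both* channels this yields one weighted adjacency matrix per
channel. On those matrices the package computes:

- **strength** (weighted degree) and **eigenvector centrality**
  (max-normalized principal eigenvector);
- **communities** by Newman's leading-eigenvector method: recursive sign
  splits of the generalized modularity matrix
  `B_ij = A_ij − s_i s_j / 2W`, stopping when the leading eigenvalue is
  non-positive or the modularity gain is not;
- **MRQAP with double semi-partialling**: OLS over dyads with p-values from
  node permutations of each predictor's residual matrix (pivotal statistic:
  t), which respects the row/column dependence of network data;
- **robustness curves**: rank correlation between networks rebuilt from n
  subsampled events and the complete network, over a grid of n, with
  bootstrap 95% CIs.

## Worked example

Simulate a 300-event deployment of a 36-individual community with 3 planted
subgroups (expert channel identifies 85% of detections, citizen channel 46%)
and run the full pipeline:

```
trapnet report --seed 1 --n-events 300 --n-permutations 200 \
    --robustness-replicates 100 --out report.json
```

Selected fields of `report.json`:

```json
"detection":      {"pct_count_agree": 85, "pct_under": 74,
                   "mean_abs_disagreement": 1.0, "n_videos": 565}
"identification": {"expert pct_with_id": 85, "citizen pct_with_id": 45,
                   "id_agreement pct_agree": 100}
"network":        {"roster_size": 24,
                   "n_events_used": {"expert": 300, "citizen": 295},
                   "communities": {"expert": 4, "citizen": 3,
                                   "pct_same_community": 96,
                                   "pct_expert_matches_truth": 96},
                   "metric_spearman": {"strength": 0.41, "eigenvector": 0.50},
                   "mrqap adjusted_r2": 0.930, "mrqap p": 0.005}
"robustness":     {"plateau_n": 260}
```

Reading: the two channels agree on the per-video headcount in 85% of the 565
videos, and disagreements are mostly citizen undercounts (74%) of about one
individual. Both channels' networks recover the planted subgroup structure
(96% of the 24-individual roster co-assigned; 96% agreement with the ground
truth), the citizen network strongly predicts the expert network (MRQAP
adjusted R² = 0.93, p ≈ 0.005 at 200 permutations), and node metrics
correlate positively across channels. The robustness curve flattens within
0.02 of its final value by 260 events.

Each stage is also exposed as its own subcommand (`simulate`, `filter`,
`events`, `network`, `metrics`, `mrqap`, `robustness`, `agreement`) reading
and writing plain CSV/JSON/GraphML, and as an importable library
(`trapnet.simulate_community`, `trapnet.build_network`, `trapnet.mrqap_dsp`,
...).

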