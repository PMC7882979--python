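# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data do and do not emulate, and
the numerical choices made where more than one defensible option existed.

## Sampling model: events, gambit of the group, simple ratio index

The sampling unit is the *event*: motion-triggered 60-s videos from one
camera whose start times chain within a 15-minute window. Chaining is
transitive with an inclusive boundary — a video joins the current event iff
its start is ≤ 15:00 after the previous member's start, so an event may span
more than 15 minutes end to end. Start times, not clip positions, anchor the
rule. Cameras never share events.

Under the gambit of the group, every individual identified anywhere in an
event is assumed to associate with every other: parties are per-event unions
of identified individuals, taken separately per observer channel. The
analysis roster comprises weaned individuals (independent enough to choose
their associates) identified at least once in *each* channel, after
standardizing citizen IDs onto the expert namespace through an explicit ID
map; a citizen ID matched to two expert IDs is flagged as a chimera rather
than silently resolved.

Association is the simple ratio index, `x / (x + yAB + yA + yB)`, computed
over qualifying events (those containing at least one roster member in the
channel). `yAB` — both seen in the event but apart — is structurally zero
when an event is a single camera's recordings, but the term is kept so the
formula remains correct if events ever span multiple detectors. An event in
which A was identified while B was present but unidentified counts toward
`yA`: unidentified individuals simply do not exist for network purposes,
which is exactly the information loss the cross-channel comparison is meant
to quantify.

## Consensus and filtering rules

Three gatekeeping rules act upstream of the networks:

- **Species flag per clip**: ≥ 2 distinct annotators classifying the clip as
  containing the focal species, or a moderator `#chimp` hashtag; `#omit`
  overrides both (modeled as a boolean override, not a workflow).
- **Video inclusion**: all four 15-s clips viewed, ≥ 1 clip species-flagged,
  and every non-flagged clip unanimously blank in ≥ 3 classifications. Each
  species-flagged clip must itself satisfy the ≥ 2-classification rule.
- **ID confirmation**: ≥ 3 agreeing annotators, zero dissent, and two
  independent sightings. Independence is operationalized purely by time and
  place: sightings at different cameras are independent; at the same camera
  they are independent iff more than 60 s apart (clips of a single 60-s
  video are always within 60 s of each other, hence dependent — the
  "consecutive clips" case). This replaces an adjacency-in-sequence
  definition with an equivalent and simpler gap rule.

Minute linking merges a video's four clips back into one record. Individuals
are tracked by producer-supplied *tokens* — the package's explicit stand-in
for the human step of linking the same animal across clips by appearance and
travel order. The individual set is the union of tokens; where only per-clip
counts exist, the count falls back to the maximum over clips, a deliberate
lower bound.

## Network statistics

Strength is the row sum of the weight matrix. Eigenvector centrality is the
principal eigenvector (dense symmetric eigendecomposition), sign-fixed to be
non-negative and scaled so the maximum is 1; scaling is irrelevant to the
rank correlations used downstream. On disconnected graphs the vector is
computed on the full matrix and concentrates on the dominant component; the
all-zero matrix returns all zeros with a warning.

Community detection is Newman's leading-eigenvector method: recursively
split each group by the sign of the leading eigenvector of its generalized
modularity matrix (zero entries join the positive block, deterministically),
accepting a split only when the leading eigenvalue exceeds 1e-10 and the
modularity gain is positive. No Kernighan–Lin refinement is applied: the
plain recursion is deterministic, testable against a brute-force modularity
oracle on small graphs, and matches the igraph reference implementation
exactly (verified in the test suite). The known cost is occasional
over-splitting: on ~10% of simulated 500-event deployments the first cut
divides one planted block, yielding four communities whose modularity a
3-way partition would beat. This is a property of the unrefined method, not
of the data pipeline.

Partition similarity is the share of individuals co-assigned after aligning
community labels by maximum-overlap optimal assignment
(`linear_sum_assignment`), making the score invariant to label permutation
and to differing community counts. Spearman rank correlations use mid-ranks
for ties.

## MRQAP with double semi-partialling

Dyads are the strictly lower triangle (symmetric matrices make the halves
equivalent; diagonals are excluded everywhere). The observed fit is OLS with
intercept; adjusted R² uses n = number of dyads and p = number of predictor
matrices. For inference on predictor i, its matrix is residualized on the
remaining predictors (matrix-level OLS over dyads, residuals reshaped to a
symmetric matrix), rows and columns are jointly permuted by a random node
relabeling, and the full model is refit with the permuted residual in place
of X_i. The pivotal statistic is the t-statistic, the choice that stays
calibrated under collinearity. Sampled permutations use the add-one
convention p = (1 + #exceed)/(1 + N) so p is never 0; an exhaustive mode
enumerates all n! permutations and reports the exact tail share. Ties in
|t| are counted as exceedances with a 1e-9 relative tolerance, needed
because the identity permutation reproduces the observed statistic only up
to floating-point noise. Zero residual variance (perfect fit) caps the
statistic at 1e12 rather than producing NaN. Regression direction is an
explicit argument — nothing in the API presumes which channel predicts
which.

## Robustness curves

For each n on a grid (default 15, 20, …, 170 — 32 points), events are drawn
uniformly **without replacement**, the SRI network is rebuilt, and its dyad
vector (all unordered roster pairs, zeros included) is Spearman-correlated
with the complete network's. The replicate draws (default 1000) double as
the bootstrap: the mean and 2.5th/97.5th percentiles per n form the curve.
Without-replacement sampling makes the full-sample endpoint exactly 1, a
clean anchor used in testing; a with-replacement mode exists behind a flag.
Dyads, not node metrics, are the correlation units. Replicates whose
subsampled network is constant (possible only at tiny n) are excluded as
undefined. The plateau utility reports the smallest n whose mean is within
0.02 of the final mean.

## Agreement statistics

The detection unit is one individual in one 1-min video (after minute
linking). Count agreement compares per-video totals; disagreements split
into undercounts and overcounts of channel B relative to A (swapping
channels swaps the two), with the mean absolute disagreement over
disagreeing videos. Cohen's kappa is computed from a square contingency
table as (p_o − p_e)/(1 − p_e). All headline percentages are rounded
half-up to integers, the convention in which such results are reported; the
stored numerators and denominators always recompute to the stored
percentage.

## The synthetic community

The generator emulates a fission–fusion society observed by camera traps:

- **Party formation** is seed-plus-independent-inclusion: each event draws
  one uniform seed individual; every other individual joins independently
  with probability `p_within` (same latent community, default 0.7) or
  `p_between` (default 0.05). This is the simplest mechanism producing
  variable party sizes and assortative co-detection; real fission–fusion
  dynamics (spatial structure, temporal autocorrelation of party
  membership, kin effects) are out of scope.
- **Events and videos**: events are spaced an hour apart at uniformly chosen
  cameras (default 20), so regrouping recovers them exactly; the video count
  per event is 1 + Poisson(mean − 1) (default mean 1.8, guaranteeing ≥ 1);
  videos within an event start 61 s apart. Each present individual appears
  in a random non-empty subset of the four clips.
- **Observer channels**: the expert channel detects every present individual
  and assigns the true ID with probability `expert_id_prob` (default 0.85);
  the citizen channel assigns a confirmed ID with probability
  `citizen_id_prob` (default 0.46) and miscounts a video with probability
  0.09 (remove one individual's detections) or 0.04 (duplicate one as an
  anonymous extra) — defaults that put count agreement near 87% with
  undercounts taking ~69% of disagreements. Unidentified detections are
  retained as anonymous tokens: they affect counts but never networks.
- **Roster**: `weaned_fraction` (default 2/3) of individuals are flagged
  weaned, assigned by a seeded permutation so weaning status is independent
  of community.

What passing tests on these data show: the pipeline's bookkeeping, the
estimators, and the inferential procedures are correct under a known ground
truth with realistic identification and counting error. What they do not
show: robustness to annotator skill heterogeneity, ID errors that assign the
*wrong* identity (the citizen channel here omits IDs but never confuses
them, so synthetic ID agreement is 100% by construction), non-stationary
detection rates, or spatially structured camera use.

## Problem sizes and defaults

Defaults are one 36-individual community in 3 latent subgroups observed over
300 events; recovery checks use 500 events, where the expert channel's
network recovers the planted structure with ≥ 90% membership agreement.
MRQAP inference defaults to 1000 permutations (200 in the bundled
calibration runs, where the add-one p-value at α = 0.05 keeps its nominal
level); robustness curves default to 1000 replicates (100–200 in bundled
runs). The acceptance script reports planted-structure recovery as the modal
community count and mean agreement over five replicate deployments, so a
single over-split recursion (see above) does not masquerade as a pipeline
property.

## Known limitations

- The leading-eigenvector recursion can over-split (no refinement pass);
  modularity-equivalent alternatives (Louvain, Infomap) are deliberately out
  of scope.
- The simple ratio index treats presence-but-unidentified as absence; with
  very low ID rates this biases association weights downward for both
  channels rather than differentially.
- `yAB` is identically zero for single-camera events, so the SRI here is
  effectively x/(x + yA + yB).
- Timestamps must be timezone-aware ISO 8601; the package refuses naive
  times rather than guessing a zone.
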