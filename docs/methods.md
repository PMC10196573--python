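# Methods

This note documents the models, conventions, parameters and design
decisions behind `foragemod`, and what the synthetic benchmarks do and do
not establish.

## Arena model and zones

The arena is a circle of diameter 35 cm. Five equally spaced holes sit on
the circle through the pot centers; the tunnel hole is at the bottom and
Pots 1–4 follow counter-clockwise at 72° steps (the equal spacing is a
package convention — published arena drawings do not fully specify the
layout). That circle is the outer radius of the Intermediate zone
(default 12 cm); the Center zone radius is half of it; everything beyond,
up to the wall, is the Wall zone. Pot zones are discs of 1.7× the pot
radius (2.75 cm). The Tunnel-Entry zone is the entry hole (pot radius);
the Tunnel zone shares the pot-zone radius; the In-Tunnel zone is a 1 cm
disc at the peripheral edge of the entry hole where the tracker pins the
animal whenever it is in the tunnel or cage. Zone precedence on overlap:
InTunnel > TunnelEntry > pot zones > TunnelZone > Center > Intermediate >
Wall; out-of-arena positions are flagged, not dropped.

Trials are aligned into this frame by a similarity Procrustes transform
(rotation + translation + isotropic scale, reflection forbidden) fitted on
the trial's recorded landmarks (tunnel + pot centers), after which the
tunnel center is the origin. Alignment is idempotent and is solved in
closed form by SVD.

## Kinematics

Velocity is inter-frame displacement × frame rate (30 /s), median-smoothed
over 5 frames (the commercial tracker's internal smoothing is unspecified;
5 frames suppresses single-frame spikes without distorting bouts). Classes
are closed exactly as stated: slow v ≤ 5, medium 5 < v ≤ 15, fast
v > 15 cm/s; a velocity bout is a maximal same-class run strictly longer
than 3 frames. Missing coordinates are linearly interpolated for gaps of
at most 10 frames, otherwise flagged and excluded from kinematics.

## Excursions and CIMAR keys

An excursion starts at the first frame outside the In-Tunnel zone after an
In-Tunnel frame and ends at the next In-Tunnel frame (half-open, 0-based
frame intervals, so frame accounting is exact). Single-frame excursions
are discarded as zone flicker; genuine sub-second excursions are kept.
Excursions straddling the analysis window are truncated; a trailing trip
that never returns is kept and flagged open-ended. The module-discovery
window defaults to 25 minutes and the epoch analyses to 30 minutes — both
windows appear in the assay design and both are configurable. Keys have
the form `m012.e003.F.adult.KO.Foraging` and round-trip losslessly.

## The 57-measure catalog (version `fm57-1`)

The catalog covers, per excursion: dwell-time fractions, visit counts and
first-visit latencies for nine zones (Pots 1–4, TunnelZone, TunnelEntry,
Center, Intermediate, Wall); duration; path length; maximal and mean
distance from the tunnel; mean distance from the wall; tortuosity;
straightness (mean cosine of the turning angle); turning-angle spread;
x/y spread and correlation; radial spread; velocity mean/max/sd; bout
count, time fraction and mean bout length per velocity class; exit and
entry speeds; latency to leave the tunnel zone; pot-zone entries; and the
number of distinct pots visited. Dwell fractions are normalized by the
excursion's arena time (the trip-level TTA), so they lie in [0, 1];
latencies are measured from the excursion's arena entry (the trip-level
analogue of subtracting the latency to enter the platform) and are
censored at the excursion duration when a zone is never visited. The
trial-level TTA/LEP normalizers, including per-bin TTA, live in
`NormalizationContext` for the epoch statistics. Two numerical
conventions matter: turning statistics use locomotion steps only
(> 0.15 cm), because tracking jitter at a standstill has random headings;
and the signed mean turn is deliberately replaced by straightness, whose
sign does not depend on the arbitrary direction of out-and-back
reversals. Columns are z-scored (ddof 1) across excursions; constant
columns are zeroed and flagged rather than dropped, preserving the
57-column contract. Trial-level measures (sand displacement, food
consumption) are not excursion properties and enter through the epoch
statistics instead.

## Module detection

Mice are split 50/50 into training and test partitions, stratified by
genotype × sex (mice are the partition unit and appear in both phases, so
phase cannot stratify a mouse-level split). PCA is fitted on the training
excursions; the retained component count maximizes the cluster count
found by the tree cut over a scan range (default 2–12), ties toward fewer
components.

### Hybrid dynamic tree cut

Authored here (no canonical implementation is importable in this
environment): Ward.D2 linkage is processed bottom-up; when two branches
meet at height *h*, each branch qualifies as a cluster if it has at least
`min_cluster_size` (20) members and its **core** — its lowest
`min_cluster_size − 1` internal joins — is both tight (mean core height ≤
`max_core_scatter`·h on the height axis scaled to the 0.99-of-maximum cut
height) and separated from the merge (scaled gap ≥ `min_gap`). Two
qualified branches stay separate clusters; otherwise they fuse. The
deep-split sensitivity 0–4 maps to
(max_core_scatter, min_gap) ∈ {(0.64, 0.27) … (0.95, 0.0375)}; at 4 a
structureless cloud is deliberately cut into many minimum-size fragments.
Unassigned points are then absorbed by the nearest cluster centroid when
within that cluster's radius (PAM-like stage).

Because a deep cut can also slice one compact cluster into adjacent
fragments, catalog construction applies a consolidation stage: for every
cluster pair, members are projected onto the inter-centroid axis and the
pair is fused when the relative point density in the middle band
(0.35–0.65 of the span) is ≥ 0.25 — fragments of one mode have no valley
between them (measured scores 0.36–0.56) while genuinely distinct
clusters score ≤ 0.2. The cluster-existence null test (below) uses the
raw, unconsolidated cut on both the observed and the null side: the
fragmentation of structure-free data is exactly its signal.

### Cluster existence

Each of the (default 10,000) iterations permutes every feature column
independently, re-runs PCA + clustering, and counts clusters; genuinely
structured data yields far fewer clusters than the shuffled null. The
lower-tail p is the observed count's exchangeable rank among the null
counts with uniform random tie-breaking; the count statistic is discrete,
and randomized tie-breaking is what makes the p-value exactly uniform
when the input itself carries no structure (p ≥ 1/(iterations+1) always).

### Reproducibility (IGP) and module certification

Test-partition excursions are assigned to the nearest training-cluster
centroid in PC space; a cluster's IGP is the fraction of its assigned
test points whose nearest test-set neighbor is assigned to the same
cluster. The permutation null destroys the *test data's* cluster
structure: each permutation independently shuffles every column of the
test scores (preserving marginals) and recomputes every cluster's IGP
against the observed centroids. Per-cluster p-values use +1 smoothing;
q-values use the pi0-estimating FDR method (cubic smoother over a lambda
grid for ≥ 100 tests, the single-lambda 0.5 estimator below that, where
the smoother's tail extrapolation is too variable); clusters with q < 0.1
are modules. Measured behavior: type-I error 0.047 at nominal 0.05 over
200 structureless datasets; perfectly reproduced clusters reach the
smoothing floor in the operating regime (≥ ~6 clusters in ≥ ~8
dimensions). Known limitation: with only 2–4 extremely tight clusters,
any marginal-preserving null retains corner atoms at the original clump
positions and the test turns conservative. Alternatives were measured and
rejected: centroids drawn uniformly in the test bounding box are strongly
conservative (type-I ≈ 0.008), and membership-permutation centroids lose
all power on strongly clustered data (null IGP saturates at 1).

Test excursions take the module label of their nearest training centroid;
training excursions keep their cluster's label; non-module clusters and
unassigned points are labeled non-modular.

## Expression statistics

Counts are tallied per mouse × phase (× epoch; an excursion belongs to
the epoch containing its start time). The interaction test fits Poisson
GLMs `count ~ sex + genotype + module + genotype:module` against the
main-effects model (per-mouse rows — the sex term requires them — and
likelihood-ratio chi-square for the interaction block). Post-tests fit
`count ~ sex + genotype` per module after dropping modules at or below
the 0.1 expression-variance quantile (the filter threshold is a package
default; only the filter itself is prescribed), with q < 0.05
significance. Goodness of fit is the upper-tail chi-square of residual
deviance at residual df; when it fails, a negative-binomial refit is an
available sensitivity check, but Poisson remains the headline model.
Contingency analyses column-scale the module × group count matrix
(z-score per column, preserving within-column rank order), cluster
columns by Ward linkage, and test dependence by chi-square, switching to
an exact test when > 20% of expected cells are < 5 — fully exact for
2×2, Monte-Carlo exact (Patefield sampling conditional on margins,
probability ordering, +1 smoothing) for larger tables.

## Epoch statistics

The windowed bias test fits, per 1-minute window (step = width = 1 by
default), a Gaussian GLM `time ~ sex + pot` on paired per-mouse times at
Pot2 and Pot1; a window is significant when the pot effect has p < 0.05
*and* favors Pot2. Epochs start at every non-significant→significant
transition and run to the next onset; epoch 1 extends back to minute 0;
no onsets means one epoch. Mice contribute paired rows without a random
effect (the simplest model consistent with a sex-absorbing patch
contrast). Cumulative patch-time curves carry missing minutes forward and
end at the total patch time; the endpoint model is
`time ~ sex * factor` with factor genotype or consolidation timing. Food
consumption uses `consumed ~ sex + genotype * phase` on fractions in
[0, 1]; a perfectly constant outcome reports p = 1 (all effect
coefficients are exactly zero). Panel statistics: paired t-test on entry
latencies across phases, one-way ANOVA over the four pots with
Tukey-adjusted pairwise tests (for two groups the Tukey-adjusted p equals
the unadjusted t-test).

## Transition dynamics

Per mouse, module-labeled excursions ordered by start time form a token
sequence; non-modular excursions are removed and the sequence re-linked
(a chain-break alternative is available). Pairs are counted within-mouse
only and aggregated per group. Counts get 1e-6 smoothing before row
normalization, guaranteeing a unique stationary distribution, solved as
the null space of (Pᵀ − I) with the normalization constraint (exact to
~1e-15 on closed-form cases). Dependence of the next module on the
current one uses the exact/Monte-Carlo margin-conditional test above.
Group differences: Euclidean distance between stationary distributions,
against a null that permutes whole per-mouse sequences between groups
(preserving within-mouse dependence; token-level resampling would break
it), ≥ 10,000 permutations by default, +1 smoothing; degenerate
permutations (an empty group) are resampled and reported.

## Cartography

The excursion landscape is embedded with PHATE when the package is
importable; otherwise with the built-in diffusion map (adaptive Gaussian
kernel at the 15-NN bandwidth, symmetrized, diffusion-scaled eigenvector
coordinates, eigenvector signs fixed for determinism). Embedding
hyperparameters are recorded in the result.

## Synthetic cohorts: what they emulate and what they do not

Defaults are the study conditions: 15 mice per genotype × sex cell (60
mice), Exploration + Foraging phases of 30 min at 30 frames/s, and
≈1,600 excursions in total. Six planted archetypes emulate described
module types — direct darts to the food pot (whose rate is elevated in
knockouts), brief home darts, former-food-patch checks (strongly reduced
in knockouts and rate-modulated in minute-windows to plant the epoch
structure: wild-type waves at minutes 0–10, 12–17 and 19–30), wall
patrols, center exploration with a control-pot visit, and two-pot tours.
Trajectories are waypoint paths with temporally autocorrelated Gaussian
positional jitter (sd 0.3 cm; white jitter would add ±12 cm/s of phantom
velocity) and 7% speed jitter. Noise excursions are *mouse-specific*
idiosyncratic templates (1–3 per mouse, ~1 trip per trial, ≈8% of
excursions): idiosyncratic behavior by definition does not recur across
held-out mice, which is exactly why non-modular excursions fail the
reproducibility test. The real study's non-modular fraction is far larger
(roughly 40%); the planted benchmark favors a clean recovery surface over
that realism. Excursions are laid out in time with exponential home
dwells (mean 20 s) and at least 0.5 s of home time between trips. The
epoch benchmark configuration is a single-genotype, Foraging-only cohort
with long (7 ± 1 s) former-patch dwells inside the waves and
Pot1-balanced occupancy outside them.

Passing the planted benchmarks shows the pipeline recovers structure it
was designed to detect under its own generative assumptions — compact,
well-separated archetypes, idiosyncratic noise, Gaussian tracking error.
It does not show that real foraging data contains such structure, nor
how the detector behaves under gradual archetype overlap, drift within a
trial, or non-modular behavior that is consistent across mice.

## Validation surface and problem sizes

All benchmarks live in `foragemod.validation` and are executed both by
the test suite and by `scripts/acceptance.py`. Sizes: module recovery —
20 full cohorts (~1,600 excursions each) with 2,000 IGP permutations;
IGP calibration — 200 structureless datasets (300 + 300 points, 6 dims,
200 permutations); existence test — 1,000 null iterations for power and
100 runs × 99 iterations for uniformity; GLM — a 16-row worked table
against a hand-rolled IRLS oracle (agreement ~1e-14) plus 50 simulated
cohorts with rate-ratio-2 effects on 6 of 24 modules at 15 mice per cell;
epochs — 20 simulated cohorts of 30 mice; transitions — closed-form
stationary checks, full hypergeometric enumeration of the 2×2 exact test,
30 power and 100 calibration simulations; determinism — two identical
pipeline runs compared byte-for-byte on the module catalog.
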