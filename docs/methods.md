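# Methods

`popfam` re-implements, as a tested pipeline over synthetic ground truth, a
population-coding analysis of visual familiarity in mouse visual cortex:
from two-photon calcium fluorescence traces to functional-connectivity
graphs, neuronal ensembles, population statistics (sparseness, selectivity,
orientation tuning, representation persistence), plasticity ratios,
force-plate behavior, and dendritic E/I synapse statistics. This note
records the models, the parameters that matter, and the design choices made
where the procedure was genuinely open.

## Trace preprocessing

Cellular fluorescence is corrected for neuropil contamination as
`Fcorr = F − 0.5·Fneu` (the contamination coefficient is configurable in
[0, 1]; 0.5 is the default throughout). The baseline F0 is:

* **multi-stimulus sessions** — the mode of the Fcorr density, estimated by
  a Gaussian KDE with Silverman bandwidth, maximized on a 512-point grid
  spanning [min, max] with ties broken toward the smaller value. "Mode of
  the density" does not pin down an estimator; this is the simplest robust
  one. F0 is computed over the whole session (per-block baselines are not
  attempted). On synthetic data the mode lands a few percent above the true
  resting fluorescence because ongoing spiking shifts the density upward;
  this bias is shared between sessions and cancels in all ratio statistics.
* **plasticity sessions** — the mean Fcorr over the 10 s of gray screen
  preceding stimulus onset.

Activity is the fraction `dF/F0 = (Fcorr − F0)/F0`; 0.05 means "5%". All
percentage thresholds are converted to fractions at the configuration
boundary and every threshold is a strict inequality ("greater than").

Spike events are frames whose deconvolved activity strictly exceeds the
per-neuron mean + 2 SD, both computed over the full trace including zeros.
The pipeline consumes a deconvolved-activity matrix; it never runs a
deconvolution algorithm (the generator emits ground-truth spikes plus small
Gaussian jitter in its place).

Quality control: neurons need at least one dF/F0 peak strictly above 10%
anywhere in the session; plasticity sessions additionally drop neurons
whose F0 falls strictly outside mean ± 2 SD of the population F0, and a
recording-level flag is raised when the mean population dF/F0 to the novel
stimulus is below 1%.

## Responses and classification

Responses are trial-averaged across cycles (8 in the multi-stimulus
session). A neuron is active for a stimulus when its trial-averaged
stimulus dF/F0 strictly exceeds 5% (high threshold) or 2 SD of the baseline
dF/F0 (low threshold) **and** a two-sided paired t test of per-trial
stimulus means against the per-trial means of the 3 s of gray immediately
preceding each presentation gives p < 0.05. Open choices resolved here:

* The baseline SD for the low threshold is the frame-wise SD of the
  trial-averaged preceding-gray trace (the simplest reading; a per-trial SD
  would only add estimation noise).
* The low-threshold criterion is implemented as the permissive union
  (passes the low *or* the high cut), so the high-threshold active set is a
  subset of the low-threshold set by construction. Without this the
  containment could fail in the pathological case 2·SD > 5%.
* Degenerate pairings (zero variance of the trial differences) make the t
  statistic undefined; such neurons are classified by threshold alone and
  flagged.

Plasticity sessions have a single trial; classification pairs the 10-s
stimulus window frame-wise with the 10-s preceding gray window.

AUC is the trapezoidal integral of the dF/F0 trace (dF/F0·s) over 3-s
(multi-stimulus) or 10-s (plasticity) windows.

## Functional connectivity

Two neurons are functionally connected when their observed coactivity count
(frames in which both are active) strictly exceeds the nearest-rank 95th
percentile of 1,000 surrogate counts, with at least one observed coactive
frame required (this floor prevents degenerate edges between near-silent
neurons whose surrogates are all zero). Each surrogate applies independent
uniform circular shifts in [1, T−1] to both trains; the count of a shifted
pair equals the circular cross-correlation at the relative lag, so the full
lag table is computed once by FFT and surrogate shifts index into it —
mathematically identical to rolling the trains, two orders of magnitude
faster. The multi-stimulus graph uses the entire imaging period; plasticity
graphs use the first 10 s of stimulus only.

The discrete nearest-rank rule with a strict inequality is conservative:
for sparse trains (few expected coactive frames) ties at the percentile cut
push the realized false-positive rate below the nominal 5%, approaching it
only when counts are large (evoked-regime rates of ~2 events/s at 4.22 Hz).
The calibration check is therefore run in that regime; at spontaneous rates
the test errs on the side of fewer edges, never more.

Degree skewness is the Fisher–Pearson moment coefficient g1 (no bias
correction). Tuning similarity of connected pairs uses the doubled-angle
circular metric `0.5·arccos(cos 2Δθ)` ∈ [0, π/2].

## Ensembles

Frames with fewer than 3 coactive neurons are excluded. Frames without any
neighbor above 50% Jaccard similarity are excluded (equivalently: their
single-linkage merge height on Jaccard distance is ≥ 0.5). Remaining frames
are Ward-clustered on Jaccard distance and the tree is cut at the k in
2..min(10, n−1) maximizing a contrast index

    contrast(k) = (mean within-cluster − mean between-cluster similarity)
                  / (mean within + mean between)

The source method's exact contrast index is not published; this form is a
stated stand-in. On recordings with appreciable background activity the cut
alone over-splits: chance-coincident coactive frames pass the neighbor
filter (a birthday effect among hundreds of frames) and the index keeps
improving as they are split into tighter groups. A cohesion filter
therefore follows the cut: clusters whose **mean pairwise** Jaccard
similarity does not exceed the same 50% threshold are chance groups, not
ensembles, and are dropped. On noiseless planted data this changes nothing.

Each ensemble j is a binary vector V_j over all frames. Neuron
participation uses Pearson (phi) correlations of binary trains: P_a =
corr(train_a, V_j), Co_ab = corr(train_a, train_b), and the pair weight
W_ab = P_a·P_b·Co_ab. Membership is decided in two stages, both against
1,000 circular-shift surrogates at the strict nearest-rank 95th percentile:

1. a neuron is a candidate when P_a exceeds the percentile of its
   shifted-train correlations with V_j;
2. candidates a, b are connected within the ensemble when W_ab exceeds the
   percentile of surrogate weights from independently shifted trains; a
   candidate is a member when it has at least one such connection.

Stage 1 is essential, not cosmetic. Testing the pair weight alone against
both-trains-shuffled surrogates is structurally anticonservative: for an
unrelated neuron a paired with a true member b, the observed weight scales
as σ²·P_b (σ the null correlation scale) while the surrogate weights scale
as σ³, so roughly half of such pairs clear the percentile and nearly every
neuron inherits membership. Gating on the neuron's own ensemble correlation
— which is also how participation is described in the source analysis —
restores a ~5% per-neuron false-membership rate. Zero-variance trains are
untestable and flagged excluded.

Under a circular shift only co-occurrence counts change, so all surrogate
correlations are likewise read from FFT cross-correlation tables.

## Population statistics

**Sparseness.** `S = [1 − (ΣR/n)²/(ΣR²/n)]/(1 − 1/n)` over per-neuron AUCs
(3-s window for the multi-stimulus experiment, 10-s for plasticity);
0 = equal activity, 1 = a single active neuron. Negative AUCs are clipped to
0 first — the statistic assumes nonnegative responses and can otherwise
exceed 1. An all-zero population is undefined and raises.

**Selectivity.** The same core without the finite-size normalization,
`SI = 1 − (ΣR/n)²/(ΣR²/n)`, over the 13 per-frame trial-averaged
deconvolved amplitudes of a 3-s natural-image set (deconvolved amplitudes
avoid the slow calcium decay bleeding across the 0.3-s images). A single
active frame of 13 gives 12/13 ≈ 0.923.

**Orientation tuning.** The von Mises curve
`f(φ) = A·e^{K(cos[2(φ−θ)]−1)} + b` is fit to the four grating AUCs: θ and
K are initialized by weighted circular statistics on the doubled angles
(weights = baseline-subtracted responses, K from the standard
Bessel-ratio inverse) and A, b by linear least squares; all four parameters
are then refined jointly by nonlinear least squares. The joint refinement
matters: the two-stage estimate alone is exact only when θ lies on a grid
symmetry axis, whereas with four angles and four parameters the refined
curve interpolates exact von Mises data (R² = 1, parameters recovered to
machine precision). Fits are valid when R² ≥ 0.7; flat responses are
invalid. Tuning width is reported as printed:
`FWHM = arccos(ln(½e^K + ½e^{−K})/K)`, which is strictly decreasing in K
and → π/2 as K → 0. Whether this formula returns width in stimulus angle or
doubled angle is ambiguous in its source; it is implemented verbatim and
not rescaled.

**Representation persistence.** Each frame's population dF/F0 vector is
normalized to unit length; the overlap at lag ℓ is the mean dot product
between frames t and t+ℓ over the analysis window (stimulus onset to 10 s
after onset), for ℓ = 1..50 frames. Zero-norm frames are excluded (their
unit vector is undefined). The curve is fit with
`Overlap(t) = (1−b)e^{τt} + b`, τ ≤ 0, 0 ≤ b ≤ 1 — equal to 1 at t = 0 by
construction. Initialization: b₀ = min(curve), τ₀ from a log-linear
regression of (curve − b₀); a constant curve drives τ to the fast-decay
boundary and is flagged by inspection of the fit.

**Plasticity ratios.** Post/pre-training ratios of: mean population AUC of
the first 10 s of stimulus, active-neuron fraction, high-responder fraction
(mean window dF/F0 > 15%), mean node degree of active neurons, and the
overlap decay rate τ. Zero pre-training denominators yield NaN.

## Behavior

Position is the force-weighted centroid of the four corner-sensor
coordinates of the 42-cm force plate, after moving-average smoothing of the
force channels (window 5 samples = 50 ms at 100 Hz; the width is not
specified in the source and 50 ms is short enough to leave 2-Hz behavior
untouched). Smoothing precedes the centroid, matching the order in which
the steps are described. Zero-force samples are interpolated from neighbors
and flagged. Paths are down-sampled 100 → 2 Hz by block means (a final
partial block is dropped). Active exploration is speed ≥ 3 cm/s (inclusive)
from consecutive-sample displacement. The SZP index is
`(t_SZ − t_NSZ)/(t_SZ + t_NSZ)` over exploration samples only — the
denominator is total *exploration* time, not session time. Samples exactly
on the midline count as non-stimulus zone, the conservative direction for a
memory claim.

## Synapse statistics

Per-dendrite densities per 100 μm: excitatory = (PSD95⁺ spines + dually
innervated spines)/length, inhibitory = (shaft gephyrin + DIS)/length. DIS
carry both a PSD95 and a gephyrin punctum and are counted toward both; the
excitatory inclusion is configurable since the source is not explicit. The
E/I correlation is Pearson across dendrites with a two-sided p; two
correlations are compared with the Fisher r-to-z statistic
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`. Gephyrin turnover:
gain = |S₂∖S₁|/|S₂|, loss = |S₁∖S₂|/|S₁| on identity-matched puncta sets.

## Synthetic data generator

The generator emulates the acquisition conditions, not the biophysics:

* **Schedule** — 4.22 Hz imaging; multi-stimulus sessions are 30 s gray
  then 8 cycles of four 3-s gratings (0/45/90/135°) and two 3-s
  natural-image sets (10 images, 0.3 s each) in per-cycle shuffled order,
  each preceded by 6 s gray; plasticity sessions are 60 s gray + one 100-s
  grating. Frames per epoch = ceil(duration × rate) with half-open spans,
  so a 3-s stimulus spans 13 frames.
* **Spiking** — Poisson with rate = baseline + von Mises evoked rate during
  gratings + per-image multiplicative gains on the baseline during natural
  images (the simplest structure that supports the selectivity index; the
  source states no natural-image amplitude distribution, so the lognormal
  gain spread σ = 1 is a free default, not a claim). Planted ensembles add
  co-firing events (Bernoulli event frames, per-member participation).
* **Fluorescence** — spikes filtered by an exact exponential kernel with
  decay constant `calcium_tau` = 2.0 s on a per-neuron baseline (~80–120
  a.u.), 0.3 dF/F0 per spike, plus a shared slow neuropil background mixed
  in at the 0.5 contamination coefficient and i.i.d. Gaussian noise (2 a.u.
  default). The neuropil channel is the shared background plus noise, so
  the 0.5 correction removes the contamination exactly on average — the
  additive-contamination assumption behind the correction formula.
* **Training** — multiplicative factors on evoked rates, on the
  strongly-tuned fraction, and on ensemble-event persistence, applied to
  post-training sessions.
* **Dendrites** — bivariate lognormal E/I densities; the target Pearson r
  applies on the density scale via the exact lognormal correlation mapping
  `ρ_log = ln(1 + r·√((e^{σ²}−1)²))/σ²`. Defaults: 50 E and 25 I synapses
  per 100 μm, σ_log = 0.25, r = 0.43.
* **Force plate** — forces are the bilinear corner weights of a scripted
  path, so the centroid formula recovers the path to machine precision
  before smoothing (the round-trip oracle).

What the generator does **not** emulate: imaging noise structure beyond
i.i.d. Gaussian + shared slow background, motion or PSF artifacts, spike
inference errors beyond Gaussian jitter, bursting or adaptation, realistic
retinotopic correlation structure, or multi-day field-of-view drift.
Passing tests therefore demonstrate that the analysis recovers what it is
defined to recover under its own assumptions — not that those assumptions
hold in any particular real recording.

## Problem sizes and determinism

The checks run at the scales the analyses describe: 80-neuron
multi-stimulus sessions (~2,000 frames) and 60-neuron plasticity sessions,
cohorts of 11 synthetic mice for the plasticity ratios, 500 train pairs ×
1,000 surrogate shifts for the null calibration, and 2,000 dendrites for
the correlation recovery. Every stochastic step draws from
`numpy.random.default_rng` seeded through `SeedSequence` with fixed
per-stage offsets, so a fixed seed reproduces every output byte for byte.

## Known limitations

* The contrast index and the stage-1 membership gate are stated stand-ins
  for an unpublished procedure; detected ensemble counts on noisy data
  depend on the cohesion threshold sharing the 50% Jaccard value.
* The surrogate connection test is conservative for sparse trains (see
  above); comparisons across conditions with very different rates inherit
  that rate dependence.
* Group-level inferential statistics (ANOVA families, KS tests, etc.) are
  deliberately out of scope; standard routines should be applied to the
  emitted tables.
* Animal-level quantities from the original recordings (e.g. specific
  post/pre means) are not recoverable without the raw data; the pipeline
  recovers planted effects from its own generator instead.
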