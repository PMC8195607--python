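# Methods

`cerebquant` quantifies five data modalities from developmental cerebellar
physiology: extracellular Purkinje-cell (PC) recordings, neuronal
reconstructions, climbing-fiber (CF) histology, compensatory eye
movements, and eyeblink conditioning. Every analysis has a paired
synthetic generator that carries its ground truth, so all estimators are
validated by recovery rather than by comparison with undeposited animal
data. This note records the models, the parameter choices and the
numerical conventions, and what the synthetic validation does and does
not establish.

## Spike trains

**Model.** Simple-spike (SS) inter-spike intervals are drawn from a gamma
renewal process with mean `1/ss_rate` and shape `k`, so the ISI
coefficient of variation is `1/sqrt(k)`; shape 1 is Poisson-like and
large shapes approach clockwork firing. No ISI family is implied by the
measurements themselves; gamma was chosen because it spans the
regular-to-irregular regimes seen across development with one parameter.
Complex spikes (CS) are an independent homogeneous Poisson process — the
simplest process consistent with CS CV2 in the 0.8–0.9 range — and every
SS within `cf_pause` seconds after a CS is deleted, reproducing the
climbing-fiber pause. Defaults describe an adult-like cell: SS 60 Hz,
shape 4 (CV 0.5), CS 1 Hz, pause 20 ms, 120 s duration.

Deletion thins the SS rate to `ss_rate·exp(−cs_rate·cf_pause)`; at the
default rates this is within 0.1% of the linear `1 − cs_rate·cf_pause`
form, which is how the property is tested.

**Statistics.** CV is the sample SD (n−1 denominator; the convention is
configurable in spirit but n−1 is fixed here) over the mean of ISIs. CV2
is `2|ISIn+1 − ISIn|/(ISIn+1 + ISIn)` per adjacent ISI pair; it is
algebraically confined to [0, 2) and its mean is exactly 1.0 for iid
exponential ISIs (the pairwise statistic `2|X−Y|/(X+Y)` is uniform on
(0, 2)), which the tests use as a closed-form limit. The regularity
index is the fraction of spikes participating in at least one locally
regular pattern, a CV2 value < 0.2 (each value covers three consecutive
spikes). Membership is **spike-based**, not ISI- or epoch-based — an
explicit operationalization, verified exactly against a brute-force
triplet enumeration, since the verbal definition admits several readings.

SS CV and CV2 exclude ISIs that contain a CS by default
(`exclude_cs_spanning=True`): the CF pause stretches exactly those
intervals and would otherwise register as irregularity of the SS process
itself. The CV2 series keeps one slot per adjacent ISI pair (length
n_SS − 2) with excluded pairs as NaN, so series bookkeeping is
independent of the toggle. The CF pause is reported as the mean over CSs
of the time to the next SS (median also exposed); its expectation under
the model is the enforced pause plus the stationary forward-recurrence
time of the renewal process, which gives the Monte-Carlo oracle used in
testing. Cells shorter than the 90-s inclusion gate are marked
`included=False` but still computed.

## Spike sorting

**Detection.** The absolute signal is thresholded at `threshold_k`
(default 4.5) times a robust noise scale, 1.4826 × the median absolute
deviation — MAD rather than SD because the spikes themselves would
inflate an SD estimate. One event is kept per 1-ms refractory window and
each is aligned on its absolute-peak sample. A complex spike is a single
multiphasic event several ms long whose spikelets can cross the
threshold on their own; a secondary peak is therefore merged into a
preceding event when it lies within 5 ms of it **and** its amplitude is
below 0.6 of the earlier peak's. Full-size spikes following a large
event survive the rule (their amplitude ratio is ~1), so genuine
short-ISI firing is not censored; the rule is amplitude-relative, which
keeps it SNR-independent. Detection is invariant to sign flips of the
trace by construction.

**Classification.** Snippets are Gaussian-smoothed along time (sigma =
1/20 of the snippet length) before projection onto the first two
principal components. The smoothing matters: the discriminative CS
features (spikelets, slow depolarization envelope) are low-frequency,
whereas per-sample noise and ±1-sample alignment jitter are
high-frequency and otherwise capture the leading PCs at low SNR.
Partitioning is 2-means with a deterministic farthest-point
initialization (first center: the point farthest from the data mean;
second: the point farthest from the first; ties break toward the lower
event index), so results are seed-free. The CS cluster is the sparser
one; when the sparser cluster does not also carry the larger mean
waveform integral, the result is flagged `needs_review` rather than
silently resolved. Classification is invariant to rescaling all snippets
by a common positive factor (every step is linear or scale-equivariant).

**Single-unit validation.** A recording is accepted as a single unit
when the mean CS-to-next-SS interval exceeds the mean SS ISI (computed
over ISIs not containing a CS). The per-CS pause distribution is exposed
for quality control.

Validated performance: pooled over 20 synthetic cells (10 s each, 50 kHz,
SS 50 Hz / CS 1 Hz) at peak SNR 5, detection recall and precision and
end-to-end label accuracy are all ≥ 0.99. At 20 kHz sampling the
per-event miss probability rises to ~2% at the same SNR (fewer samples
near the peak); the validation therefore uses the 50-kHz acquisition
configuration.

## Morphometry

Trees are SWC files parsed with line-level error reporting (cycles,
multiple roots and dangling parents are rejected by name). Sholl
crossings count parent–child segments that straddle a concentric radius:
with endpoint distances `d_lo ≤ d_hi`, a segment crosses radius `r` iff
`d_lo < r ≤ d_hi`. The half-open rule makes endpoint-on-circle cases
deterministic and is what the brute-force oracle implements. Radii run
from one `radius_step` (default 1 µm; profiles at any step are
oracle-checked, absolute counts are step-dependent by nature) to the
largest node distance. Dendrites are analyzed in 2-D (xy projection,
centered on the SWC type-1 soma — an error if absent); axon arbors in
3-D, centered on the first branch point, defined as the node with ≥ 2
children at minimal path distance from the root (ties to the lower node
id). The mode is always an explicit argument.

The projected area is the convex hull of all nodes projected to xy. The
measured quantity it models is a thresholded-mask area of a filled cell;
the hull is a vector-geometry analog that bounds the mask area from
above wherever the silhouette is non-convex, and a rasterize-and-count
alternative (`rasterized_area`, painting segments with their radii onto
a grid) is provided as a fidelity cross-check. Degenerate (collinear)
geometry returns 0 with a warning.

The tree generator grows segment by segment from a soma: each tip
bifurcates with probability `branch_prob` or continues with direction
jitter, to `max_depth` segments; `planar=True` confines growth to the
xy-plane like a PC dendritic arbor, `planar=False` grows 3-D arbors.
With branch probability 1 this is a full binary tree and with 0 an
unbranched path, which pins down the combinatorics in tests.

## Histology

Images are single-plane grayscale arrays with a physical scale; pixel
centers sit at `(i + 0.5)·µm_per_px`, and the soma edge is a horizontal
line with the molecular layer (ML) extending apically. Puncta are
8-connected components above a fixed intensity threshold with at least
`min_size_px` pixels (the component count is verified exactly against a
flood-fill oracle); a fixed threshold is the default because an
adaptive one (Otsu) would tie the measurement to per-image content —
both the threshold and the choice are recorded in outputs. Density is
centroids inside a half-open rectangular ROI divided by its area
(µm⁻²); a ×100 "percent-style" scaling is trivially available but the
raw density is always the primary value.

ML height is measured at three x-positions as the distance from the soma
line to the top edge of the outermost supra-threshold pixel in that
column; positions with no signal are skipped and counted. CF height uses
the most apical punctum **centroid** within ±10 µm of each measurement
line, and the CF extension is `100·mean(CF)/mean(ML)` per image. The
centroid convention under-reads the true band top by roughly the mean
gap to the most apical punctum (≈ 1/(density·window width)) plus misses
the punctum radius; at the dense adult-like configuration used for
validation (0.05 puncta/µm²) the bias is ≈ 1 µm and a built 80.5%
extension is recovered within 2 percentage points. At sparse densities
the same estimator reads low — a property of the measurement, not a
defect, and the reason the density read-out and the extension read-out
are validated in separate regimes.

## Compensatory eye movements

The stimulus is `A·sin(2πft)` with frequency known (stimulus-controlled,
never estimated). Gain and phase come from sine fits at the stimulus
frequency: quick phases are masked where the eye velocity deviates from
its median by more than 5 × the MAD scale (±25 ms margin; a warning
fires when more than half the trace is masked), both traces are
zero-phase low-pass filtered (4th-order Butterworth, 6 Hz), numerically
differentiated, and fitted with `a·sin + b·cos + c` by least squares on
unmasked samples. Gain is the ratio of fitted velocity amplitudes and
phase the fitted eye-minus-stimulus difference, wrapped to (−180°, 180°],
positive = eye leads.

Fitting the **velocity** samples directly, rather than differentiating a
position fit analytically, is deliberate: saccadic steps leave
piecewise-constant offsets in position that a single-intercept sine fit
cannot absorb, whereas in velocity they are isolated impulses that the
mask removes entirely (the mask is widened by the filter response time
so smeared edges stay excluded). For clean sinusoids the two routes are
identical; with injected quick phases the velocity route keeps the gain
error below 0.02. The low-pass stage controls the noise amplification of
differentiation (white position noise would otherwise dominate the
velocity fit); its attenuation at the stimulus frequency cancels in the
gain ratio and contributes no phase because the filter is zero-phase.

For the VOR, phase is reported relative to the perfectly compensatory
direction: a perfect VOR is (gain 1, phase 0) and a fully reversed VOR
approaches 180°, which makes the phase-reversal learning curve read
naturally. The phase-reversal protocol object encodes 5 days × 6
sessions at 0.6 Hz with drum amplitudes 5°, 7.5°, then 10° on days 3–5
against a fixed 5° table. Consolidation is
`100·(dx_t0 − dx_next_t0)/(dx_t0 − dx_t30)` — before-training value on
day d, before-training value on day d+1, last value on day d — computed
for gain over day 1→2 and phase over days 2→3 and 3→4; a zero
denominator (no within-day change) is an explicit undefined status, and
missing probes are flagged, never imputed.

Recovery validation: over gain ∈ {0.2…1.0} × phase ∈ {−90°…90°} with
noise at 10% of the eye amplitude and 20 stimulus cycles, at least 95%
of 100 runs per cell land within ±0.02 gain and ±2° phase.

The generator's quick phases are instantaneous steps at Poisson times
(sign-symmetric normal magnitudes); real quick phases have ~20 ms
rise times and position-resetting dynamics, which the masking margin
renders irrelevant to the fit but which this generator does not emulate.

## Eyeblink conditioning

A session is 20 blocks of [1 US-only, 10 paired, 1 CS-only] = 240
trials; the CS (LED) lasts 280 ms, the US (air puff) 30 ms, onset 250 ms
after CS onset so the two co-terminate. Raw eyelid traces are converted
to the fraction of eyelid closure, FEC = (area − open)/(closed − open),
clipped to [−0.1, 1.1] with clip counts reported. Trials are normalized
by subtracting the 500-ms pre-CS baseline mean and dividing by the
session's full-blink size — the **median** UR peak across US-containing
trials, median for robustness to single outlier blinks. A trial is
invalid when its pre-CS FEC range (max − min) strictly exceeds 0.05, the
same scale as the CR amplitude criterion; "significant pre-CS activity"
is not otherwise defined, so this operationalization (threshold
configurable) is declared rather than inferred.

A conditioned response on a valid paired/CS-only trial requires all
four: amplitude (peak FEC in [0 ms, US time]) > 0.05; onset — the first
post-CS sample exceeding 0.05, an explicit operationalization of the
latency criterion (a 10%-of-peak alternative would shift onsets by a few
ms on ramps) — within [50, 250] ms; peak latency within [100, 250] ms;
and a positive least-squares slope over the 150 ms before US time. All
windows are closed; boundary samples count. CR% is CR-positive valid
(paired + CS-only) trials over valid such trials, ×100. UR onset is the
first post-US sample exceeding the pre-US level (mean of the preceding
50 ms) by 0.05, and UR peak is the post-US argmax.

The generator draws CRs with probability `cr_prob` as raised-cosine
closures with onset/peak latencies uniform in windows that satisfy the
criteria by construction and amplitudes clipped to [0.1, 1]; URs rise
5 ms after the puff to the full-blink amplitude; paired trials take the
pointwise maximum of the two components because eyelid closure
saturates. Noise is Gaussian smoothed with a 10-ms kernel and rescaled
to the requested SD: per-sample independent noise at any realistic SD
would trip the pre-CS *range* validity criterion on most trials purely
through sampling extremes, which no physical eyelid trace does. Even
with smoothed noise at SD 0.01 a noticeable minority of trials (~10%)
is invalidated by the range rule — an intended consequence of keeping
both the criterion and the noise honest, and harmless to CR% because
invalid trials leave the denominator. Pooled over 50 sessions per
condition, detected CR% stays within the binomial 95% interval of
cr_prob at 0.2, 0.5 and 0.8, and the detector is unbiased to < 1
percentage point at this noise level.

## Problem sizes and determinism

Every generator takes one integer seed and owns a single
`numpy.random.Generator`; identical seeds give bit-identical outputs,
and the pipeline runner records seed and config hash in all metadata.
The validation suite uses problem sizes chosen so each check's
Monte-Carlo error is several times smaller than its tolerance: 10,000
ISIs for the closed-form limits; 100 random trees / 1,000 random trains
/ 50 random images for exact oracle agreement; 2,500 gain-phase
recoveries; 50 conditioning sessions per CR probability; 20 ten-second
cells for sorting; 1,500 s of spiking (~1,200 pauses) for the CF-pause
oracle, whose standard error (~1%) sits well inside the 5% band.

## Limitations

Synthetic recovery bounds estimator error under the stated models only:
fixed spike waveforms without amplitude drift or bursting, stationary
renewal firing, disk-shaped puncta with uniform placement, stationary
sinusoidal eye responses, and stereotyped CR/UR shapes. Real recordings
add electrode drift, waveform variability and overlapping units;
real images add uneven illumination and 3-D structure; real eyelid
traces add spontaneous blinks that the validity rule only partially
models. The sorter is two-class by design (no multi-unit demixing), the
Sholl counts depend on the chosen radius step, and the convex-hull area
systematically exceeds a thresholded-mask area for non-convex arbors.
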