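# Methods

This note documents the models, conventions and numerical choices behind
`hdmea`, in the spirit of the methods documentation of simulation and
analysis packages: what is computed, under which assumptions, and what
the synthetic validation does and does not demonstrate.

## Chip model

The default chip is a 64×64 grid (4096 electrodes) at 60 µm pitch,
sampled at 20 kHz; electrodes are numbered row-major with electrode 0 at
the origin, so electrode *(row, col)* sits at *(col·pitch, row·pitch)* µm.
Planar electrodes are 21 µm squares; 3D variants carry microneedles
(90 µm × 26 µm for slices, 65 µm × 14 µm for spheroids/organoids) on
pedestals. Pedestal width + microchannel width equals the pitch, so the
tissue-contact area of a 3D chip is `4096 · pedestal_width²`: 7.9 mm² at
44 µm (small microchannels), 5.3 mm² at 36 µm (intermediate), 3.7 mm² at
30 µm (large; quoted elsewhere as 3.6 mm² — the 0.1 mm² discrepancy traces
to an ambiguous area convention and this value is not asserted anywhere).
A planar chip contacts its full footprint, (64·60 µm)² = 14.75 mm².

Amplifier quality is summarised from an injected reference sine (100 µV
peak-to-peak at 1 kHz): power is the mean squared mean-removed amplitude,
so a pure sine has power A²/8; SNRₑ = P_signal/P_noise per electrode and
the chip SNR is the median across electrodes (robust to a few dead
channels).

## Synthetic recordings

The generator stands in for recordings that cannot be redistributed; it
reproduces the statistical structure the analyses assume, with a
ground-truth sidecar for round-trip validation.

* **Units** are gamma-renewal processes: shape k gives ISI CV = 1/√k.
  Defaults use k = 1.8 (CV ≈ 0.75, matching the sub-Poisson regularity of
  cortical units in slice); scenarios validating the spike detector use
  k = 5, whose refractory-like ISI floor matches real neurons — a
  Poisson unit occasionally fires twice within the detector's 1 ms
  refractory period, a coincidence no threshold detector can resolve.
* **Bursts** are planted as Poisson-timed runs of n spikes at a fixed
  intra-burst ISI, satisfying the ≥5-spike / ≤100 ms rule by construction.
* **Connections** copy each source spike into the target with transfer
  probability p at a Gaussian lag (mean ≤ 30 ms). The *standard network*
  used for connectivity validation is a convergent feed-forward motif
  (15 sources → 5 targets, three inputs per target, p = 0.5,
  lag 6 ± 2 ms, 5 Hz units, 600 s). The motif is chosen deliberately: in
  recurrent graphs, chains and shared sources induce genuine second-order
  correlations that any pairwise correlogram method reports, so planted
  adjacency and true pairwise structure only coincide when no unit is both
  source and target. Passing the recovery test therefore shows the method
  finds direct correlations reliably — not that it can separate direct
  from indirect coupling in recurrent circuits (a known limitation of
  pairwise methods).
* **Raw traces** render each spike as a 1 ms biphasic template — a
  negative half-sine carrying 2/3 of the peak-to-peak amplitude followed
  by a positive half-sine with 1/3 — in additive white Gaussian noise
  (default SD 10 µV; no wet-condition noise floor is published for these
  chips, so this is a free parameter). The negative-leading shape matches
  detection by negative threshold.
* **Pharmacology.** TTX wash-in thins spikes with survival probability
  exp(−(t−t₀)/τ), the first-order model of a perfusion-limited channel
  blocker; KCl steps multiply the instantaneous rate (m ≤ 1 thins; m > 1
  superimposes Poisson spikes at (m−1)× the unit's base rate).
* **LFP waves** sweep a negative Gaussian deflection (default 5 ms width,
  200 µV) across electrodes at a planted speed. Width matters: a 20 ms
  deflection has a peak flat enough that sample-level latency jitter
  biases the regression by several percent across a 540 µm electrode row.
* **ΔF/F movies** are per-pixel Gaussian noise with a square transient of
  a stated amplitude (in baseline-SD units) added to masked pixels one
  frame after the stimulus.

All randomness flows through one `numpy` generator per call, seeded from
the ground truth; identical seed + parameters give bit-identical output.

## Preprocessing and unit extraction

High-pass filtering is a zero-phase (forward–backward) 4th-order
Butterworth; cutoffs follow the per-preparation presets (10 Hz
cortico-hippocampal, 50 Hz cerebellum, 100 Hz prefrontal cortex). The
zero-phase choice avoids group-delay bias in propagation-speed estimates;
note a sine exactly at the cutoff is attenuated ≈ −6 dB (two −3 dB
passes). Activity thresholds ("mean firing rate higher than x Hz") are
strict inequalities; spikes inside 500 µs post-stimulus blanking windows
are excluded from all counts.

Detection registers a crossing below the (negative) threshold, times the
spike at the local minimum within 1 ms, and suppresses crossings within a
1 ms refractory period; snippets span −1/+2 ms around the minimum. These
windows are fixed here for reproducibility — the acquisition software's
internal detector parameters are not published.

Sorting is per electrode: snippets → top 3 principal components →
k-means for k = 1…4 → k chosen by the gap statistic (Tibshirani's
uniform-bounding-box references, B = 20 draws, one-standard-error rule
with the √(1+1/B) correction). Fewer than 10 snippets bypass clustering
(single unit); identical snippets short-circuit to k = 1. Unit ids are
ordered by decreasing spike count so output is invariant to snippet
order up to relabelling.

## Activity metrics

MFR = spikes/duration within an epoch. CV and CV2 need ≥ 3 spikes and
are reported as missing otherwise; CV2 uses the standard pairwise
definition (bounded in [0, 2]; an alternating-ISI train a,b gives exactly
2|a−b|/(a+b)). Bursts are maximal runs of consecutive ISIs ≤ 100 ms
containing ≥ 5 spikes; the boundary is inclusive with a 10⁻⁹ relative
tolerance so times constructed as decimal multiples sit inside the rule.
Intra-burst ISI regularity is the interquartile range of the pooled
intra-burst ISIs with linear-interpolation quantiles (bit-reproducible).

Drug time courses pool all units' spikes into bins anchored at the
application time, normalise by the mean rate over the preceding 60 s
baseline (baseline bins average to 1 by construction), and report
t₁₀/t₅₀/t₉₀ as the first post-application bin midpoint at or below the
criterion that stays below for 3 consecutive bins (a guard against bin
noise). The default bin is 10 s for plotting minutes-scale decays;
parameter-recovery analyses use 2 s bins, since the bin-midpoint
convention biases t₅₀ by up to half a bin (material for τ = 20 s).
With exponential thinning, τ is recovered as t₅₀/ln 2.

Percent changes are 100·(after−before)/before, rounded to the nearest
integer by default to match the reporting convention of condition
comparisons (76 → 111 µV is +46%; 0.02 → 1.9 bursts/min is +9400%).

LFP propagation speed regresses inter-electrode distance (from the
earliest-peaking electrode) on negative-peak latency after a 100 Hz
low-pass; identical latencies return infinity rather than a number.

## Connectivity

Cross-correlograms histogram t_target − t_source over [−30, +30) ms in
twenty 3 ms right-open bins; a zero difference falls in the [0, 3) ms
bin. The correlation value is the peak bin count divided by the
geometric mean of the two spike counts, clipped to [0, 1]: identical
trains give 1, and a planted connection with transfer probability p
between equal-rate trains gives ≈ p/√(1+p) when the lag jitter stays
within one bin.

Link calling tests each ordered pair against surrogates in which the
target train is jittered uniformly by ±50 ms (destroying millisecond
coincidences, preserving slow rate structure; at least ⌈1/α⌉−1
surrogates are required). Two choices go beyond the bare (1−α) surrogate
quantile and are both configurable:

1. **Direction by lag sign.** A link i→j is called only when the
   correlogram peak lies at positive lag. The window is symmetric
   precisely so the lag sign carries direction; without this rule every
   true link is mirrored by a reverse-lag call.
2. **Family-wise control.** The observed value must also exceed a
   Gaussian tail bound at level α/n_pairs fitted to the surrogate values.
   With 380 ordered pairs and only ~15 true links, a per-pair α = 0.05
   threshold would admit ≈ 18 chance links and cap precision near 0.45;
   the corrected threshold keeps the expected number of chance links per
   network near α while leaving planted links (whose values sit tens of
   surrogate SDs above the null) untouched.

The correlation index is links/units; condition comparisons subsample
100 correlation values without replacement (seeded) when matching the
statistical protocol of multi-phase recordings.

## VSDi

Trials sharing a stimulus frame are averaged pixelwise (noise SD drops
by √n_trials), then smoothed with a 3×3 spatial mean filter and a cubic
(3rd-order Savitzky–Golay, 5-frame) temporal filter — one concrete
reading of "cubic and spatial (3×3)" filtering; both steps are
switchable. A pixel responds when its ΔF/F strictly exceeds baseline
mean + 2.5 baseline SD in ≥ 2 consecutive frames within the
post-stimulus response window; the responding area of a region is
100·|responsive ∩ region|/|region|.

The response window defaults to 30 ms: granular-layer responses to mossy
fibre stimulation are millisecond-fast, and the window length controls
the chance of false runs in noise — with per-frame exceedance 1−Φ(2.5) ≈
0.0062, a 2-frame run in a 15-frame window occurs with probability
≈ 14·(0.0062)² ≈ 6×10⁻⁴ per pixel (below 10⁻³), whereas a 100 ms window
would exceed 10⁻³. Two practical notes: baseline statistics estimated
from short baselines inflate the exceedance tail (use ≥ 100 baseline
frames where possible), and exact-area mapping uses a 3-frame
persistence, since with 2 frames a chance run among ~500 null region
pixels arises in roughly a quarter of movies. Temporal smoothing
correlates adjacent frames and raises run probabilities substantially;
false-positive calibrations therefore apply the detector to unsmoothed
averages.

## Pipeline

Presets bind each preparation to its (high-pass cutoff, activity
threshold) pair: cerebellum (50 Hz, 0.5 Hz), cortico-hippocampal
(10 Hz, 0.1 Hz), prefrontal cortex (100 Hz, 0.1 Hz), spheroid
(—, 0.1 Hz), cortical organoid (—, 0.5 Hz), spinal organoid (—, 0.1 Hz).
A run writes the fully resolved YAML config, a SHA-256 config hash, a
structured JSON-lines log (stage, wall time, counts) and CSV/JSON/GraphML
outputs; fixed config + seed reproduces outputs byte-for-byte. The
default simulated scenario is a 16-unit, 4×4-electrode, 60 s recording —
sized so a full end-to-end run takes seconds while exercising every
stage; durations, grid and rates are config fields.

## Scope and limitations

The generator emulates renewal firing, planted bursts, pairwise lagged
coupling, step/exponential rate modulation and additive white noise. It
does not model bursting dynamics beyond planted runs, volume conduction
or electrode cross-talk, spike-waveform drift, non-stationary rates
outside pharmacology epochs, or correlated (shared) noise across
electrodes. Validation on these synthetics therefore demonstrates
algorithmic correctness and calibration — not robustness to waveform
drift, overlapping spikes on one electrode, or recurrent-network
confounds, which real recordings can present. Group-level inferential
statistics are deliberately out of scope beyond percent-change tables.
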