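# Methods note

Conventions and design choices of the `optoresp` analysis chain. Where a
published convention exists it is followed; where a procedure leaves
room, the choice made here is stated explicitly.

## Membrane-potential chain (`optoresp.ephys`)

**Filtering and centering.** Each trial is smoothed with a 250 ms
sliding **median** (robust to spikes). The window is centered and
shrinks at the trace edges rather than padding (implemented via
`pandas.rolling(..., center=True, min_periods=1)`); for even sample
windows the extra sample lies to the left. Each filtered trial is
centered by subtracting its own median.

**Thresholds.** The 10th and 90th percentiles of baseline activity are
taken over the 900 ms window starting 100 ms into the trial, pooled
across all filtered trials of a cell (per-trial percentiles averaged is
available as an option). Percentiles interpolate linearly between order
statistics.

**Classification.** The pointwise median of the filtered, centered
trials is evaluated in the 1 s window after stimulus onset. *Excited*:
at least 50 consecutive ms above the upper threshold; *inhibited*: the
mirror criterion. If both criteria are met, the label whose qualifying
run starts earlier wins; a tie goes to *excited*.

**Spike detection.** Spikes are found on the high-pass residual
(raw − median-filtered trace) as peaks with height ≥ k robust standard
deviations (1.4826 × MAD, default k = 6), a prominence floor of half
that, and a 2 ms refractory. A pure prominence criterion at the same k
fires on white noise at 20 kHz (peak-to-trough prominences in dense
noise routinely span ~4 σ), hence the height-based rule. Firing rates
are binned at 250 ms.

**AUC.** Trapezoidal areas over the 1 s windows before and after onset,
right endpoint included; ΔAUC = post − pre. AUCs are computed on the
median-centered median trace.

**Latency.** Per Savitzky–Golay window (400/200/100/50 ms, 4th-order
polynomial): filter each raw trial, center by its median, take the
pointwise trial median, recompute the 10/90 baseline percentiles on the
filtered traces, and record the first post-onset crossing of the upper
(excited) or lower (inhibited) threshold. The final latency averages the
per-window values; windows without a crossing are flagged and excluded,
and the latency is undefined if no window crosses. Note that this
estimator needs baseline variability with slow components: a purely
white baseline is annihilated by the filter, the recomputed percentiles
collapse toward zero, and the smeared leading edge of the response then
crosses arbitrarily early. The synthetic generator therefore offers an
Ornstein–Uhlenbeck drift term, and latency validation runs with it
enabled.

**Statistics.** Two-sided Wilcoxon signed-rank on paired pre/post AUCs
(zero differences dropped; all-zero comparisons return p = 1; exact null
distribution when available). Per-cluster tests require ≥ 5 cells. The
population effect coefficient is the mean post-stimulus AUC normalized
by the maximum AUC among excited cells; when no cell is excited the
normalizer falls back to the maximum |AUC| over all cells and the result
is flagged.

## Calcium chain (`optoresp.calcium`)

Frames are smoothed with a 2 px Gaussian (interpretable as σ or FWHM),
aligned by integer-pixel phase correlation against a 50-frame reference
from the first trial, and realigned with circular shifts (consistent
with the periodicity assumption of phase correlation). ΔF/F uses, per
trial and per pixel, the mean of the lowest 10 % of frames as F0. ROI
traces are label-mask means. Classification mirrors the ephys rule with
20th/80th percentiles over the 5 s windows before the first stimulus of
each trial, and a duration criterion of 25 % of the frames in the
window from stimulus onset to 5 s past offset. ΔAUC compares that
response window with the 5 s pre-window (an equal-window option
integrates matched durations). Spike-triggered ΔF/F averages snippets
from −0.5 s to +2 s around spike times; overlapping events are flagged.

## Connectome and expression

Edges with transmitter prediction scores < 0.62 are relabeled
*unknown* (a score exactly at threshold keeps its label); edges with
fewer than 5 synapses are dropped; duplicate (pre, post) edges are
collapsed by summing counts. Input profiles aggregate synapse totals and
partner counts per target and transmitter.

IPC transcriptomes are cells with nonzero Ilp2, Ilp3 **and** Ilp5
counts. Percent-expressing is 100 × (cells with nonzero count)/n, called
against 5 % and 10 % cutoffs (boundary inclusive). The 5 % cutoff over
16 IPCs corresponds to 0.8 expected cells; over 392 transcriptomes any
gene detected in fewer than ceil(0.05 × 392) = 20 cells is treated as a
false positive.

## Synthetic data (`optoresp.synthetic`)

Defaults mirror the recording conditions the chain was designed for:
10 trials of a 100 ms stimulus at 10 s intervals, 20 kHz sampling,
−40 mV baseline, 0.8 Hz spontaneous spiking (2 ms, ~30 mV biexponential
templates); responses are difference-of-exponentials with configurable
latency, amplitude and time constants; noise is white Gaussian plus
optional Ornstein–Uhlenbeck drift. Calcium sessions use a
double-exponential indicator kernel (rise 0.08 s, decay 0.6 s —
literature-typical GCaMP6m values, exposed as parameters), 0.8 Hz
spontaneous events at 0.1 ΔF/F each, and two 5 s pulses per 2 min trial;
stack mode renders Gaussian-blob ROIs over a background offset and
applies integer circular shifts. Synapse counts follow shifted Poisson
or geometric laws; expression matrices are Bernoulli-gated shifted
Poisson counts. All randomness derives from one root seed per session.

## Validation problem sizes

The sizes below are this package's own validation choices, picked to
keep the suite within desk-scale runtime on one CPU:

- Ephys label recovery: 200 cells (80 excited / 60 inhibited / 60
  zero-response) at 5 kHz sampling with 2.5 s stimulus-aligned windows;
  amplitude 8 mV = 5 × the 1.6 mV noise SD. Acceptance: ≥ 95 % overall
  agreement, ≥ 90 % specificity on zero-response cells, ΔAUC sign equal
  to injected polarity on correct responders.
- Latency: injected latencies 10–150 ms, 8 mV responses over 1 mV white
  noise plus 1 mV drift; |error| ≤ 20 ms and monotone.
- Oracle equivalence: every primitive against a brute-force
  reimplementation on ≥ 100 random instances (1e-9 relative tolerance).
- Calcium: exhaustive integer shifts |s| ≤ 5 recovered exactly on
  noise-free stacks; ΔF/F of constant input identically zero;
  ≥ 95 % label recovery on a 13-ROI, four-trial movie session with
  ±3 px per-frame motion.
- Spike-triggered ΔF/F: kernel peak within one frame and peak amplitude
  within 10 % on a sparse-spike session.
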