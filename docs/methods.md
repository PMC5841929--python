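# Methods

This note documents the analysis definitions, the synthetic-data model
behind the validation suite, the numerical choices, and the limits of
what the passing tests demonstrate.

## Session model and time base

A session is a run epoch (back-and-forth laps on a linear track)
followed or bracketed by rest epochs. All times are seconds from
session start as 64-bit floats; epochs are half-open `[start, end)`.
Position, spikes and LFP share this time base. Velocity thresholds are
applied from a single `VelocityTrace` everywhere: 2 cm/s for rate maps,
mean rates and PSD gating, 6 cm/s for spike-phase statistics.

## Behaviour

Tracking artifacts are samples whose arrival implies an instantaneous
speed above 150 cm/s (far above mouse running speed; the threshold is a
package choice, exposed in config). They are flagged and linearly
interpolated from valid neighbours. Positions are then smoothed with a
Gaussian kernel of SD 0.05 **seconds**; velocity is smoothed with a
Gaussian of SD 2.5 **samples**. The mixed units are deliberate — both
are exposed in `PipelineConfig` — because the two smoothing steps are
specified at different stages of the pipeline and a single convention
would silently change one of them.

Laps are traversals between the outer 10% end zones of the track (the
1D coordinate is the projection onto the principal axis of the cleaned
positions). An excursion that returns to its starting end zone is
discarded; brief mid-track reversals do not split a lap. Consecutive
laps therefore alternate direction by construction.

## Rate maps and place fields

Rate maps use 1 cm bins along the track axis, occupancy and spikes
restricted to speed ≥ 2 cm/s, and Gaussian smoothing with SD = 1 bin.
The default order is divide-then-smooth (rate = counts/occupancy per
bin, then smoothing of the rate with a normalised masked kernel);
smooth-then-divide is selectable (`smooth_mode`). Unvisited bins are
masked and excluded from all sums. The 170 × 10 cm track is collapsed
to 1D; the narrow dimension carries no tuning in this setting and no
implemented metric consumes it.

A place field is the maximal contiguous bin set containing the global
peak with rate above 20% of the peak. Place cells require field size
≥ 6 bins, mean run rate > 0.2 Hz, peak rate > 1.0 Hz, and positive
SNR, defined here as log₂(in-field / out-field rate) — positive iff
the field genuinely concentrates firing. The directionality index is
computed only when the main field's peak bin lies in the middle 80% of
the track, on direction-mean rates over left vs right laps.

## Complex spike index and bursts

Consecutive spike pairs with ISI ≤ 15 ms are eligible; a pair counts
positive when the ISI also respects the 3 ms refractory bound and the
second amplitude (on the channel with largest mean amplitude) is
smaller, negative otherwise. `CSI = 100·(pos − neg)` normalised by the
eligible pair count, which bounds it in [−100, 100] and puts the
pyramidal-cell threshold (CSI ≥ 5) on a percentage scale; the
unnormalised difference would grow without bound in spike count.

Bursts chain consecutive ISIs ≤ 10 ms transitively (spikes at 0, 6,
12 ms form one 3-spike burst); chains of length ≥ 2 are bursts. The ISI
histogram uses log-spaced bins, 1 ms–10 s at 50 bins per decade, and
the mode is the geometric centre of the maximal bin.

## Population vectors

The PV matrix stacks the left-direction rate curves of all place cells
above the right-direction curves (bins × cells, 2 × 170 rows at 1 cm).
Every pair of rows is correlated with Spearman's ρ; rows with missing
bins or zero variance across cells are masked. Same-direction profiles
pool the LL and RR quadrants by |Δbin|; opposite-direction profiles
keep the signed offset of the LR quadrant so an asymmetric (prospective)
peak shift remains visible. Per-distance comparisons between groups use
the two-sided rank-sum test on the pooled correlation entries.

## LFP, theta phase, phase locking

Decimation low-passes at half the target rate (8th-order Butterworth,
zero-phase) before taking every 20th sample: 32556 Hz → 1627.8 Hz. The
Welch PSD uses Hann windows of 2048 samples (1.26 s) with 50% overlap
and 4096-point FFTs (2.52 s); segments are kept when the speed at the
segment midpoint is ≥ 2 cm/s (the paper-level description does not fix
the bin-to-segment mapping; the midpoint rule is the package's choice).
Each PSD is divided by its own mean power over 1–3 Hz so curves are
comparable across electrodes and animals.

Theta phase is anchored at the extrema of the 6–12 Hz zero-phase
FIR-filtered trace: peaks 0°, troughs 180°, phase linear in time
between anchors. This waveform anchoring is insensitive to theta
asymmetry, unlike the raw Hilbert angle. The FIR length is chosen for
≥ 40 dB stopband at 3 and 20 Hz after forward-backward filtering.
Phase-locking statistics per unit: 36-bin (10°) firing-probability
histogram, circular mean (preferred phase), resultant length r,
Rayleigh p (standard refined approximation), KL divergence from the
uniform histogram in nats, and modulation index KL/ln 36 ∈ [0, 1]
(0 iff uniform, 1 iff single-bin). Significance is Rayleigh p < 0.05;
units with < 10 spikes above 6 cm/s are flagged low-n.

## Ripple detection

The rest-epoch LFP is band-passed 80–250 Hz with a 69-order
Kaiser-window FIR applied zero-phase; the envelope is |Hilbert|
smoothed with a 50 ms Gaussian *window* (kernel SD = 50/6 ≈ 8.3 ms,
configurable). Envelope mean and SD come from the whole rest epoch
(events included — the estimate is not iterated). An event is a maximal
above-mean excursion that reaches mean + 3 SD and lasts > 30 ms; its
edges are the return-to-mean crossings, which also serve as the
reported duration (the above-threshold core time is stored alongside).
Applying the 30 ms test to the mean-to-mean span rather than to the
above-threshold core matters: the smoothed envelope of an 80 ms
Hanning-windowed event at 6 SD spends only ~27 ms above the 3 SD level
because the Hanning top is narrow, so a core-duration rule would reject
textbook events; the span rule keeps the detector's recall on injected
5–6 SD events at ≥ 0.95 while leaving pure-noise false positives rare.
Events at a higher threshold are a strict subset of those at a lower
one, giving monotone nesting across the 2/3/6 SD sweep.

MUA gating: the summed spike train of all units in 1 ms bins, Gaussian
smoothed (SD 5 ms), thresholded with the same mean + 3 SD rule — but
with the 30 ms minimum applied to the above-threshold core, because the
population rate has a near-zero rest mean and the above-mean excursion
of a single stray spike already spans ~40 ms of smoothing kernel.
Candidates not overlapping an MUA burst are discarded. The MUA-only
variant uses those bursts directly as events.

Per-event peak frequency: the band-passed event segment is multiplied
by a Hanning window of its length, then a 3-taper multitaper spectrum
(DPSS, time-bandwidth 2, ≥ 4096-point FFT) is averaged and its 80–250 Hz
peak taken. Event amplitude is reported both in SD units above the
envelope mean (comparable across animals) and in raw units.

## Group statistics

Unit-level metrics (rates, SI, sparsity, DI, CSI, burst and ISI
statistics, resultant length, modulation index, ripple participation)
are compared with the two-sided Mann-Whitney U test, exact when both
groups have ≤ 20 untied values. Proportions use Pearson's chi-square on
the 2 × 2 table with 1 d.f. and no continuity correction — with the
published counts 121/256 vs 115/259 this reproduces χ² ≈ 0.43,
p = 0.514. Animal-level ripple summaries use one-way ANOVA. SEM is
SD/√n at the aggregation level used. No multiple-testing correction is
applied, and the report notes this.

## Synthetic sessions

The generator reproduces the statistical structure the analyses assume,
not biophysics. Defaults describe a 170 × 10 cm track, 10 laps at
15 cm/s with 0.5 s end pauses, tracked at 30 Hz with 0.2 cm noise
(typical diode tracking), and a 120 s rest epoch.

Spiking: each unit has a Gaussian place tuning (default width 8 cm,
peak 8 Hz, evenly spaced centres), a direction gain (0.3 off the
preferred direction — clearly directional but not silent), a 0.5 Hz
baseline, and multiplicative von Mises theta modulation
(`exp(κ cos(θ−µ))/I₀(κ)`, unit mean over phase; default κ = 1,
µ = 180°) applied to the whole run-epoch rate. Spikes are drawn by
1 kHz Bernoulli thinning. Each primary event becomes a burst with
probability 0.35 (sizes 2–5 with probabilities .5/.3/.15/.05,
intra-burst ISIs uniform 3–8 ms); amplitudes attenuate by 0.8 per
successive spike with 5% jitter. The primary-event rate is divided by
the expected burst multiplicity so the *emitted* rate matches the
stated tuning. A 2 ms per-unit dead time is enforced on the final
train — without it, overlapping bursts and injected ripple spikes
produce refractory violations no properly sorted unit would show, and
every unit would fail QC. Feature vectors are 8-dimensional Gaussians
per unit (two per tetrode channel); amplitudes use a per-unit
4-channel template with one dominant channel.

LFP: 1/f noise (exponent 1, unit SD) over the whole session, plus a
theta cosine during run whose amplitude (2 broadband SDs) yields an
unambiguous 6–12 Hz PSD peak. Ground-truth spike phase is defined on
the same oscillator, so waveform-anchored phase estimation can be
scored against it.

Ripples: `round(rate × rest/60)` Hanning-windowed sinusoid packets
(default 150 Hz, 80 ms, 10/min) at uniformly random non-overlapping
rest times (bounded retries, then error). Amplitude is calibrated so
the *smoothed envelope peak* sits `ripple_amp_sd` SDs above the
envelope mean — the quantity the detector measures — and the band
background is attenuated under the packet taper, since a ripple
dominates the 80–250 Hz band rather than superposing on an independent
background of comparable power (without the replacement, nominal 6 SD
packets measure anywhere from ~3 to ~10 SD through phase interference).
Each packet comes with a coincident MUA burst (600 Hz summed rate,
envelope-shaped, spread over the units). Detected amplitudes of nominal
6 SD packets measure ≈ 5.6 SD because the detection-side SD includes
the injected events; this is the detector's honest behaviour, not a
calibration error.

Determinism: a single `numpy` generator seeded from `SynthConfig.seed`
drives everything; identical configs produce byte-identical session
files.

## Validation design and problem sizes

Parameter-recovery suites isolate the estimator under test. Field
recovery runs 20 seeds of 10-lap sessions with two units of known
tuning (centre 85 cm, SD 5 cm, peak 10 Hz) and bursts disabled; with
bursts enabled, spike clustering inflates the finite-data map *peak*
(a max statistic) by roughly +19% at 10 laps and thereby narrows the
measured 20%-of-peak width by ~2 bins — a real estimator-bias
interaction worth knowing about when interpreting peak rates from short
sessions. Phase recovery pools ~1500 spikes per session across 20-unit,
6-lap sessions (bursts disabled for the same reason); ripple recovery
uses 20 seeds of 60 s rest epochs with 10 injected events each.
Calibration suites use 10⁴ null replicates. The two-group contrast uses
5 synthetic animals per group (10 units, 4 laps, 300 s rest — about 50
ripple events per animal, so per-animal summary sampling error sits
well below the injected differences, as in the long rest recordings
this emulates), the deficit group generated with burst probability
0.35 → 0.10 and ripple amplitude/duration 6 SD → 4 SD and 80 → 55 ms;
burst metrics are compared unit-level (Mann-Whitney), ripple summaries
animal-level (ANOVA). These sizes keep the full suite and the
acceptance script at well under a minute each while leaving comfortable
statistical margins.

## Limitations

- The generator's trajectory is near-deterministic (constant speed,
  small noise); occupancy is close to uniform, so rate-map behaviour
  under strongly non-uniform occupancy is exercised only by the
  velocity-gating tests.
- Injected ripples have no internal sequence content, and rest-epoch
  spiking is homogeneous Poisson outside the injected bursts; replay
  analyses are out of scope.
- Passing recovery tests shows the estimators are correct under the
  generative model's assumptions (Gaussian tunings, von Mises phase
  preference, Hanning ripple envelopes); real data violate all of these
  to some degree, and the tolerances here do not bound those effects.
- Theta-phase estimation anchors on filtered-trace extrema; with very
  low theta signal-to-noise the anchor jitter deflates resultant
  lengths slightly (the von Mises recovery tolerance absorbs this).
- The isolation-distance noise set is all non-cluster spikes of the
  same tetrode; other conventions (e.g. amplitude-thresholded noise)
  would shift absolute values.
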