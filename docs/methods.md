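# Methods

`drowsekit` implements an offline pipeline for validating video-based
drowsiness scoring against concurrent EEG in simulated driving sessions.
This note records the model, the parameter choices, the numerical details
and the known limitations.

## Visual scoring

**Eye aspect ratio.** For six eye landmarks P1..P6 (P1/P4 the horizontal
corners, P2/P6 and P3/P5 the vertical pairs),

    EAR = (|P2 − P6| + |P3 − P5|) / (2 |P1 − P4|).

EAR is dimensionless and invariant to translation, rotation and uniform
scaling of the landmark set. When both eyes are supplied the two EARs are
averaged. Landmark localization itself (face detection, 68-point models) is
out of scope; the package consumes landmark coordinates or ready EAR traces.

**Adaptive threshold.** A fixed EAR cut-off (0.16–0.28 across the
literature) transfers poorly between subjects and lighting conditions.  The
detector instead subtracts a constant offset (default 0.04 EAR units) from
a smoothed baseline of the trace itself — a median filter of length 17
frames followed by a moving average of length 5 (defaults; ~0.57 s and
~0.17 s at 30 fps). Both filters use truncated (shrinking) windows at the
session edges so no data is fabricated; for even moving-average lengths the
extra sample is taken from the past. The *raw* EAR is compared against the
threshold: the 17-frame median would erase ordinary 100–400 ms blinks from
the smoothed signal, so the smoothed signal can only act as a slow baseline
tracker.

**Frozen baseline (default detector).** The plain composition
`MA(median(EAR)) − offset` has a structural flaw for drowsiness work: during
a closure longer than about half the median window the baseline itself
descends to the closed-eye level and the comparison turns false ~0.3 s into
the closure. Closures of ≥ 2 s — the very events that define drowsiness —
would be invisible. The default detector therefore updates the baseline
only from frames classified open: a trailing median (17) and trailing
moving average (5) run over *held* values in which each closed frame
repeats the last open sample. Each frame is classified against the
threshold derived from the frames before it, so the rule is causal and
usable on a live stream. The literal centered composition remains available
as `baseline="tracking"` (appropriate for blink-rate work), and a fixed
threshold (default 0.2) is provided for comparison.

Maximal closed runs of at least `min_blink_frames` (default 2 frames,
~67 ms — rejects single-frame noise; no minimum is standard in the
literature, this is a package choice) become blink/closure events.

## Episode scoring

Two oculometric measures are derived per frame:

* **PERCLOS** — fraction of closed frames in a trailing 60 s window
  (the regulatory "percentage of eye closure within a minute"). The
  denominator is always the nominal window length; before a full window has
  elapsed the unseen frames count as open. Normalizing by the truncated
  length instead would let a single ordinary blink in the opening seconds
  of a session cross the drowsiness threshold.
* **CLOSDUR** — seconds of ongoing closure, resetting on any open frame.

A frame is drowsy when PERCLOS ≥ 0.3 or it belongs to a closure run whose
eventual length reaches 2 s; the closure rule is applied retroactively from
the run's first frame (offline scoring; one closure is never split across
two episodes). Maximal same-flag runs tile the session into alternating
wake/drowsy episodes; runs shorter than `min_episode` (default 0 s = off)
are merged into the preceding episode. Raising either threshold can only
shrink total drowsy time (monotonicity, covered by tests). A session whose
first frames are drowsy simply begins with a drowsy episode — no empty wake
stub is inserted.

A known consequence of the trailing window: after a long closure PERCLOS
decays over up to ~40 s, so a detected drowsy episode can extend into the
following wake segment. This is inherent to per-frame trailing-window
scoring and is visible in the simulator-recovery tests.

## EEG preprocessing

Equiripple (Parks–McClellan) FIR filters of order 25: high-pass with cutoff
1 Hz (transition 1 Hz) against slow ocular drift, low-pass with cutoff
30 Hz (transition 10 Hz) against EMG. Both are applied forward–backward by
default (zero phase — episode boundaries are not delayed; attenuation
doubles); a causal single-pass mode exists. Numerical details:

* a high-pass needs an odd tap count (an even-length symmetric FIR has zero
  gain at Nyquist), so 26 taps are bumped to 27;
* at this order a 1 Hz transition cannot produce both a flat passband and
  deep low-frequency rejection; the designs weight passband flatness
  (stop:pass weights 1:20 for the high-pass, 10:1 pass:stop for the
  low-pass), giving a passband flat to a few percent, ~48 dB at 50 Hz after
  the double pass, and only *relative* DC attenuation (DC gain ≈ 0.9 of
  passband). The contract tested is exactly that: passband within 10 %,
  50 Hz ≥ 20 dB down, DC strictly below passband.

## Band decomposition and features

Episodes are cut from the filtered EEG at `round(t × fs)` sample indices
(adjacent episodes share the boundary sample index, so segments partition
the recording). A configurable constant offset reconciles the video and EEG
clocks; recordings in this montage nominally start together.

**Bands.** delta 1–4, theta 4–7.5, alpha 7.5–15, beta 15–30 Hz.

**Band power** (default path): Welch PSD — Hann windows of
`min(episode, 2 s)`, 50 % overlap — integrated over the band edges by the
trapezoidal rule.

**DWT path** (config-selectable): the segment is polyphase-resampled to
60 Hz and decomposed with a db2 level-3 discrete wavelet transform using
periodized boundaries, which keeps the transform orthogonal (perfect
reconstruction and exact Parseval energy balance, both tested at 1e-8;
segment lengths are trimmed to a multiple of 2³ for exactness). At 60 Hz
the dyadic subbands land on 15–30 (D1→beta), 7.5–15 (D2→alpha), 3.75–7.5
(D3→theta) and 0–3.75 Hz (A3→delta) — matching the physiological edges up
to the 3.75-vs-4 Hz approximation. At the native 200 Hz no level-3 dyadic
split can match these bands, which is why the resample step exists. Band
power is then the mean square of the subband reconstruction. db2's
four-tap filters leak between neighboring octaves: a 10 Hz tone at 60 Hz
sampling puts 71 % of its energy in D2 (dominant, but far from all); the
Welch path is the default for this reason.

**Ten features per (episode, channel):** the three band powers
(delta/theta/alpha), their ratios (theta/alpha, delta/alpha, delta/theta),
and four spectral-shape features computed from the Welch PSD restricted to
the 1–30 Hz passband:

* spectral entropy `H = −Σ n_f log2 n_f` with `n_f` the normalized PSD —
  in bits, not normalized by `log2 L`, zero-power bins contribute nothing;
* spectral centroid `C = Σ f_k X_k / Σ X_k` (Hz);
* spectral spread `S = sqrt(Σ (f_k − C)² X_k / Σ X_k)` (Hz);
* spectral rolloff: the frequency of the lowest bin whose cumulative weight
  reaches C × total (C default 0.9); monotone in C.

The weights `X_k` are PSD values by default ("power"); square-root
("magnitude") weighting is selectable. Because the bins are uniform, a
centroid in Hz differs from one in bin index only by a positive affine map,
so all episode comparisons are invariant to that choice. Episodes shorter
than 1 s (configurable) yield NaN feature rows — flagged, never dropped
silently or imputed.

## Agreement criteria and sensitivity

Each feature has an expected direction of change with drowsiness: ratios,
theta/delta power and spread increase; alpha power, entropy, centroid and
rolloff decrease. A drowsy episode *i* agrees with a feature on a channel
when its value is strictly beyond *both* wake neighbors *i−1*, *i+1* (the
single available neighbor decides at session boundaries — boundary episodes
are not excluded). Wake episodes have no published rule; the mirrored form
is used: wake *j* agrees when its value lies on the wake side of every
adjacent drowsy episode. Both rules extend to channel sets by union (agree
on ≥ 1 member), so adding channels can never remove agreement.

Under a null model with i.i.d. *continuous* feature values, an interior
drowsy episode satisfies its criterion with probability exactly 1/3 (the
middle of three exchangeable values is the extreme one time in three).
This holds empirically for nine of the ten features in a zero-effect
simulation. The exception is spectral rolloff: it is bin-valued (0.5 Hz
resolution at 2 s Welch segments), neighboring episodes tie with
appreciable probability, and the strict inequality then fails, depressing
the null pass rate to ≈ 0.30. This is a property of the bin-valued rolloff
definition, not of the criterion logic; making rolloff continuous would
change its printed identities (e.g. flat 10-bin spectrum → 9 Hz).

Sensitivities are percentages over *all* episodes (wake and drowsy):
`sensitivity(channel) = 100 × agreeing/total`, and for channel sets
`combine = 100 × (1 − missed-by-union/total)`, which is monotone in the
set. Regions are the montage pairs frontal F3/F4, central C3/C4, occipital
O1/O2; cross-subject aggregation is the arithmetic mean, reported to one
decimal with raw values retained. Across subjects, Spearman's rank
correlation (tie-corrected, two-sided t-approximation p) relates the number
of scored episodes to the number of agreeing episodes per subject. A
subject missing a feature contributes an explicit NaN gap to the report.

## The session generator

The simulator emulates the acquisition this pipeline is built for: 50-minute
sessions, 30 fps video EAR, 200 Hz six-channel EEG. Defaults: wake segments
60–180 s and drowsy segments 20–90 s (uniform), sessions start awake; wake
blinks are Poisson at 12/min with 100–300 ms durations; drowsy segments
contain either repeated 2–6 s closures tuned to a closure fraction of 0.4,
or one continuous closure spanning the segment (microsleep; used by the
strong-effect preset); open/closed EAR levels 0.32/0.05 with Gaussian noise
(σ = 0.01) and ~2-frame lid transitions.

EEG channels are sums of four band-limited Gaussian components plus
broadband noise (σ = 2 µV). Each component is white noise band-passed
(4th-order Butterworth) into its band and *measured-and-rescaled* — its
in-band Welch power is normalized to 1 — so configured band-power targets
are met by construction rather than trusted to filter gains (calibration is
verified to 15 % by the feature extractor in tests). Wake targets are
delta/theta/alpha/beta = 20/10/20/5 µV²; the moderate drowsy default is
30/16/14/5; the strong-effect preset doubles delta and theta and halves
alpha. A per-channel gain scales the wake→drowsy excursion,
`p_wake + gain × (p_drowsy − p_wake)`; the default gains (F4 = 1.0,
F3 = 0.45, O2 = 0.3, O1 = 0.2, C4 = 0.15, C3 = 0.12) encode the frontal
dominance and weak central involvement reported for theta–alpha changes in
driver-drowsiness EEG, and are deliberately spread out so that single-channel
sensitivities separate instead of saturating. Every session is a
deterministic function of its seed; independent sub-streams drive the
schedule, the EAR noise and each (channel, band) component.

What the generator does **not** emulate: 1/f background spectra, ocular or
EMG artifacts in the EEG, non-stationarity within a state, imperfect
landmark tracking, or drowsiness with open eyes. Passing tests therefore
demonstrate the pipeline's internal consistency and statistical behavior
under controlled conditions, not clinical performance.

## Problem sizes in the test and acceptance runs

Simulation-based checks use scaled sessions chosen to exercise the same
statistics at manageable size: the null run uses 2000 interior drowsy
episodes of 4 s in a zero-effect session (standard error of the 1/3 rate
≈ 0.011); the strong-effect cohort uses three subjects with 200 scheduled
episodes each (wake 20 s / drowsy 6 s — short enough that per-episode
spectral estimates carry realistic noise, long enough for 2 s Welch
windows); the acceptance script runs five subjects of 5000 s with random
wake 25–40 s / drowsy 5–8 s schedules. Episode duty cycles are kept below
~25 % so that trailing-window PERCLOS does not saturate across neighboring
drowsy segments.

## Known limitations

* Order-25 equiripple filtering leaves sub-1 Hz content attenuated only
  relatively; slow drift is reduced, not removed.
* The adaptive detector requires a stable open-eye baseline; systematic
  baseline drift faster than the median window will shift detections.
* Episode boundaries from trailing-window PERCLOS lag state changes (see
  above); boundary-sensitive applications should rely on the CLOSDUR rule
  or post-hoc alignment.
* The discrete rolloff statistic ties between similar episodes; its
  strict-inequality criterion is conservative as a result.
* Spearman association across subjects needs at least three subjects and
  non-constant counts on both sides.
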