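# Methods

## Signal model

Every epoch of EEG is modelled as the sum of spontaneous background activity
and stimulus-evoked components:

```
EEG_n(t) = EEG_s_n(t) + EEG_e_n(t),      n = 1..N trials
```

The background averages towards zero across trials (variance of the N-trial
mean is var/N for independent epochs), while evoked components are time- and
phase-locked and survive averaging.  Go and Nogo stimuli share the
components evoked by physical and elemental stimulus attributes; Go stimuli
additionally evoke informational components.  With balanced designs
(N Go = M Nogo trials, the default), the difference of condition averages

```
IRP(t) = ERP_go(t) − ERP_nogo(t)
```

cancels the shared components exactly and estimates the informational
contribution with residual noise of order `σ·√(1/N + 1/M)`.

## Synthetic sessions

**Components** are Gabor atoms: `a · exp(−(t−c)²/2w²) · cos(2πf(t−c))`
with centre `c = latency + region_lag`, scaled per channel by its region's
gain.  Rendering refuses templates whose ±3w envelope leaves the epoch.
The visual preset injects an IN400/IP400 pair (4 Hz, w = 100 ms, ±4 µV;
negative in FL/PL/OL, positive in FR) in Go trials only, on top of three
shared components (P1/N1/P2-like, 4–8 Hz, 4–6 µV).  The auditory preset
injects IN750/IP750 (3 Hz, w = 70 ms; negative frontal, positive
parietal/right-temporal).  Inter-region latency offsets of 12–24 ms model
transmission delays (occipital leads for visual, temporal for auditory
sessions).

**Background** is Gaussian noise shaped to `1/f^α` amplitude (α = 1) with
an optional 10 Hz (alpha) bump, per-channel RMS `background_level`.  Each
channel mixes an independent part with a part shared across its region
(fraction 0.5), giving the block spatial covariance that CSP and PDC need.
The default level of 2.5 µV RMS equals roughly 1× the informational
component's RMS — the single-trial signal-to-background ratio under which
the recovery properties below are stated.

**Timing/behavior.**  One latency jitter per trial (Gaussian, SD 10 ms
by default) shifts all of that trial's components; jitter affects latency
only, preserving phase-locking approximately.  Trial-to-trial latency
variability is not reported for such experiments; the value is an exposed
parameter.  RTs are lognormal with condition-specific mean/SD
(visual: 0.91/0.69 s Go/Nogo; auditory: 1.57/1.29 s); correctness is
Bernoulli (visual: 94.56 %/98.23 %; auditory: 93.33 %/99.16 %).  RT SDs
(0.12–0.20 s) are the package's choice — only means are published.

**What the generator does not emulate:** ocular/muscular artifacts (the
ICA stage is therefore a pass-through hook), volume-conducted continuous
mixing between regions, nonstationary background statistics, and
between-subject variability beyond the seed.  Passing recovery tests on
these sessions therefore shows correctness of the estimators under the
additive model, not performance on real recordings; in particular,
single-trial decoding saturates near 1.0 here whereas real sessions of
this kind peak near 0.8.

**Auditory epochs.**  Time zero of an auditory session is the onset of the
critical (second) element.  Epochs run to 1.0 s post-event rather than
0.8 s: a 750 ms component and the 650–900 ms network window cannot fit in
a −200..800 ms epoch.  The visual preset keeps −200..800 ms.

## Preprocessing

Fixed order: polyphase resampling (default 1000 → 250 Hz, events re-indexed
to the nearest sample) → average reference → zero-phase FIR band-pass
(1–45 Hz, Hamming design, ~1 Hz transition bands, linear phase applied by
FFT convolution with the group delay compensated exactly) → epoching over
the half-open window [−0.2 s, post) with per-channel subtraction of the
pre-stimulus mean → behavioral rejection (incorrect response or RT above
the cutoff; mask only, data untouched) → arithmetic region pooling in the
fixed order FL, FR, PL, PR, TL, TR, OL, OR.  RT cutoffs default to 1.5 s
(visual) and 3.0 s (auditory — the auditory Go mean RT of 1.57 s makes a
1.5 s cutoff unusable).  Events too close to the recording edge are
flagged, never silently dropped.

## Decoding

Per 200 ms window (100 ms shift, starts from −0.2 s so pre-stimulus
windows exist): band-pass 1–6 Hz (Butterworth order 4, forward–backward,
hence zero-phase), select the modality's channels (24 frontal/parietal/
occipital channels for visual, 22 frontal/parietal/temporal for auditory;
first k of each region in montage order), delay-embed with τ = 12 ms
(3 samples at 250 Hz, zero-padded at the window start), fit CSP on the
training folds only, take log-variances of the 2×3 selected projections,
classify with a linear SVM (C = 1 — the classifier family is standard, the
constant is the package's fixed choice), stratified 5-fold CV.

CSP details: per-trial covariances are trace-normalized before averaging
(standard practice; trials with zero trace are skipped); filters are the
generalized eigenvectors of `(Σ_a, Σ_a + Σ_b)`, so eigenvalues lie in
[0, 1] and the filters whiten the composite covariance.  A rank-deficient
composite receives a diagonal ridge of `1e−6 × trace/dim` with a warning.
Log-variances are floored at 1e−20 so constant projections stay finite.

## Networks

Region-level MVAR models are fitted by least squares pooled across trials
(per-trial mean removed; model order by an Akaike-style criterion over
1..10 when unset).  Stability (companion spectral radius < 1) is flagged,
not silently accepted.  Partial directed coherence uses the original
column-normalized convention, so `Σ_i pdc(i,j,f)² = 1` per source and
frequency; the diagonal is kept in the tensor and excluded at thresholding.
Summaries average PDC over 1–6 Hz (the IRP band).  Analysis windows:
350–600 ms (visual), 650–900 ms (auditory), or sliding 200/100 ms.

Graphs keep the top `round(q·56)` directed edges (default q = 0.3, i.e. 17
edges on 8 nodes); fixing density rather than an absolute cutoff keeps the
density-sensitive clustering coefficient comparable across conditions.
Clustering uses Fagiolo's all-motif directed definition on the binarized
graph by default (nodes with < 2 neighbours get 0); the symmetrized
Watts–Strogatz coefficient and Fagiolo's weighted form are options, since
published group tables do not state which variant they use.  Group
comparison: per region, two-sided paired t-test plus Cohen's d in the
pooled-SD form — that form reproduces the published visual-experiment
effect sizes exactly from their printed means ± SDs, which is why it is
the package default.  Note that with average-referenced data and
phase-locked evoked components shared across regions, off-diagonal PDC is
substantial even without genuine coupling; condition contrasts, not raw
PDC magnitudes, are the meaningful quantity.

## Numerical and design choices

- Epoch windows are half-open with nearest-sample event rounding, so
  sample counts are unambiguous (1.0 s epoch = 250 samples at 250 Hz).
- Component detection reports the polarity-specific extremum per search
  window (defaults: 0.35–0.45 s, 0.50–0.62 s, 0.70–0.80 s) and flags it
  present when |amplitude| exceeds k = 3 baseline-period SDs — a
  threshold heuristic, not a formal test; no cross-electrode statistics
  are attempted.
- Morlet maps use 3 cycles by default: inside a one-second epoch the
  1–6 Hz band needs short wavelets, trading frequency resolution for
  temporal localization; signals are zero-padded so the longest wavelet
  fits, and the pad is cropped from the output.
- Proportional thresholding breaks ties deterministically (by weight,
  then row/column index).
- The pipeline expands its global seed via `SeedSequence.spawn` into one
  child per simulated subject plus one for fold shuffling; a run is
  bit-reproducible from (config, seed) and its report lists every output
  file with a SHA-256 checksum.
- Tests and the acceptance script simulate at 250 Hz directly (the
  analysis rate) with 20-session / 20-subject batches — study-scale sizes
  chosen for desk-scale runtimes; resampling is validated separately on
  1000 Hz signals.

## Known limitations

Sessions are stationary, artifact-free and share one template set, so
absolute decoding accuracies and PDC magnitudes are not comparable to real
recordings; only the estimators' correctness properties (exact noiseless
recovery, chance-level calibration, oracle equalities, 1/N averaging) and
the qualitative structure (component topography/latency, accuracy-peak
timing) transfer.  EDF export is not provided; recordings serialize to a
documented directory layout (raw array + JSON sidecar + behavior CSV).
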