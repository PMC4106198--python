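# Methods notes

This note records the modelling assumptions, parameter choices and
numerical conventions behind `spectrodict`, including the places where
the published pipeline the package follows leaves details open and a
choice had to be made.

## Front end

Audio is downmixed to mono by channel averaging and polyphase-resampled
to 44.1 kHz. Mel spectrograms use non-overlapping 1024-sample Hamming
frames (frame period ≈ 23.2 ms; the trailing partial frame is
discarded, so the frame count is exactly ⌊N/1024⌋), mapped through a
40-band Slaney-style triangular, area-normalised mel filterbank whose
lower edge is 500 Hz — the low-frequency cutoff is implemented in the
filterbank, not by zeroing STFT bins. The whole matrix is divided by
one scalar so its RMS is 1; this happens before optional noise
reduction. Magnitudes are kept linear by default; a `log_mel` config
flag applies log compression before feature learning for
experimentation, since the convention the learned-feature path should
follow is genuinely ambiguous.

MFCCs log-compress (floor 1e-10), apply an orthonormal DCT-II across
bands and keep coefficients c0–c12 (c0 retained so the count is 13).
Deltas are symmetric first differences with edge replication, giving
26 dimensions total. Because of the RMS normalisation, MFCCs are exactly
invariant to global gain.

Noise reduction subtracts the per-band median over time (median of an
even count = mean of the central pair) and clips at zero, one profile
per recording. It assumes stationary background noise; it does nothing
useful against fluctuating noise, by construction.

## Dictionary learning

Patches are Δ consecutive frames stacked into one vector (Δ·40 dims).
Each patch is mean-subtracted and divided by its Euclidean norm
(switchable), then PCA-whitened; whitening eigenvalues are floored at
ε = 1e-8, which also absorbs the one exactly-degenerate direction the
per-patch mean subtraction creates. Whitening is eigendecomposition
based and fitted only on the reservoir sample.

The online spherical k-means update assigns a unit-normalised patch to
the centroid with smallest cosine distance (ties to the lowest index)
and applies a count-weighted step, `c ← normalise(c + x̂/(n+1))` — the
minimal adaptation of count-weighted online (Hartigan-style) k-means to
the unit sphere. Centroids are initialised from k distinct patches of
the shuffled reservoir sample. Training is two streamed passes:
reservoir sample (default capacity 100,000 patches, algorithm R) +
shuffle + whitening fit + online pass over the sample, then an online
pass over every patch with tallies carried over (carry-over and the
weight schedule are config hooks, as the exact published behaviour is
unspecified). Zero-norm patches are skipped and tallied. Rarely-updated
centroids are kept, not re-seeded; the per-basis update counts are
exposed so dead bases are observable.

Projections are signed dot products of whitened patches with every
basis (no rectification). The two-layer variant fits on Δ=4 patches,
projects, max-pools by 8 along time (trailing partial block pooled
as-is), and fits a second Δ=4 dictionary on the pooled sequence (patch
dimension 4k); classification uses the layer-2 sequence.

Two properties worth noting for interpretation of the tests:

* Direction-recovery experiments run with whitening disabled
  (`whiten=False`): on data generated as rays through the origin, the
  whitening mean-offset deliberately destroys the ray structure, so
  recovery of planted directions is a property of the spherical k-means
  learner, not of the whitened pipeline.
* Both the online trainer and a batch (Lloyd-style) spherical k-means
  are local optimisers. From a shared data-seeded initialisation they
  almost always converge to objectives within a few tenths of a percent
  of each other, but occasionally the batch iteration escapes a local
  optimum the diminishing-step online rule cannot leave. Agreement is
  therefore asserted on the median over several instances rather than
  per instance.

## Summarisation

`mean_std` uses the population standard deviation (ddof 0). The
modulation summary takes one full-length FFT per feature dimension
along time (a single transform keeps the output length independent of
duration, which the fixed dimensionalities require), divides magnitudes
by the frame count so long recordings do not dominate, and averages
them into 10 equal-width bins from 0 to the frame-rate Nyquist; bins
containing no FFT frequency are zero. Learned-feature configurations
use only `mean_std`.

## Classification and evaluation

The classifier contract is fixed: 200 trees, entropy criterion,
library defaults otherwise. Multilabel mode is one multi-output forest;
binary relevance trains one forest per species, with a constant score
of 0 (and a warning) for a class with no positive training examples.
Decision windows are cut on the feature-frame axis (seconds converted
via the frame period), non-overlapping, with partial trailing windows
kept down to one frame; each window inherits its recording's full label
set, and per-window scores are pooled per recording by mean or max. All
windows of a recording stay in the same crossvalidation fold, so
windowing can never leak test audio into training.

AUC is the Mann-Whitney statistic (average ranks; ties count half).
The per-run headline is the mean over folds of the micro-average over
all (item, class) cells; a macro variant (mean of per-class AUCs over
classes with both labels present) and pooled-over-folds variants are
computed and stored alongside, since the published aggregation is not
pinned down. MAP is the mean over items of the average precision of
the item's species ranking, ties broken by class index; items with no
true labels are excluded with a warning. Feature learning runs inside
each fold on training audio only.

## Synthetic data

The generator emulates the structure the pipeline assumes rather than
any real species: a species is 2–4 syllable templates (tone, up-chirp,
down-chirp, harmonic stack; centre frequencies log-uniform between
1 kHz and a third of Nyquist, durations 80–250 ms, sweep rates
1–4 kHz/s) repeated as a Poisson process, placed in pink or white noise.
Defaults: short single-label clips are 3 s at 20 dB SNR with a random
two-fold split that keeps every species in both folds; dawn-chorus
recordings are 20 s at 10 dB SNR with 2–4 species each and a by-"recordist"
three-fold split. Annotations equal exactly the set of species with at
least one placed event, and everything is reproducible from the seed.

What the generator does *not* emulate: reverberation, microphone and
recordist idiosyncrasies, diurnal amplitude drift, species similarity
structure, or label noise. Passing tests therefore demonstrate the
correctness and end-to-end behaviour of the pipeline, not field-level
recognition accuracy; the relative merits of feature types at desk
scale (tens of clips) also invert the large-data picture, because a
500-basis dictionary is over-parameterised for a few thousand patches.

The end-to-end experiment in the test suite uses five species and fifty
10-second clips under two-fold crossvalidation. Ten seconds (typical of
field recordings of song bouts) rather than the 3 s clip default is used
there so that the two-layer configuration — which consumes 8× temporally
pooled sequences — still has at least k = 500 layer-2 patches per
training fold.

## Known limitations

* WAV input only; FLAC would need an audio codec dependency.
* The modulation summary's length normalisation is this package's
  choice; other implementations may normalise differently, changing
  absolute (not relative) magnitudes.
* Binary-relevance training cost grows linearly in the species count.
* The pipeline cache keys on configuration fingerprints, not on file
  contents; editing a dataset in place without changing its path
  requires clearing the cache.
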