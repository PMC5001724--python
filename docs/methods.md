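# Methods

This note documents the models implemented in `coopaffect`, the choices
made where the design was genuinely open, and the limits of what the
synthetic testbed demonstrates.

## Concordance

`metrics.ccc_value` implements Lin's concordance coefficient with
*population* moments (divide by n).  The convention matters only when
variances do not scale together; population moments were chosen so the
windowed estimator is the plain plug-in of the window moments.  Degenerate
windows are resolved deliberately: two constant series with equal means
score 1, any other constant case scores 0 (a flat prediction must never
"agree" with a moving one), and fewer than two jointly valid samples is
undefined (NaN) rather than an arbitrary number.  Windows are
right-aligned half-open intervals (t_end − width, t_end] on the trace
grid, and a width is admissible only when it holds its full complement of
samples, so consensus output can begin at t = min(window widths).

## Gold-standard fusion and reaction lag

Annotator weights are each trace's mean pairwise Pearson correlation with
the others, floored at zero (an anti-correlated annotator contributes
nothing rather than inverting) and normalised.  Fusion mean-centres each
trace on its own mean, averages with the weights, and restores the
weighted grand mean, making unanimous annotators an exact fixed point;
`grand_mean="drop"` gives the zero-mean variant for pipelines that
re-anchor labels elsewhere.

The reaction lag — the delay between expressed affect and the recorded
rating — is searched on the frame grid in [0, 4 s] (4 s covers the lags
reported for time-continuous affect annotation), segment by segment, and
the arithmetic mean over segments is applied to the whole trace.
`estimate_reaction_lag` recovers planted lags to within one frame when the
reference series is independent of the gold standard (this is tested over
20 seeded trajectories).  **Known limitation:** inside the training
pipeline the reference is a preliminary all-feature ridge prediction
(α = 1.0) *fit to the unshifted gold standard*; because the ridge fit
aligns with its own target, the in-pipeline estimate collapses toward
0 s on realistic data.  A refit-per-lag variant is equally uninformative
at this penalty (the ridge can fit any shift).  The lag machinery is
therefore exact as an operation but close to inert inside training; both
arms of every comparison share the limitation.

## Per-speaker regression (SSRM)

Feature selection is a greedy forward search on the CFS merit
k·r̄_fy / √(k + k(k−1)·r̄_ff), run separately on the positive-sign and
negative-sign segments of the gold standard and concatenated.  In the
spirit of best-first CFS the chain tolerates up to five consecutive
non-improving additions and returns the best-merit prefix.  Two intrinsic
properties are worth knowing:

* conditioning on the sign of the target induces correlation between
  otherwise independent features, so per-quadrant selections are smaller
  than full-range ones — a noiseless target built from several independent
  features is not generally refit exactly;
* the √k merit penalty implies a detection threshold: a feature whose
  absolute correlation with the target is far below its co-selected
  siblings' (≈ 0.25 next to 0.5-strong features) is dropped on a
  non-trivial fraction of draws.  Parameter-recovery tests therefore plant
  balanced weights; recovery error is then below 1 %.

The regression is partial least squares on the z-scored selected
descriptors (the standard reading of a latent-projection linear model in
this literature); the component count maximises the mean CCC over
5 contiguous (blocked) cross-validation folds, and the fitted model is
stored as a plain affine map, so prediction is exactly deterministic and
serialisable as JSON.

## Consensus rule

The five-step chain (windowing, average pairwise CCC, adaptive threshold
split, width selection, pooled linear extrapolation) is recomputed at
every frame; the public scalar operations define the semantics and a
vectorised implementation (cumulative-moment sliding windows) computes
whole sequences — a 5-member, 7 500-frame sequence takes ~0.1 s — and is
tested for step-by-step equality against the scalar chain.  Candidate
thresholds are the midpoints between consecutive sorted distinct
member-averages; when all averages are equal everyone is retained with
objective 0.  Ties in width selection go to the smallest width; ties in
the split go to the larger retained group.  The 1 s fit interval is the
most recent second inside the optimal window, and the prediction advances
one frame period.  The output sample is missing wherever the optimal
concordance is negative.

Pooling note: the extrapolation line is fit to the *pooled samples* of the
retained traces, so each retained member is implicitly weighted by its
sample count.  Duplicating every retained member is a no-op; duplicating a
single member double-weights it and can also shift the retained set by
raising its average concordance — documented behaviour, exercised in the
tests.

## Pool lifecycle and RED-EX

States and edges are LABELED (terminal), UNLABELED → {WFI, EXCLUDED},
WFI → {INCLUDED, EXCLUDED}; every transition is logged with its cause.
Sufficiency (valid machine-label fraction ≥ 0.5, boundary inclusive) gates
model construction.  RED-EX compares candidate and active-model
predictions on a probe sequence (the next unlabeled speaker by default, a
held-out probe in the scripted protocols); redundancy is a whole-sequence
CCC strictly above 0.99 against any single member.  Because the
per-dimension models are independent, redundancy in *either* dimension
excludes the speaker (`redex_combine="any"`; `"all"` is available).  In
the repeated-feed protocol the first feed of a pool-speaker clone is
typically INCLUDED — its machine-labeled model is a novel blend of the
whole ensemble, not a duplicate of any single member — after which the
pool reaches a plateau: each inclusion perturbs the next feed's machine
labels by ~1 % CCC, greedy selection occasionally flips a feature subset,
and after at most a couple of transient inclusions the labels stabilise
exactly and every further feed is excluded.  Without RED-EX the pool grows
by exactly one model per feed.

## Synthetic testbed

The generator emulates the structure of a time-continuous affect corpus:

* **Latents** — Gaussian noise filtered with a Gaussian kernel chosen so
  the autocorrelation at the smoothness length (3 s default) is e⁻¹,
  scaled to 0.5 standard deviations and clipped to [−1, 1]; valence and
  arousal correlate at 0.3.  Frame period 0.04 s (25 Hz), duration 300 s
  by default.
* **Features** — 130 channels named after the ComParE LLD layout
  (4 energy + 55 spectral + 6 voicing, doubled by deltas).  20 informative
  channels are linear mixtures of the latents and their derivatives; the
  dataset-wide mixing matrix, informative-channel identities and a
  3-dimensional "style" basis are shared across speakers, and each speaker
  deviates along the style basis (jitter 1.2) with channel noise at an
  amplitude SNR of 2.  Valence-driven weights are scaled by 0.3 — valence
  is notoriously less audible than arousal.  These levels were set so the
  fixed-pool baseline lands in the regime reported for real corpora
  (median CCC ≈ 0.4–0.6 arousal, ≈ 0.1–0.3 valence, wide per-speaker
  spread) and were then frozen.
* **Annotators** — six traces per dimension: the latent delayed by a
  per-annotator lag from [0.5, 2] s, scaled by a gain in [0.9, 1.1],
  offset by a bias in ±0.1, plus smooth noise of σ = 0.1.
* **Datasets** — 4 labeled + 15 test speakers plus one held-out probe;
  the labeled pool clusters in style space (spread 0.3 around a random
  centre) while test speakers span it, encoding the semi-supervised
  premise of a small, unrepresentative labeled set.  Emotionally flat
  speakers (latent SD < 0.1) are redrawn, mirroring the usual curation of
  flat speakers.

What it does **not** emulate: real acoustic nonlinearity, speaker-specific
noise structure that would make honest ensembles *discord* on hard
speakers, session effects, or annotator drift.  One consequence is
documented prominently: all model predictions remain positively concordant
even when wrong, so machine labels are produced for ~98 % of frames
regardless of difficulty, the sufficiency gate almost never fires, and
machine-labeled models — students of the pool that labeled them — form a
mutually concordant cluster whose errors inherit the pool's.  In this
world growing the pool does **not** improve median prediction quality
over the fixed-pool control; the scripted comparison protocol reports
that honestly.  Passing tests demonstrate the machinery (fusion, lag,
selection, regression, consensus, lifecycle, redundancy exclusion), the
outlier-rejection property of the consensus, and the self-referencing
protection of RED-EX — not a general claim that self-training improves
accuracy on real speech.

## Protocol replications and problem sizes

The scripted protocols run on 60 s sequences at 25 Hz (1 500 frames),
4 labeled + 15 test speakers, 10 random orders, 10 repeated feeds —
sizes chosen so a full protocol completes in seconds while every stage
(including cross-validated training of ~40 models) is exercised.  The
supervised control is the identical consensus applied to the initial pool
only; being stateless it is exactly order-invariant, so its across-order
dispersion is zero by construction.  Significance is reported at
α = 0.05 with paired two-sided t-tests (df = n − 1; a zero-variance
difference yields a signed infinite-t sentinel), and boxplot statistics
as median ± interquartile range.
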