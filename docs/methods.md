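# Methods

## The scoring model

The clinical activity score (CAS) for thyroid-associated orbitopathy
(TAO) is a count of seven binary items: five inflammatory signs that an
ophthalmologist reads from the periorbital appearance and two
orbital-pain symptoms answered from the patient's history.  The package
reproduces the three-stage reading workflow:

1. decide, per eye, whether each of the five signs is present;
2. call a sign present for the *patient* if it is present in at least
   one eye (logical OR);
3. add the two pain answers and threshold: CAS ≥ 3 ⇒ active phase,
   CAS ≥ 5 ⇒ highly active.

Missing pain records leave the CAS *undefined* rather than imputed —
such patients still contribute to per-sign training and metrics but are
excluded from CAS and activity analyses.  An optional bounds mode
reports the attainable CAS range (missing answers counted all-no /
all-yes) for triage use; it is off by default because an undefined CAS
is the honest output when a third of the score's pain contribution is
unknown.

## Region-of-interest geometry

All crop rectangles are pure functions of five landmarks per eye
(medial/lateral canthus, upper/lower lid apex, mid-brow) expressed in
units of the palpebral fissure width `W = |lateral − medial|`:

| ROI | definition | signs read from it |
|---|---|---|
| orbital | landmark bounding box ± 0.30 W laterally, 0.70 W above the upper lid apex, 0.45 W below the lower lid apex | eyelid redness, eyelid swelling |
| lateral conjunctiva | 0.60 W square centred 0.25 W inward from the lateral canthus | conjunctival redness, conjunctival edema |
| medial conjunctiva + caruncle | 0.60 W square centred 0.25 W inward from the medial canthus | caruncle/plica inflammation |

The margins are free design parameters (exposed in `CropGeometry`);
the values above were chosen to cover the stated anatomy with
headroom and are held fixed throughout.  Rectangles are snapped to
integer pixels (floor), treated half-open, clipped to the image, and
resized to 64×64 RGB with bilinear interpolation without aspect
preservation — small enough for PCA at desk scale.  Snapping makes
crops bitwise invariant under joint integer translation of image and
landmarks, which the tests exercise.  Conjunctival redness is read
from the lateral crop only, keeping one crop per model input; the
medial crop serves caruncle inflammation alone.  Laterality is always
taken from landmark labels (a frontal photograph mirrors anatomy:
the patient's left eye sits on the image's right half).

Landmark ingestion is a pluggable backend; the default reads the JSON
sidecar the synthetic generator writes.  Detection of landmarks on
real photographs is deliberately out of scope — any detector
satisfying the small `LandmarkBackend` protocol can be substituted.

## Classifier architecture

Each sign's model holds three **submodels**, one per expert rater:
centering PCA followed by a linear-kernel SVM on the flattened
12,288-dimensional crop.  ("Linear-kernel PCA" spans the same subspace
as standard linear PCA, so the numerically simpler form is used.)
Hyperparameters are tuned by stratified fivefold cross-validation over
the grid C ∈ {0.01, 0.1, 1, 10} × components ∈ {8, 16, 32, 64}
(defaults; configurable), selecting by mean CV accuracy with ties
broken toward fewer components, then smaller C.  Within each fold the
PCA is fitted once at the largest feasible dimensionality and leading
components are reused for the smaller candidates; the winning pair is
refitted on all training data.  The component grid is clipped, with a
logged warning, when the sample size cannot support it.  Class
weighting is not applied (a flag exists).  Randomized-SVD PCA and
liblinear primal solving keep fits deterministic under a fixed seed.

Two consensus architectures combine the submodels:

* **voting** — majority of the three submodel labels; the continuous
  score for ROC analysis is the mean of the three decision values;
* **aggregating** — a fourth PCA+SVM whose input is the PCA projection
  of the crop concatenated with the three rater readings encoded ±1,
  trained against the raters' agreed diagnosis.  Training uses the
  true rater labels (teacher forcing, mirroring how the written expert
  readings are available at training time); at inference the head is
  fed the submodels' hard ±1 predictions.  A configuration toggle
  trains on submodel predictions instead (not default).  The head's
  decision value is the model's ROC score.

Default assignment: aggregating for eyelid redness and caruncle
inflammation, voting for eyelid swelling and both conjunctival signs.
Everywhere the label convention is strict: `label = (score > 0)`, an
exactly-zero score is negative.

Fitted models serialize as a directory bundle — metadata JSON plus raw
arrays (`.npz`) — with a format version check; no pickling, so bundles
are stable across minor releases and corruption fails loudly.

## Synthetic cohorts

Clinical photographs cannot be redistributed, so the generator renders
schematic periorbital images: a skin-toned field, elliptical sclera,
iris and pupil disks, an eyelid crease band and a medial caruncle blob
per eye, with Gaussian pixel noise (σ = 0.015) and per-patient skin
jitter.  Each sign adds an intensity-scaled perturbation confined to
the ROI it is read from, with a distinct channel/spatial signature
(e.g. a uniform red tint in the eyelid band for eyelid redness, a
smooth brightness bump for swelling, a bluish bulge on the lateral
sclera for chemosis).  Truth is `intensity > 0`; landmarks are exact
by construction.

Cohort structure follows the modeled study population: default
patient-level prevalences 342/1020, 428/1020, 849/1020, 123/1020,
107/1020 for the five signs; pain prevalences 109/918 and 78/918; both
pain records blanked together with probability 102/1020.  A positive
sign is bilateral with probability 0.5, else affects one random eye
(per-eye prevalence data do not exist; the parameter keeps the eye-OR
rule non-trivial and is configurable).  Rendering intensity for a
present sign is drawn uniformly from (0.4, 1.0) by default — wide
enough to create easy and hard cases — and can be pinned to 1.0 for
recovery tests.  Three simulated raters read each sign/eye
independently through sensitivity/specificity channels (defaults
0.75/0.88, 0.80/0.90, 0.85/0.92 — chosen so that full three-rater
agreement is uncommon, as in real multi-reader scoring); when they
disagree, the simulated discussion recovers the latent truth except
with a flip probability (default 0.1).  Pain flags are independent of
image signs, as no joint distribution is available.

Even at maximal signal the consensus reference retains a floor of
label noise: when all three simulated raters make the same error
(probability `(1-spec)^3` or `(1-sens)^3` per eye-sign), the unanimity
rule adopts the wrong label and a correct image reading is scored as a
miss.  With 0.96 raters this caps attainable per-sign AUC slightly
below 1 for rare signs in small test sets.

What passing tests on this generator demonstrate: that the cropping,
feature, consensus, scoring, splitting and metric machinery is
correct and lossless when a linearly separable, ROI-localized signal
exists.  What they do not demonstrate: performance on real
photographs, where illumination, pose, skin-tone diversity, occlusion
and correlated rater errors dominate — none of these are emulated, by
design.

## Evaluation protocols

* **entire** — repeated 8:2 train/test splits (30 by default), freshly
  drawn per repeat from a named substream of the base seed.  Splits
  stratify on activity status (patients with undefined CAS form their
  own stratum) via largest-remainder allocation, to avoid single-class
  test sets at small n; an unstratified mode exists.
* **consistent subset** — the test set is a fixed-size draw (100) from
  the patients on whom all three raters agreed on *every* sign in both
  eyes (the strictest reading of "consistent"; pain items come from
  records, not raters, and are excluded from the criterion).  Everyone
  else — inconsistent patients plus consistent leftovers — trains.

Per-sign metrics are computed at the patient level, after the eye-OR
(a per-eye mode exists behind a flag).  Sensitivity and specificity
count against the consensus reference; AUC uses the rank (Mann–Whitney)
formulation with ties contributing ½, which the tests cross-check
against trapezoidal ROC integration.  The patient-level score is the
maximum of the two eye scores, matching the OR aggregation.  Repeat
values are summarized as mean with a Student-t 95% CI (`ppf(0.975,
n−1)·sd/√n`); identical values give a zero-width interval.  CAS
comparisons pool over repeats into an 8×8 confusion matrix; exact and
within-1 agreement are reported both as pooled percentages and as
per-repeat means with CIs, which can differ slightly when per-repeat
test sizes vary.  A failed repeat is logged and skipped; the report
records completed repeats and the error messages.

## Numerical and design choices

* Single global seed, expanded into named substreams (cohort labels,
  face rendering, rater simulation, splits, fits) via CRC-hashed
  `SeedSequence`s — changing the number of repeats never perturbs
  cohort generation, and every derived seed stays below 2³¹.
* Degenerate inputs fail loudly: single-class training labels, fewer
  than two samples per class, degenerate palpebral width (≤ 2 px),
  out-of-bounds landmarks, CAS outside 0..7, empty confusion matrices.
* The bundled reference tables (`src/casvision/data/`) are inputs for
  worked-example statistics only; models are never fitted to them.
* Test problem sizes: the recovery suite uses a 300-patient cohort
  with 5 repeats and the signal-ladder check uses 150-patient cohorts
  at three levels with reduced grids — sizes chosen to make the
  separability argument at desk scale.

## Known limitations

* The renderer is schematic; no claim is made about real-photograph
  performance, and the published real-data operating points are not
  reproducible without the clinical images.
* Rater errors are independent across signs, eyes and raters;
  correlated reader behaviour is not modeled.
* The aggregating head's teacher-forcing mismatch (trained on true
  rater labels, fed submodel predictions at inference) is reproduced
  deliberately; its effect is only visible when submodels are poor.
* No probability calibration, data augmentation, or convolutional
  models — the classifier family is linear by design.
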