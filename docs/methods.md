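# Methods

## Problem setting

`ctcnoise` analyses how interobserver variability in manual annotation
("label noise") limits the training and evaluation of automated binary
classifiers of fluorescently stained circulating tumor cells (CTCs).
The data model is a panel of N image cutouts — square regions centred
on a candidate object, stained blue for cell nuclei, green for
EpCAM/cytokeratins and red for the CD45 leukocyte counterstain — each
labelled CTC / no-CTC by M observers.  A cutout counts as a CTC when
the blue nucleus is intact, the green staining is positive and
structured, and no red staining is present.

## Agreement statistics

For observers A and B with binary label vectors over N cutouts, the
pairwise agreement is

    P_Agr(A, B) = 1 − (1/N) Σ_i |A_i − B_i|,

i.e. one minus the normalised Hamming distance.  Per observer we report
the mean of the M−1 pairwise agreements, its standard error (sample SD
of those M−1 values divided by √(M−1)), the CTC count N_CTC, and the
signed mean count difference ΔCTC(A) = mean_B (N_CTC(A) − N_CTC(B)).
ΔCTC is kept signed so that conservative observers (who only call a CTC
when certain) appear at negative ΔCTC; the ΔCTC values sum to zero over
the panel by construction.

Under the null model that every observer resolves every cutout
correctly with one common probability p, two observers agree with
probability ≈ p², so p is estimated as the square root of the mean
pairwise agreement (taken over the M(M−1)/2 unordered pairs) and the
expected number of unanimous cutouts is N·p^M.  Comparing this
prediction with the observed unanimity count — and a one-sample t-test
of the pairwise agreements against the unanimity-implied agreement —
tests whether disagreement probability is uniform across cutouts (it is
not; ambiguity concentrates in a subset of hard cutouts).

## Consensus limit and GT/probGT partition

The consensus limit c for an M-observer panel at level α (default 0.05)
is the smallest count such that P(X ≥ c) < α for X ~ Binomial(M, 1/2):
concordance of ≥ c observers is then unlikely to arise from coin
flipping.  The tail is computed with exact binomial coefficients
(rational arithmetic), and the one-sided form is used: it yields c = 9
for 11 observers and c = 5 for 5 observers, whereas a two-sided version
would give c = 10 for 11 observers.  For M ≤ 4 no c qualifies and a
sentinel is returned.

A cutout with ≥ c concordant votes (in either direction) is a
*consensus* point with the winning vote as its consensus label.
Unanimous cutouts form the ground-truth stratum (GT); all others form
probGT.  probGT admits only *probabilistic annotations*: each point
independently takes the label of a uniformly drawn observer, so the
marginal P(label = 1) equals the point's vote fraction q_i.  The
expected Hamming distance between two independent probabilistic
annotations is Σ_i 2 q_i (1 − q_i).

## Preprocessing

Cutouts are acquired at 1.0, 0.5 or 0.25 µm² per pixel.  The pipeline,
in order: (1) centred crop to a fixed physical area of 2500 µm²
(side = round(√(area/pixel_area)): 50, 71 or 100 px); (2) isotropic
Gaussian smoothing with σ = 1 px at the source resolution (smoothing
precedes downsampling, matching the processing order of the original
workflow); (3) bilinear downsampling to 50 × 50 px (area-mean
aggregation could be substituted via the config); (4) RGB→HSV, V
dropped (overall brightness is not decisive and varies with exposure),
H and S in [0, 1] vectorised row-major into a 5000-entry feature
vector, hue block first.  Hue of achromatic pixels (S = 0) is pinned to
0; hue is treated as a plain real, so the red wraparound (H near 0 vs
near 1) is a known representational artifact.  The pipeline is
invariant to a global brightness rescaling of the input, which is the
rationale for discarding V.

## Classifiers and measures

Two fixed classifiers: a Breiman random forest with 500 trees (√p
features per split, unlimited depth) and a soft-margin SVM with RBF
kernel K(x, y) = exp(−γ‖x−y‖²), C = 2, γ = 0.005 (γ is the inverse
squared kernel radius).  No threshold tuning or calibration; hard
labels only.  Performance is summarised by accuracy, precision and
recall from pooled confusion counts; precision/recall are reported as
NaN when their denominator is empty.

## Evaluation protocols

All protocols use balanced random folds (unstratified by default, the
fold sizes differ by at most one) and audit that no test point appears
in its own training set.

* **Cross-observer, whole set.**  Five folds; when fold t is tested,
  fold (t+1) mod 5 is excluded and the remaining three train, so every
  point is classified exactly once per sweep.  Each observer's raw
  annotation serves in turn as both training and test reference;
  confusion counts are pooled per observer over the sweep and the
  report is the unweighted mean ± SD across observers.
* **Label-noise grid.**  GT is split into three folds, probGT into two
  (five folds of comparable size).  Training uses two folds — both GT,
  one GT + one probGT, or both probGT — and testing always uses a GT
  fold not used for training, rotating over the three GT folds.  GT
  folds always carry the unanimous labels; probGT folds carry a freshly
  drawn probabilistic annotation in every repetition.  Confusion counts
  are pooled over rotations within a repetition; means ± SD are taken
  over repetitions (default 50 for probGT-containing conditions, 10 for
  pure GT, where only classifier-internal randomness remains).
* **Consensus evaluation.**  Four folds over the consensus set, trained
  on three and tested on the fourth against the consensus labels;
  observers are scored against the same labels.  Caveat: each observer
  voted in the consensus, which flatters the observers relative to the
  classifiers.
* **Test-reference comparison.**  One model trained on GT and evaluated
  on probGT twice, against majority-vote labels and against
  probabilistic annotations: measures the accuracy lost merely by
  admitting annotation noise into the test reference.

One master seed expands deterministically (via `numpy.random.SeedSequence`
over a position tuple) into fold seeds, per-repetition annotation seeds
and per-fit RF seeds, so any grid cell can be re-run in isolation.

## Synthetic data generator

The study's images and annotation matrix are not publicly deposited, so
the generator emulates their decision-relevant structure:

* **Scenes.**  Each scene has a latent truth label (prevalence 0.5,
  matching the roughly balanced CTC fraction of the panel) and a latent
  difficulty in [0, 1].  Difficulty jointly fades staining intensity,
  fragments the nucleus, and destructures the green signal, so
  ambiguous annotation points are also genuinely harder images.
  Non-CTCs are red-positive blood cells (55 %) or red-negative
  faint/unstructured objects whose appearance overlaps weakly stained
  CTCs; intensities carry multiplicative jitter.  This overlap is what
  keeps classifier accuracy below 1 even on unanimously labelled data,
  as observed in practice — observers judge morphology that the colour
  features only partly capture.
* **Images.**  100 × 100 px rasters (margin enough for the 2500 µm²
  crop at all three magnifications): Gaussian-profile nucleus blob
  (blue), cytoplasmic green ring degraded toward a smear at low
  structuredness, optional red membrane staining, Poisson(0.7) flanking
  objects, additive Gaussian background noise (σ = 0.02).  Appearance
  is stylised; only the channel statistics that drive the CTC call are
  controlled.
* **Observers.**  An observer becomes unsure with probability
  min(1, slope · difficulty); unsure neutral observers guess uniformly,
  unsure conservative observers answer "no CTC" with probability 0.9.
  At difficulty 0 every profile reproduces the truth.  The default
  panel is 9 neutral profiles (slope 1) and 2 conservative profiles
  with slope 2.5: conservative observers demand more evidence, which
  reproduces the observed clustering — markedly lower N_CTC *and* lower
  mean agreement than every neutral observer.
* **Difficulty distribution.**  A two-component Beta mixture: a clear
  component concentrated near 0 (Beta(1, 14)) and an ambiguous tail
  (Beta(4, 2), optionally rescaled).  A mixture is used because the
  Bernoulli analysis above shows disagreement is not uniform across
  cutouts.  The ambiguous-mass fraction is the primary calibration
  knob (mean agreement is monotone in it, enabling bisection); the tail
  scale is chosen on a coarse grid by the achieved consensus fraction.
  Calibrating to mean pairwise agreement 0.85 and consensus fraction
  0.81 lands within ±0.02 / ±0.03 of the targets.

Latent truth is exported for testing and calibration only; no analysis
stage reads it.  What the generator does **not** emulate: optical
physics of the capture wire, focus artifacts, segmentation errors, the
full vote-count distribution per cutout (only aggregate agreement and
consensus statistics are matched), and any correlation between
observers beyond the shared scene difficulty.  Passing tests on this
data therefore support the *relative* claims (condition orderings,
RF-vs-SVM robustness, the cost of noisy test references) rather than
the absolute performance numbers of any real data set.

## Problem sizes and runtime choices

The package's standard study size is 617 cutouts × 11 observers.  The
end-to-end label-noise checks run that size with 10 repetitions per
condition; calibration simulates label-only panels (8 replicates per
parameter evaluation), which avoids rendering images inside the search
loop.  Unit tests use smaller panels and reduced forests where the
contract under test does not depend on the full settings.

## Known limitations

* The median convention is the standard midpoint rule; no attempt is
  made to reproduce published summary values that are inconsistent with
  their own underlying counts (they are documented in the tests as
  excluded).
* The expected-unanimity formula is exposed as N·p^M from the *rounded*
  mean agreement; evaluating it at 0.85 gives ≈ 252.4.
* Hue wraparound near red and the H = 0 convention for achromatic
  pixels inject small discontinuities into the feature space.
* The probabilistic-annotation model treats observers as exchangeable
  per point; it does not model per-observer reliability (no
  Dawid–Skene-style weighting), matching the raw-vote design.
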