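# Methods

`wildface` implements a four-stage face-recognition pipeline for individual
identification of animals that lack unique body markings, together with the
evaluation protocols used to validate each stage and a synthetic face
generator that makes the whole system trainable and testable at desk scale on
one CPU.

## Pipeline model

An input photograph passes through four stages, each a separately trained
model:

1. **Detection** (`FaceDetector`). A sliding window is scored over an image
   pyramid (downscale factor 1.2 per level, one upscale level) and greedy
   non-maximum suppression (IoU > 0.45) prunes overlapping hits. The window
   scorer is a linear max-margin model over HOG features (9 orientations,
   8 px cells, 2×2-cell blocks, L2-Hys normalization). Training minimizes
   hinge loss over positive windows (ground-truth boxes resized to the
   window) and negative windows, with hard negatives re-mined from the
   training images for a configurable number of rounds (default 2). The
   final score threshold is chosen to maximize F1 on the training images.
   The window height defaults to 64 px; the width follows the median aspect
   ratio of the training boxes. Boxes narrower than the window divided by
   the upscale factor are rejected at fit time with the offending images
   named, since no pyramid level can represent them.

2. **Landmark localization** (`ShapeRegressor`). Six landmarks (left/right
   eye, nose tip, left/right ear, top of forehead) are estimated by cascaded
   regression inside the detected box: the shape is initialized from the
   training-set mean shape in box-normalized coordinates and refined by a
   fixed number of stages (default 8). Each stage samples sparse
   pixel-difference features at offsets indexed relative to the current
   shape — offsets are carried through the similarity transform aligning the
   mean shape to the current estimate, which is what makes the cascade
   tolerant of in-plane rotation — and regresses a shape update with ridge
   regression (alpha 1). Training replicates each face under jittered
   initializations (default 10) so the cascade learns to recover from
   imperfect detector boxes. Stage feature radii shrink geometrically
   (0.25 of the box per side at stage 1, decay 0.82), the classic
   coarse-to-fine schedule. A depth-0 model predicts the mean shape mapped
   into the box. We use linear stages rather than boosted regression trees;
   on this problem the cascade of ridge stages reaches training error well
   under 0.05 mean normalized distance in seconds of CPU time, which the
   tree ensembles we prototyped did not beat at comparable cost.

3. **Chip extraction** (`compute_chip_transform` / `extract_chip`). The face
   is warped to a canonical 150×150 chip by the unique similarity transform
   sending the two eye landmarks to fixed positions — 30% and 70% of the
   chip width at 40% of the height. Only the eyes drive alignment; the other
   landmarks are carried along for provenance. The two-point alignment is
   solved in closed form in complex arithmetic; chip pixels are sampled by
   inverse warp with bilinear interpolation and edge replication. Canonical
   eye positions and chip size are configuration, not constants: they are
   hyperparameters of the encoder stage.

4. **Metric embedding** (`MetricEmbedder`) and **classification**
   (`IdentityClassifier`). A chip is summarized by grid HOG over the
   grayscale chip (15 px cells at the 150 px default) concatenated with
   coarse 6×6 chromaticity statistics (per-cell r and g fractions, which are
   invariant to global illumination gain but carry coat color). A learned
   linear projection maps the standardized feature vector to a 128-D
   Euclidean embedding. The projection is trained with **pairwise hinge
   loss**: with distance threshold T = 0.6 and margin M = 0.04, a matched
   pair at distance d contributes max(0, d − T + M) and an unmatched pair
   max(0, T − d + M). Batches hold 5 identities × up to 8 chips; all
   same-identity pairs are counted, and hard-negative mining keeps only the
   equally many smallest-distance different-identity pairs, so positives and
   negatives enter the loss 1:1. Every time a chip enters a batch it is
   re-augmented (similarity jitter up to 6 px / 10° / ±10% scale; per-channel
   gain 0.8–1.2 and gamma 0.8–1.25). Optimization is Adam (lr 1e-4, 10
   epochs × 20 batches by default); the projection is initialized so typical
   inter-chip distances start near T, which keeps the hinge active from the
   first step. Embeddings are deliberately not L2-normalized: the decision
   threshold is an absolute distance. Identity classification is a
   one-vs-one linear SVM (C = 1, one binary model per unordered label pair,
   K(K−1)/2 in total) with majority voting; ties break to the label seen
   earlier in training order and are flagged. The catalogue is closed — new
   individuals must be enrolled by retraining.

   The backbone is a configuration block. The default fixed-feature +
   linear-head encoder trains in about a minute on one CPU and is the
   configuration all reported numbers use; the same loss, mining and
   batching apply unchanged to any drop-in feature map.

## Verification mode

Two chips are declared the same individual iff the Euclidean distance
between their embeddings is strictly below T. Ties at exactly T count as
non-match.

## Evaluation protocols

- **Detection**: precision, recall and all-point interpolated average
  precision at IoU 0.5. Predictions are pooled across images, ranked by
  score, and matched greedily to the highest-IoU unmatched truth box in the
  same image (ties to the first truth index). AP is the area under the
  precision–recall curve after the monotone precision envelope; an 11-point
  variant is a flag away. The degenerate no-truth/no-prediction case is
  defined as AP 1.0 and flagged.
- **Landmarks**: mean over the six landmarks of the prediction-to-truth
  distance divided by the interocular distance of the truth; reported as
  mean ± SD over faces.
- **Verification pairs**: balanced sets of matched and unmatched chip pairs,
  unique as unordered pairs, never pairing a chip with itself, sampled
  uniformly over all eligible pairs without replacement. The feasible number
  of matched pairs is C(n, 2) × m for n chips per identity over m
  identities (a fractional mean n is rounded to the nearest integer).
  Accuracy is class-balanced, (TPR × 0.5) + (TNR × 0.5), with the ROC traced
  by a threshold sweep. Folding is either **by chip** (chips shuffled and
  split evenly; identities shared between train and test — a closed set) or
  **by identity label** (each identity assigned wholly to one fold; test
  identities unseen in training). By-label accuracy is expected to be lower;
  the gap measures how much of the encoder's performance is identity
  memorization rather than a transferable metric.
- **Classification**: confusion matrix over the classifiable test items;
  test items whose true identity never occurs in training are excluded and
  counted. Overall accuracy is correct/classifiable; per-class percent
  correct is the row diagonal over the row sum (2 decimals); the mean
  percent is the unweighted class mean.
- **Pipeline accounting**: per source image, a detection matching truth at
  IoU 0.5 is a correct face and every other detection is an erroneous
  extra; correct and extra faces all produce embeddings. End-to-end accuracy
  (correct identifications / classifiable source images) is bounded above by
  classifier-only accuracy on ground-truth chips of the same images, because
  detection and alignment errors only remove or corrupt inputs.

## Synthetic data

The generator renders stylized animal-like faces — ellipse head, disc ears,
trapezoid muzzle, dark eyes and nose, an identity-seeded fur-texture field
attached to the face frame — over cluttered seeded backgrounds (gradient,
elliptical blobs, grain). An identity is a nine-parameter point (eye
spacing/height, muzzle length/width, ear spread/size, fur color, outline
scale, texture seed); sampling enforces that any two identities differ by at
least 5% in at least two normalized parameters, so identities are separable
by construction. Per-image nuisance draws are in-plane rotation ±25°, scale
0.6–1.4, bounded translation, illumination gain 0.7–1.3, Gaussian blur
sigma 0–1.5, and a fresh background — the kinds of variation field
photographs show. Landmarks are computed in closed form from the identity
geometry and mapped through the nuisance similarity transform, so ground
truth is exact; the box is the tight landmark hull padded 15% per side. The
default images-per-identity distribution is a lognormal with median 22
clipped to [1, 242], emulating a long-tailed field collection.

What the generator does **not** emulate: out-of-plane pose, occlusion,
age-related appearance change, wet/dry coat states, multiple faces per
image (beyond rendering them side by side), sensor noise models, or
photorealistic texture. Passing the synthetic benchmarks therefore
demonstrates that the pipeline's machinery — detection, alignment, metric
learning, voting classification and all protocol bookkeeping — is correct
and learnable, not that field-photograph accuracy will match.

## Problem sizes and numerical choices

Reported synthetic benchmarks use 20 identities: the detector trains on 200
images and the landmark cascade on 300, both evaluated on 100 fresh renders
of the same identities; the encoder trains on an 80/20 chip split of 400
chips; the classifier evaluation uses 16 identities; end-to-end runs over 50
fresh images. The acceptance script uses a 12-identity world with the same
structure. These sizes were chosen as the smallest at which the property
targets are comfortably stable.

Other numerical choices: train/test counts round half away from zero
(4,675 images at 80% give exactly 3,740/935); by-chip folds differ in size
by at most one (4,674 chips in 5 folds give 935×4 + 934); box coordinates
are 0-based half-open pixel ranges, making IoU an exact set computation;
the verification decision uses strict inequality; detector and SVM solvers
are seeded and tolerance-bounded (LinearSVC tol 1e-5/1e-4), so training is
bit-reproducible for a fixed seed.

## Known limitations

- The detector is a single rigid linear template per aspect ratio: profile
  or heavily out-of-plane faces would need a multi-component or nonlinear
  scorer (the config accepts one; none is shipped).
- The encoder's fixed feature map cannot be fine-tuned end to end; with a
  GPU and a convolutional backbone the same loss/mining/batching code
  applies, and that is the intended upgrade path.
- Open-set recognition (flagging an individual as never-enrolled) is out of
  scope; the classifier always answers with a known identity.
- Landmark localization assumes exactly the six-name schema; faces with
  fewer visible landmarks cannot be annotated or trained on.
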