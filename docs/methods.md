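# Methods

## The measurement

On a posteroanterior (PA) chest radiograph the cardiothoracic ratio is

    CTR = (MRD + MLD) / ID

where ID is the widest internal thoracic diameter, and MRD/MLD are the
midline-to-right and midline-to-left horizontal heart diameters.  CTR > 0.5
suggests cardiomegaly.  `ctrkit` automates the measurement from a lung-field
mask and a cardiac-silhouette mask: the masks come either from ground truth
(phantoms) or from one of four segmentation networks run on the image.

### Geometric conventions

All geometry is in image coordinates (x rightward, y downward, 0-based);
radiographic side labels are metadata.  Lengths are inclusive pixel counts
(an extent over columns a..b has length b − a + 1).  The conventions were
chosen so that every quantity has an exact, testable definition:

* **ID** is measured on a single row — the row where the cleaned lung-field
  union is widest, ties resolved upward.  Whether the original clinical
  software scanned one row or several is unknowable from the outside; the
  single-row rule is the classic radiological convention and admits an
  exhaustive per-pixel oracle.
* **Midline** = midpoint of the ID endpoints.  No spine model is needed, and
  the choice affects only the MRD/MLD split — never the CTR.
* **MRD/MLD** are measured on the rows where the heart attains its extreme
  columns (possibly different rows), from the midline to the *outer edge* of
  the extreme pixel (the half-pixel terms in the code).  This yields the
  exact identity `MRD + MLD = heart max column − heart min column + 1`, i.e.
  the heart's global horizontal extent, independent of the midline.  The
  identity is asserted, not approximated.
* A heart entirely on one side of the midline gives a negative MRD or MLD;
  the case is flagged pathological but the CTR (global extent over ID) is
  still reported.  CTR > 1 is likewise reported, never clamped.
* **No sub-pixel refinement** of mask boundaries: quantisation error on the
  CTR is bounded by ~2/ID and the bound is tested.  Sub-pixel precision
  enters only through soft-probability upsampling at prediction time (below).

### Mask cleaning

Predicted masks are post-processed before measurement: holes filled, then
the k largest connected components kept (k = 2 for lungs, 1 for heart),
dropping components below 0.5% of the frame.  An empty result is a legal
signal — it maps to the *poor* grade downstream rather than raising.

## The phantom generator

Real chest radiographs and their clinical CTR reports are private; the
package instead ships a parametric phantom whose CTR is exact by
construction.  Lung fields are superellipses (exponent ≈ 2.5, slightly
boxier than ellipses, echoing the flattened lateral chest wall); the heart
is an ellipse straddling the mediastinal gap.  The thoracic extent is
`thorax_width_frac × image width` and the cardiac extent is
`cardiac_width_frac × ID`, so `truth_ctr = cardiac_width_frac` exactly;
rasterisation at pixel centres keeps the measurable CTR within ±2/ID of it.

The intensity model is deliberately minimal: dark lung fields (≈0.25) on a
brighter soft-tissue/mediastinum background (≈0.6–0.8), the cardiac
silhouette drawn bright over the lungs, a smooth random texture field
(Gaussian-filtered noise, amplitude 0.05) and per-pixel Gaussian noise
(sd 0.03 on a 0–1 scale).  Masks are purely geometric, so noise settings
never touch them.  Ribs, clavicles, gastric bubbles, pathology (effusion,
scoliosis) and DICOM photometrics are *not* modelled; consequently, passing
tests demonstrate that the pipeline's machinery is correct and that the
networks can learn this family of silhouettes — they say nothing about
segmentation accuracy on clinical radiographs.

Cohorts draw the true CTR from a truncated normal mixture.  The default mix
is 60% a "normal" regime (0.452 ± 0.032) and 40% an enlarged-heart regime
(0.549 ± 0.043), the two population means reported for clinical normal and
cardiomegaly groups.  Anatomical nuisance parameters (thorax width 0.72–0.88
of the frame, lung height/placement, mediastinal gap, heart offset/height)
are jittered per sample so a cohort is not a single silhouette; `shape_jitter=0`
switches this off.  Per-sample seeds derive from the cohort seed, making
cohorts byte-identical under a fixed seed.

## The segmentation models

Four encoder–decoder architectures are provided, all sharing 2×2 max-pool
downsampling and differing in their encoder stacks and upsampling paths:

| name | encoder | decoder |
| --- | --- | --- |
| `vgg11_unet` | VGG-style stacks, 1,1,2,… convs/stage | nearest-up + skip concat |
| `vgg16_unet` | VGG-style stacks, 2,2,3,… convs/stage | nearest-up + skip concat |
| `segnet` | VGG-16-style stacks | max-unpooling via memorised pool indices, no skips |
| `albunet` | residual (ResNet-style) blocks | nearest-up + skip concat |

The loss is the sum of the Soft Dice loss (smoothing ε = 1.0, averaged per
sample and channel) and mean binary cross-entropy, both computed from
logits.  Optimisation is Adam.  The full-scale defaults are batch 8, 75
epochs, initial learning rate 1e-4; the *toy* presets used throughout the
tests train from scratch for 8–10 epochs at learning rate 1e-3 (2e-3 for
SegNet) — a short from-scratch run needs a hotter rate than a long
fine-tuning schedule, and the loss definition is never altered.  One model
carries both output channels (lung, heart) by default; single-head modes
exist for parity experiments.

The networks run on a small pure-CPU engine inside `ctrkit.nn`: im2col
convolutions lowered to BLAS matmuls, hand-derived backward passes
(verified against central finite differences to ~1e-9 in float64), pooling
that memorises argmax indices so SegNet's decoder can unpool through them,
and a textbook Adam.  Arithmetic is single-threaded-deterministic: fixed
seeds reproduce loss traces exactly.

### Toy capacity and problem sizes

The tested configuration is depth 3, 128×128 inputs, 8 base channels for
AlbuNet and VGG-16 U-Net, 12 for VGG-11 U-Net (its encoder stacks only one
convolution in each of its first two stages) and 16 for SegNet (its decoder
lacks skip connections); the wider presets buy back the boundary precision
the thinner variants of those two architectures lack.  Phantoms are generated at 256×256 and
downsampled for the network; at prediction time the probability maps are
upsampled back bilinearly before thresholding at 0.5, which recovers
sub-pixel boundary placement and roughly halves the CTR error relative to
hard 128-px masks.  Training cohorts of 200 phantoms and held-out sets of
40–60 keep a four-architecture training sweep plus evaluation within a
desk-scale CPU session.  Full-capacity configurations (depth 5, 32 base
channels, 256×256) are constructible but not exercised by the test suite.

### Augmentation

Off by default; when enabled, horizontal batch flips only.  The phantom
family is nearly left-right symmetric, so flips add little at desk scale.

## Grading and the combined mode

`CTR_diff = 100·(ctr_model − ctr_reference)/ctr_reference`, signed, with the
manual/ground-truth value as denominator (reference-relative, not
pair-mean-relative).  Grades: *poor* iff segmentation failed (empty mask);
*excellent* iff |CTR_diff| ≤ 1.8 (boundary inclusive — the source range is
stated without boundary semantics, so inclusivity is a documented choice);
otherwise *good*.  In combined mode the model with the smaller |CTR_diff|
is selected, ties deterministically to model A.  Since
min(|dA|,|dB|) ≤ |dA|, the combined excellent yield provably dominates both
single-model yields; the suite asserts this on random cohorts.

`simulate_session` replaces the live two-reader workflow with a scripted
oracle: each reader accepts the presented (combined-selection) result iff it
falls within the band of the reader's own reference, perturbed by Gaussian
jitter (sd in percent).  A record is excellent only if *all* readers accept.
With zero jitter and one reader the session reduces exactly to the band
rule.  Real readers can accept outside the band or adjust within it; the
oracle is an explicit simplification.  `processing_time_s` records pipeline
compute time only — human operating times are out of scope.

## Agreement statistics

For paired series (model vs manual, or reader vs reader): bias = mean
percentage difference; 95% limits of agreement = bias ± 1.96·sd of the
percentage differences (some reports label this interval "95% CI"; it is
structurally the limits of agreement and named so here); paired Student's t
on the raw values with two-sided p.  The coefficient of variation is

    CV = 100 · sd(raw paired differences) / grand mean of all raw measurements

"Divided by their mean" is ambiguous in prose descriptions of this CV;
dividing by the mean *difference* is unstable near zero bias and cannot
produce the small positive CVs that characterise good agreement, so the
grand-mean denominator is used and stated prominently.  Degenerate cases:
identical series give bias 0, CV 0, t 0, p 1; a constant nonzero difference
gives infinite t with a `degenerate_variance` flag.

## Numerical choices

* Dice smoothing ε = 1.0; mask binarisation threshold 0.5 (symmetric default).
* He initialisation; biases start at 0.
* Ties: widest-row ties go to the uppermost row; combined-mode ties to
  model A; pool argmax ties to the first (flat-index) position.
* Images are 8-bit grayscale PNG on disk (masks 0/255); CTR quantisation from
  8-bit storage is nil because masks are binary.

## Known limitations

* Phantoms are smooth convex/concave silhouettes; no occlusion, rotation,
  or pathology.  Expect all quality numbers to be optimistic relative to
  clinical data.
* The engine is CPU-bound; full-capacity training at 256×256 is possible
  but slow (hours), and no GPU path exists.
* The ResNet encoder depth in `albunet` is a shallow residual stack at toy
  scale rather than a fixed 34-layer encoder; the architecture family, not
  the exact layer count, is what the toy preserves.
* `simulate_session` models reader behaviour as a band rule with Gaussian
  jitter; it cannot reproduce reader-specific adjustment habits.
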