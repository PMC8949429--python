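# Methods

## The coding model

`veincode` treats a finger-vein ROI image as a texture to be summarized by
order relations between local mean intensities. The coder composes two
pooling stages:

1. **Block-mean pooling.** The image is zero-padded on the bottom/right to
   the next multiple of the block size `a×b` and each block is replaced by
   its arithmetic mean. Padding zeros are *included* in boundary-block
   means: the canonical order of operations is pad first, then average.
   This biases boundary means downward; since both enrolled and probe
   images of one dataset share the same geometry, the bias is common to
   all codes being compared and does not by itself separate subjects.
2. **Center-symmetric comparison.** The block-mean matrix is partitioned
   into non-overlapping 3×3 tiles, row-major, again zero-padding ragged
   boundaries. Each tile's eight border entries are read clockwise from
   the top-left corner (`n1..n8`; the center entry is never used), and
   four bits compare diametrically opposite pairs: bit *j* is 1 iff
   `n_j >= n_{j+4}`.

The comparison uses `>=`, so tied pairs encode 1; a constant image encodes
all-ones. Comparing against the opposite neighbor rather than the center
halves the bits per neighborhood relative to plain LBP and makes the code a
function only of intensity *order*, hence invariant under positive affine
intensity maps with no clipping.

The clockwise-from-top-left border walk is a fixed internal convention
(tagged `cw-tl-v1` in the serialization header). Any fixed walk that pairs
`n_j` with `n_{j+4}` yields an internally consistent matcher; codes are
only comparable within one convention, which is why the code-file header
pins it.

## Matching and its assumptions

A subject's template set holds the codes of its first N images. A probe's
score against a subject is the minimum Hamming distance to any of that
subject's templates, divided by the codeword length; acceptance is
`score <= DT`, with the boundary accepting (strictness at equality is an
arbitrary choice; it is applied consistently in `verify`, FAR counting and
recognition rates). Codes are matched positionally — no shift or rotation
search is performed — so translation/rotation tolerance comes only from the
pooling stages. This is the matcher's main limitation: pose changes larger
than roughly one block visibly degrade genuine scores (the robustness
sweeps below quantify this).

Hamming distances are computed on MSB-first packed codes with a bytewise
popcount; byte-padding bits are zero in both operands and cannot
contribute. The test suite cross-checks the packed path against a per-bit
loop and the whole coder against a naive triple-loop reference.

## Verification protocol and error estimation

The first N samples of each subject enroll; every remaining sample is a
probe. Each probe produces one genuine trial (against its own subject) and
one impostor trial against *each* other subject's full template set, so K
subjects with s samples each give `K·(s−N)` genuine and `K·(s−N)·(K−1)`
impostor trials. The impostor pairing is probe × subject (min over that
subject's N templates), not probe × template — this is what makes 210
subjects × 12 samples at N=6 produce 263,340 = 1260 × 209 impostor trials.

- `FAR(t)` = fraction of impostor scores ≤ t (non-decreasing in t);
- `FRR(t)` = fraction of genuine scores > t (non-increasing in t);
- both are sampled on 1001 evenly spaced thresholds in [0, 1];
- the EER is located by linear interpolation of the sign change of
  `FAR − FRR`; if the two curves are exactly equal over a run of grid
  points, the midpoint of that run is reported. With score distributions
  bounded in [0, 1] a crossing always exists on the grid.

Recognition rates at a threshold are reported in percent with their integer
false counts (false rejects among genuine trials, false accepts among
impostor trials).

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| block size `a×b` | 3×8 | px | suits landscape ROIs whose vessels run along the finger; wider-than-tall blocks pool along the vessel direction. 5×5 suits squarer geometries. |
| templates N | 6 | images | half of a 12-sample class; past 6 the marginal EER gain is small while enrollment cost grows. |
| decision threshold DT | 0.19 | score | a mid value of the useful sweep on real databases; the best DT is dataset-specific and should be re-derived (e.g. from the EER threshold) per dataset. |
| threshold grid | 1001 points in [0,1] | — | 10⁻³ resolution; finer grids change the interpolated EER negligibly. |

## The synthetic generator

The generator emulates the features of cropped near-infrared vein ROIs that
matter to a texture coder: dark smooth curvilinear ridges (cubic splines
through random control points, Gaussian cross-section, FWHM equal to the
drawn width) on a brighter background with a random low-order illumination
gradient; per-sample pose jitter (uniform translation and rotation,
bilinear resampling) and sensor noise (additive Gaussian, plus pepper/salt
dropout). Rotation and translation fill exposed borders with the background
level rather than zero — zero-fill would create high-contrast frame edges
no real sensor produces, and the coder would latch onto them.

Defaults (the benchmark conditions): 50 subjects × 12 samples, 120×240 px,
7 vessels of width 3–7 px and depth 60–110 gray levels, background 200
± a gradient of amplitude 25, translation ≤ 4 px per axis, rotation ≤ 3°,
Gaussian σ = 12 gray levels, pepper density 0.002, seed 42. These
magnitudes were chosen so the benchmark sits in a realistic difficulty
regime — EER ≈ 10 % with 2 templates falling to ≈ 3 % with 6 — rather than
saturating at zero error, which would make parameter trends unobservable.
`snr_db` replaces the fixed σ with the value realizing a whole-image SNR of
`10·log10(mean(signal²)/σ²)` dB; 30 dB and 40 dB are the conventional
mild-noise presets.

Per-subject randomness derives from `SeedSequence([seed, subject_index])`,
so datasets are bit-reproducible and subjects are independent of how many
others are generated.

What the generator does **not** model: vascular branching topology, finger
shape and ROI-cropping variability, scattering blur depth dependence,
session-to-session illumination drift, or sensor fixed-pattern noise.
Passing the pipeline tests therefore shows the coder/matcher/evaluator are
internally correct and behave sensibly under controlled pose and noise
perturbations — not that any particular error rate will transfer to real
vein databases.

## Problem sizes used in tests and the acceptance script

Unit tests run on images ≤ 30×30 and on a 6-subject × 8-sample dataset of
48×96 px images. The end-to-end checks use the default 50×12 benchmark
(300 genuine / 14,700 impostor trials per run) and re-generate it at three
noise and three rotation levels; protocol trial-count checks use the
210×12 and 492×12 shapes on 9×9 stand-in images, where coding cost is
negligible. The whole suite runs in well under a minute on one CPU.

## Known limitations

- No alignment search at match time; robustness to pose is bounded by the
  pooling footprint (about one block of translation).
- Zero-padding conventions couple code bits at image boundaries to absolute
  intensity (a padded block's mean competes with real means), so boundary
  tiles carry less discriminative information.
- The EER estimator is grid-based; with very few trials its value is
  quantized by the empirical score distributions, not by the grid.
- Synthetic results calibrate and exercise the pipeline; they are not
  claims about real-database performance.
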