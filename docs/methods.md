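# Methods

This note records the models and procedures implemented in `coloqc`, the
parameter defaults and why they were chosen, what the synthetic data does
and does not emulate, and the design decisions taken where the design was
genuinely open.

## Color coding and the occupancy-cube classifier

RGB pixels are converted to CIELAB under the D65 illuminant and 2°
observer (via scikit-image) and byte-coded as

    L_coded = round(L* · 255/100),  a_coded = round(a* + 128),
    b_coded = round(b* + 128),

clamped to [0, 255]. The coding is the common byte representation of
CIELAB; it is invertible to roughly one byte step, and all thresholds
below are expressed on the coded scale.

For each of mucosa, residue and lumen, a patch library (small rectangles
of unambiguous region content) is accumulated into an *occupancy cube*: a
logical 256×256×256 array over coded (L, a, b) counting how often each
nuance occurs. Counts, not booleans, are kept: nuances seen repeatedly are
treated as more characteristic, and counts break ties between cubes.
Storage is a sorted sparse (key, count) table; a frame is classified by a
vectorised binary search per cube.

Classification is rule-first and total:

1. `L ≥ artifact_L_min` (default **253**) → artifact. Very bright nuances
   are rare in natural scenes but typical of reflections from wet mucosa,
   overexposure and text overlays.
2. `L < lumen_L_max` (default **50**) → lumen (the dark cavity).
3. Otherwise the class whose cube holds the largest count at the pixel's
   coordinate; ties break by the fixed precedence **residue > mucosa >
   lumen** (residues are rarer and clinically critical, so doubt resolves
   toward them). No cube containing the nuance → *unclassified*.

Saturated non-white artifact colors (pure orange/green/blue overlays) are
not rule-encoded by default; the `ClassifierRules` dataclass is the hook
for extending the rule set.

## Annotation encodings

Review annotations are lossless 24-bit TIFFs (mucosa pure red 255-0-0,
residue pure green, artifact pure blue, lumen pure black; unclassified
pixels keep the source frame pixel when available, otherwise mid-gray
128-128-128). Training labels are 8-bit grayscale PNGs: mucosa 64,
residue 94, artifact 124, lumen 154, background/unclassified 0. JPEG is
never used: lossy compression would corrupt the pure marker colors. Both
encodings are exact inverses through the label map, which the test suite
verifies by round-tripping.

## Segmentation network

A deliberately small encoder–decoder, implemented directly in numpy
(im2col convolutions; analytic backward passes verified against central
finite differences in the test suite):

    input H×W×3  (H, W divisible by 4; canonical full scale 576×720)
    → conv 3×3 /2, C channels,  BN, ReLU
    → conv 3×3 /2, 2C channels, BN, ReLU
    → ×2 nearest upsample → conv 3×3, C, BN, ReLU
    → ×2 nearest upsample → conv 3×3, C, BN, ReLU
    → conv 1×1 → 4 class scores per pixel

Defaults: `base_channels C = 32`; SGD with momentum 0.9; mini-batch 48;
schedule 50 epochs at 1e-3, 50 at 7e-4, 50 at 4.9e-4; input order
reshuffled every epoch; He initialisation from the model seed, making
training bit-reproducible on one platform. Inputs are "zerocenter"
normalised by subtracting the per-channel training mean; they are
additionally divided by the per-channel training standard deviation, a
numerical-conditioning choice so that the prescribed small learning rates
act on unit-scale activations. Batch normalisation inside each block is
part of the same choice: it removes the strong dependence of convergence
speed on the initialisation draw that a plain conv-ReLU stack shows at
these learning rates.

The loss is pixel-wise softmax cross-entropy over the four regions with
gray level 0 (unannotated background) excluded. This is the mechanism by
which the network *extends* the annotated "clouds of pixels": it is never
penalised on pixels the rule classifier could not label, yet must output a
class everywhere, so predictions are total — the unclassified rate of the
model is exactly 0 by construction (arg-max over four scores).

The exact depth/width of the original full-scale network is not
reproducible here; the implemented architecture is the minimal one
consistent with "reduce the resolution twice, then reconstruct", with
configurable widths. Reported mini-batch accuracy/loss are per-epoch means
over that epoch's mini-batches, computed on annotated pixels.

## Per-frame statistics, validity, per-segment aggregation

For a label map, `pct[c]` is 100 × (pixels of class c) / (all pixels). A
frame is **valid** iff `pct[artifact] < threshold`, strictly; the default
threshold is **34%**, with 25% and 40% selectable (34 balances retained
versus excluded frames; 25 excludes too many, 40 too few). Per scope
(whole video, and segments 1–3 delimited by frame-index cuts derived from
mm:ss timestamps at 25 fps via `floor(seconds × fps) + 1`), class
percentages pool pixel counts over valid frames only. The indicator counts
— frames with mucosa > 75% (well visualised) and frames with residue >
50% (poor preparation) — are evaluated on *all* frames, valid or not.
Segment membership uses the half-open convention: frame i belongs to
segment 1 when `i < cut_1_2`, to segment 2 when `cut_1_2 ≤ i < cut_2_3`,
else to segment 3. A scope with zero valid frames has undefined (NaN)
pooled percentages; the pipeline scores such a segment 1 (artifact-
saturated, uninterpretable).

## Quality score and agreement statistics

A segment scores **3** when mucosa ≥ 70 and residue ≤ 10, **1** when
mucosa < 50 and residue > 15, else **2**. Boundary inclusivity (≥ 70,
≤ 10, < 50, > 15) is fixed by the packaged per-segment records: the rows
at exactly (70, 5) score 3 and at (50, 15) score 2. Four of the 21
packaged rows are inconsistent with *any* reading of these cutpoints
(T1 seg 2, T3 seg 1, T3 seg 3, T6 seg 3); `scoring.flag_inconsistent`
surfaces them rather than fitting them, and the published scores are kept
verbatim in the fixture.

Agreement uses the tie-corrected Spearman coefficient (Pearson correlation
of mid-ranks; both series are short, ordinal and heavily tied) and, for
the categorical score-vs-score comparison, Cohen's kappa
((p_o − p_e)/(1 − p_e) with product-of-marginals chance agreement). The
backends are scipy and scikit-learn; the test suite cross-checks both
against naive mid-rank and contingency-table implementations. The BBPS
series defaults to rater 1: recomputation shows rater 1's segmental scores
reproduce all five published statistics (0.69, 0.63, −0.47, −0.65, 0.28),
while rater 2 and the rater mean are selectable. Agreement is computed at
segment level (n = 21), the only granularity with paired data.

## Synthetic data: what it emulates, what it does not

Region geometry is a Gaussian-smoothed white-noise field partitioned at
the quantiles of the requested area fractions (default smoothness σ = 8 px
on 64×64 frames): seeded, organic, connected regions whose areas match the
request to the pixel. Colors are drawn per class from RGB boxes chosen in
accordance with the field descriptions — mucosa reds-to-browns, residue
yellows-to-browns — and validated by rejection against the coded-L rules,
so lumen pixels satisfy `L < 50` and bright-artifact pixels `L ≥ 253`
*with probability 1*. A `hue_overlap ∈ [0, 1]` dial slides the mucosa and
residue green-channel ranges together (disjoint at 0, ~40 gray levels of
overlap at 1) to probe cube tie-breaking and the network's robustness to
ambiguous nuances.

Pseudo-videos plant three segment profiles with per-frame fraction jitter
(s.d. 0.06) and artifact "spikes" (a frame becomes 50% artifact with
probability 0.30 for the poor-preparation profile, 0.05 for the good one),
emulating reflection/overexposure bursts that the validity filter must
reject. The good profile centres on 72% mucosa / 6% residue, the poor one
on 40% / 22% — the contrast observed between a well and a poorly prepared
real examination.

Not emulated: specular-highlight geometry, motion-blur kinetics, NBI
color shifts, on-screen text shapes, camera vignetting, or inter-patient
color variation. Passing tests on this data therefore demonstrate the
correctness and internal consistency of the pipeline (rules, encodings,
statistics, training mechanics, score ordering), not clinical performance
on real endoscopy video.

## Scaled-down study sizes

The benchmark routines (`coloqc.benchmarks`) run the pipeline's headline
computations at sizes chosen to complete in a few minutes on one CPU:
64×64 frames; patch libraries of 209/84/154 patches of 30–80 px (the same
library sizes as the real collections); a 60-frame training set with 15
held-out frames; the schedule shortened proportionally to 15+15+15 epochs
at the same staged learning rates with mini-batch 8; 50,000 fresh pixels
per class for recovery; 45-frame pseudo-videos for the ordering study.
Under these conditions the rule classifier recovers ≥ 99% of fresh
same-palette pixels (errors are unclassified unseen nuances, not
cross-class confusions, since the default palettes are disjoint), and the
network reaches ~0.92 held-out pixel accuracy training on rule-based
annotations with moderately overlapping palettes (`hue_overlap = 0.5`) —
residual errors concentrate at region boundaries (upsampling blur) and in
the deliberately ambiguous mucosa/residue overlap.

## Numerical and degenerate-input choices

* Lab coding rounds half away from zero and clamps; grays always code to
  a = b = 128.
* Cube lookup of an empty cube returns 0 everywhere; building a cube from
  an empty patch collection is an error.
* `spearman` raises on constant series (undefined correlation); kappa
  raises when chance agreement is 1. Non-integer category values (rater
  means) are supported through integer category codes.
* Frame indices are 1-based throughout (`04_07563.tiff` is frame 7563);
  timestamp mapping `floor(seconds × fps) + 1` is the only rounding that
  sends 0:00 to frame 1.
* Training aborts before any weight update if a label file contains a
  value outside the gray-code table; a mini-batch with no annotated pixels
  is an error.
* float32 arithmetic throughout the network; BN epsilon 1e-5, running-
  statistics momentum 0.1.

## Known limitations

* The rule classifier's accuracy is bounded by library coverage; nuances
  absent from every cube stay unclassified (on real data roughly half of
  all pixels, which is precisely why the network exists).
* The network has no skip connections, so boundaries are localised only to
  within the upsampling factor; on synthetic scenes this caps pixel
  accuracy around 0.95.
* Anatomical segment boundaries are user-supplied timestamps; automatic
  transition detection is out of scope.
* NBI-filtered frames are excluded via a user-provided list, not detected.
* Reported full-scale statistics (frame counts, class percentages of real
  examinations) depend on clinical video that cannot ship with the
  package; the packaged per-segment table is the only real-data artifact.
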