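# Methods

This note records the model, the numerical choices, and the synthetic
world the package is tested in — including what a green test does and
does not establish.

## Model

Fusion is cast as per-pixel binary classification: for each pixel,
decide whether source A or source B carries more information there,
then copy that source's pixel. The classifier is a convolutional
extreme learning machine — a fixed *random* convolutional feature
extractor with a single fitted linear readout.

### Feature extractor

Each siamese branch applies three valid (no-padding) 3×3
cross-correlations with 64, 128 and 256 output channels, ReLU after
every convolution, 2×2/2 max-pooling after the first two, and global
average pooling at the end. On a 32×32 patch the spatial sizes are
32 → 30 → 15 → 13 → 6 → 4. Cross-correlation is used as written (no
kernel flip); both conventions are equivalent here up to a reflection
of the random kernels.

Kernel entries are i.i.d. N(0, σ²) with σ = 1/√fan_in
(fan_in = in_channels·9). The variance-preserving scale keeps
post-ReLU activation magnitudes roughly constant across layers, so the
512-dimensional concatenated feature neither vanishes nor saturates.
Biases are zero: with zero biases the whole branch is positively
homogeneous, which makes the features behave predictably under global
intensity scaling. Only the readout weights β are fitted, by the ridge
system (I/C + HᵀH)β = HᵀT solved with a Cholesky factorization
(`assume_a="pos"`); a residual check at 1e-8 relative tolerance guards
against ill-conditioning. C defaults to 1.0; the corpus is separable
enough that accuracy is flat over orders of magnitude of C.

The two branches are merged by concatenation of their GAP vectors.
Concatenation (rather than difference or absolute difference) keeps
both branches' information and leaves the ridge solve unchanged; the
head has one real output with targets {0, 1} and decision threshold
0.5, ties going to A.

### Dense scoring

The classifier is trained on patches but applied densely: each pixel is
scored by the 32×32 patch centred on it after reflect-padding by 16.
Scoring every patch naively would redo almost all convolution work, so
the conv/pool stack runs once over the whole padded image and each
patch's GAP feature is recovered as a 4×4 window mean of the final
feature maps. With two stride-2 pools, the pooling lattice of a patch
at offset (4i, 4j) coincides with the whole-image lattice, so these
features are *identical* to patch-wise evaluation (verified to float
precision in the tests); the 16 sub-lattice shifts cover every pixel in
exact mode. The default scoring grid is stride 4 — the natural
alignment period of the two pools — with nearest-neighbour upsampling
between grid points; `exact=True` scores all pixels at ~16× cost.

### Decision refinement

Stage 1 cleans the raw ownership map with a single-pass 3×3 rule: a
pixel is re-assigned to A if ≥ 5 of its 8 neighbours (replicate-padded)
belong to A, to B if ≤ 3 do, and kept at exactly 4. All sums are taken
over the pre-filter map, so the result is independent of scan order.

Stage 2 arbitrates with local similarity: r_B = 5×5 windowed RMSE
between F and B, r_A = same against A; MF = 1 where r_B > r_A strictly
(F locally resembles A more). A naive transcription that compares
RMS((F−B)−A) with RMS((F−A)−B) is vacuous — the two arguments are the
identical image F−A−B — so the similarity form above is the one
implemented. The windowed mean is computed by direct correlation, not a
running-sum filter, so windows of exact zeros stay exactly zero; this
matters because the strict inequality must tie (→ 0) when F, A and B
agree. MF is smoothed by exactly one binary opening followed by one
closing with a flat all-ones 5×5 square structuring element (a literal
5×5 *identity matrix* would be a diagonal element that cannot smooth
outlines; the square is the intended reading). One application each:
opening∘closing is idempotent in this order for the structures that
matter, and iterating changes nothing on our maps. The final image
re-selects A where MFF = 1 with all 8 neighbours 1, B where MFF = 0
with all 8 neighbours 0, and keeps the stage-1 pixel otherwise.

Consequences worth knowing: every output pixel is a verbatim source
pixel (selection closure), and fusing an image with itself returns it
exactly — both are asserted end-to-end in the tests.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `patch_size` | 32 px | classifier context; must be divisible by 4 so the pooling lattices align |
| `conv_channels` | (64, 128, 256) | width of the three random layers |
| `elm_C` | 1.0 | ridge coefficient; penalty on β is 1/C |
| `score_stride` | 4 px | scoring grid; 1 = exact, larger = blockier decisions |
| `threshold` | 0.5 | score above which a pixel comes from A |
| `blur_sigma_range` | [2, 4] px | blur widths in the training corpus |
| metric windows | 8×8 (Piella), 5×5 (RMSE), 16×16 (CV regions) | see below |

## Synthetic world

**Training corpus** — each pair is a sharp 1/f²·^0.75 (power exponent
1.5) texture patch and a Gaussian-blurred copy (σ ~ U[2, 4]); the sharp
member is information-rich by construction and occupies slot A for
exactly half the pairs. 500 pairs, an 80/20 split and one linear solve
give validation accuracy 1.0.

**Phantoms** — modality A carries a bright ring (outer radius 0.42·size,
inner 0.34·size) and six sharp radial spokes over a dim shared
background; modality B carries smooth textured blobs strictly inside
the ring, with an intensity ramp (distance transform, 6 px) so B
differs from the background only inside its own mask. The ground-truth
masks are exact by construction: disjoint, and jointly covering every
materially different pixel.

What this world does *not* emulate: real CT/MRI noise statistics,
partial-volume effects, intensity non-uniformity, imperfect
registration, or pathology. A green phantom-recovery test establishes
that the trained classifier transfers from blur-contrast training pairs
to structure-vs-smooth test content and that the two refinement stages
preserve that decision — not that the method reaches clinical quality
on hospital data.

## Metrics

The four scores follow the standard constructions: raw spatial
frequency of the fused image on the 0–255 scale; the Piella–Heijmans
weighted quality index Q_W (Wang–Bovik Q0 over sliding 8×8 windows,
variance saliency, degenerate windows counted as perfect only when the
window pair is identical, otherwise skipped and logged); Hossny's
entropy-normalized mutual information with 256 bins (base-independent);
and the Chen–Varshney measure with Mannos–Sakrison CSF
H(ρ) = 2.6(0.0192 + 0.114ρ)exp(−(0.114ρ)^1.1), 16×16 regions,
gradient-energy saliency, and the Nyquist frequency mapped to 30
cycles/degree (configurable — published implementations differ in all
three of region size, saliency exponent and viewing geometry, so
absolute Q_CV values are comparable only within one configuration).
All metrics are computed on luma for color images.

## Numerical choices and degenerate inputs

- Images live in float64 [0, 1]; files are 8-bit PNG with
  round-to-nearest quantization (round-trip error ≤ 1/255).
- Difference images are signed and unclipped.
- Replicate padding for all windowed decision operations; reflect
  padding for the scoring patches (replicating would bias border
  patches toward their edge row).
- Odd pooling inputs drop the trailing row/column.
- Morphology border convention: erosion pads with 1, dilation with 0
  (the padding is then absorbing, never structure-creating); this
  matches scikit-image, which the tests use as an independent oracle.
- Constant images: spatial frequency is 0; mutual information terms for
  constant pairs are defined as 1 when identical, 0 otherwise; Piella
  and Chen–Varshney raise a `MetricError` when *no* window/region is
  informative rather than return a number that means nothing.

## Known limitations

- The stride-4 score grid can misplace decision boundaries by up to 2
  px; exact mode removes this at ~16× cost.
- The classifier compares local information content, not semantics: if
  both sources are informative at the same pixel (which the phantom
  generator deliberately avoids), the winner is whichever looks locally
  richer to random features.
- With two colored sources, chrominance follows the luminance decision
  per pixel, which can produce hue seams along decision boundaries.
- Training and inference patches are drawn from different distributions
  (blurred textures vs. anatomy-like structures); the transfer works on
  the phantom family but is not guaranteed for arbitrary content.
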