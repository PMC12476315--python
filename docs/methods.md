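# Methods

`lesionseg` studies a single scientific question at library scale: does
fusing lesion-level clinical metadata into the bottleneck of a U-Net improve
dermoscopic segmentation accuracy and reduce predictive uncertainty?  This
note documents the model, the uncertainty machinery, the synthetic data the
package is exercised on, and the numerical and design choices behind them.

## Segmentation model

The image path is a standard U-Net.  Each encoder block applies two 3×3
same-padding convolutions with ReLU, followed by 2×2 max pooling; channel
widths double per block (default 64→128→256→512).  The bottleneck consists
of two 3×3 convolutions at 1024 channels.  For a 224×224×3 input the latent
map is 7×7×1024: after the four width-doubling pools an extra,
width-preserving max pool halves 14→7.  The decoder mirrors the encoder —
a parameter-free nearest 2× upsample undoes the extra pool, then four
blocks of 2×2 stride-2 transposed convolution (halving channels), skip
concatenation with the same-resolution encoder features, and two 3×3
convolutions.  A 1×1 convolution with sigmoid yields per-pixel lesion
probabilities.  Because all convolutions preserve spatial size, the skip
"crop-and-copy" degenerates to a plain copy (a center-crop guard remains
for non-standard configurations).

Rationale for the extra pool: a classic four-pool U-Net bottoms out at
14×14 for 224 input, while a five-double-pool variant would hold ~39M
parameters.  The parameter-free fifth pool gives a 7×7 latent *and* keeps
the trainable budget at 31.0M (31,037,798 with the default metadata branch)
— both properties of the reference design.

### Metadata branch and fusion

The metadata vector has 29 one-hot/binary entries laid out by a
user-overridable schema.  The default schema covers: diagnosis (3),
asymmetry (3), pigment network (3), dots/globules (3), streaks (3),
regression (3), blue-whitish veil (2), border irregularity (3) and six
binary colour flags.  Each attribute group is embedded by a lookup table
(4-dimensional per group by default; binary flags use 2-row tables); the
embeddings are concatenated and passed through dense layers of 36 and s²
units with ReLU (s² = 49 for the 7×7 latent; the second width generalizes
to other latent sizes), then reshaped to s×s×1.

Four fusion strategies are implemented at the bottleneck:

| strategy | operation |
|---|---|
| `embedding_concat` (default) | channel concatenation → 7×7×1025 |
| `onehot_dense` | raw 29-vector through the dense layers, then concatenated |
| `weighted(w_img, w_meta)` | w_img·F_latent + w_meta·M_embed broadcast over channels, w_img+w_meta = 1 |
| `none` | image-only U-Net |

`weighted(1, 0)` reproduces the image-only network exactly, which the test
suite uses as a structural identity.

### Bayesian variant

With `bayesian=True` a dropout layer follows every two-convolution block
(encoder, bottleneck, decoder).  The rate defaults to 0.5 at reference
scale; the reduced desk-scale configuration uses 0.1, since small networks
at rate 0.5 lose too much capacity.  Dropout is parameter-free, so the
Bayesian flag never changes the parameter count.

## Training

Adam (β₁ = 0.9, β₂ = 0.999), pixel-mean binary cross-entropy or the
soft-Jaccard surrogate

    L_IoU = 1 − (Σ p·y + ε) / (Σ p + Σ y − Σ p·y + ε),   ε = 1,

validation loss after every epoch, best-weights checkpointing, early
stopping (default patience 20, stop after `patience` consecutive
non-improving epochs), and paired augmentation: one random draw from
{identity, horizontal/vertical flip, rotation 90/180/270°, scale in
[0.9, 1.1] with crop/pad} applied identically to image and mask.  All 29
metadata attributes are geometric invariants of these transforms, so the
metadata vector passes through unchanged while staying paired with the
transformed image.  Reference-scale defaults: learning rate 1e-4, batch 16,
up to 200 epochs.  Every source of randomness (init, shuffling, dropout,
augmentation) derives from explicit seeds; two runs with the same seed
produce identical histories bit for bit.

Overlap metrics binarize predictions at 0.5; IoU = |∩|/|∪| and
Dice = 2|∩|/(|A|+|B|), with the both-empty convention = 1.0 (a correct
empty prediction should not score 0/0).  Dice = 2·IoU/(1+IoU) holds
exactly and is property-tested.

## Uncertainty quantification

Monte Carlo Dropout: T = 10 stochastic forward passes with dropout active
at inference approximate sampling from the posterior predictive
distribution.  The sigmoid output is materialized as a two-class
distribution (p, 1−p) so the four pixel-wise estimators share one code
path (log base 2 everywhere — bounded, interpretable bits; the base
cancels under the min–max normalization below):

* confidence C = max_c p̄(c) of the pass-averaged distribution;
* predictive entropy H = −Σ_c p̄(c) log₂ p̄(c) (total uncertainty);
* mutual information MI = H(p̄) − mean_t H(p_t) (epistemic disagreement);
* EPKL = mean over ordered pass pairs of KL(p_i ‖ p_j).  The literal
  pairwise definition is the default; a `to_mean` variant (mean KL against
  the ensemble mean) is selectable by flag.

Probabilities are clipped at 1e-12 inside logarithms.  Per-image means of
the four maps are min–max normalized across the evaluation cohort being
reported (a degenerate cohort maps to 0), and combined into

    U_tot = α·C − β·H + γ·MI − δ·EPKL,  (α, β, γ, δ) = (0.4, 0.2, 0.2, 0.2).

The sign pattern is implemented exactly as printed in the source design:
the confidence term *raises* U_tot while entropy and EPKL lower it, so the
score is not monotone in "uncertainty" alone.  The ranking direction is
therefore an explicit configuration choice (`descending=True` by default),
and every report records its normalization cohort so that scores from
different cohorts can never be ranked together.

## Synthetic data

The generator emulates the structure — not the photorealism — of
dermoscopic segmentation datasets: a single lesion (ellipse deformed by
low-frequency radial cosine noise) on smoothed-noise skin-textured
background; the binary mask is the exact region indicator *before* edge
blurring, so supervision stays clean even when the rendered boundary is
soft.  Metadata attributes are rendered as localized additive textures
(reticular grid, dark dots, radial spokes crossing the boundary, pale
regression patches, blue tint, colour shifts), while asymmetry and border
irregularity modulate the radial shape spectrum and diagnosis follows a
PH2-like prevalence (0.4/0.4/0.2).  Each renderer draws from its own
random substream, so toggling one metadata attribute changes pixels only
inside that renderer's support — the property that makes the
metadata→pixel coupling directly testable.  Defaults: lesion radius
0.22–0.42 of the image side, boundary blur σ_b = 1 px, contrast 0.4,
sensor noise σ = 0.03, datasets of 200 images at 224×224 (the PH2 scale).

What the generator does **not** emulate: hair and ruler artifacts,
multi-lesion images, camera vignetting, and the long-tailed appearance
variability of real dermoscopy.  Passing tests therefore demonstrate that
the implementation realizes the intended mechanisms, not that the model
would reach any particular accuracy on clinical data.

### The ambiguous task

`make_ambiguous_task` builds the setting where metadata is *necessary*,
not merely helpful: contrast is clamped to ≤ 0.12–0.15, boundary blur is
raised to σ_b ≥ 2, and every image contains the lesion plus a same-sized
distractor blob, with the diagnosis metadata deciding which blob is the
lesion.  Two rules are implemented:

* **side** (default): lesion and distractor look identical; melanoma
  lesions sit in the left image half, non-melanoma in the right, with the
  distractor mirrored.  The metadata branch can express this as a spatial
  prior over the latent map — a first-order interaction that small
  networks learn reliably.
* **sign**: the lesion is darker than background iff melanoma and the
  distractor carries the opposite offset.  Resolving it requires a global
  appearance×metadata gating; the Bayes-level separation holds (the tests
  evaluate the closed-form intensity discriminant with and without the
  metadata), but in practice gradient descent on desk-scale U-Nets finds
  the gating only sporadically and late, so this rule is kept for
  analysis rather than as the default benchmark.

Under either rule an image-only classifier — including the Bayes-optimal
intensity rule — cannot distinguish lesion from distractor and at best
labels both blobs (IoU ≈ 0.5 ceiling).  Texture attributes are set to
"absent" on this task: any overlay rendered only on the true lesion would
leak its identity through pixels and defeat the construction.  Diagnosis
prevalence is rebalanced to 0.25/0.25/0.5 so both cases appear at
comparable rates.

## Desk-scale experiment design

The reference 224×224 configuration is audited symbolically (layer table,
parameter counts) and by a single forward pass; training experiments run
on reduced configurations chosen once:

* **trainability**: 32×32 images, widths (8, 16), bottleneck 32, soft-IoU
  loss, learning rate 3e-3, 60 training images, 30 epochs — reaches
  validation IoU ≥ 0.8 on most seeds.
* **metadata benefit**: the ambiguous task (side rule) at 32×32 (90
  images, lesion radius 0.15–0.22, noise 0.01, per-image min–max contrast
  stretch as preprocessing), a two-pool network with widths (16, 32),
  bottleneck 64 at an 8×8 latent, Bayesian dropout 0.1, learning rate
  1e-3, 60 epochs, identical recipes for the embedding-concat and
  image-only models across 3 seeds; compared on mean test IoU and on
  cohort-mean C/H/MI/EPKL from T = 10 MCD passes.  Typical outcome:
  fused ≈ 0.74 mean test IoU vs ≈ 0.40 image-only, with lower entropy,
  mutual information and EPKL and higher confidence for the fused model.

The desk recipes differ from the reference hyperparameters (1e-4, 200
epochs) because a 32-pixel task trained for minutes needs a proportionally
larger step size; both models in any comparison always share the recipe.

## Numerical choices

* The network stack (reverse-mode autodiff, im2col GEMM convolutions,
  transposed convolutions as pure reshuffles for kernel = stride = 2,
  Adam, dropout, embeddings) is implemented on numpy and verified against
  central finite differences.  For same-padding stride-1 convolutions the
  input gradient is computed as a convolution with the transposed,
  180°-rotated kernel, sharing the forward GEMM path.
* Engine dtype is float32 (standard for CNN training, twice the CPU BLAS
  throughput); `set_default_dtype(np.float64)` switches the engine, which
  the gradient-check tests use.  Runs are bit-reproducible in either
  precision.
* Max-pool gradients split ties evenly (ties have measure zero under
  random init); BCE clips probabilities at 1e-7; uncertainty estimators
  clip at 1e-12 inside logs.
* He-uniform initialization for conv/dense, uniform(−0.05, 0.05) for
  embeddings; backbone layers are initialized before the metadata branch
  from one seeded generator, so configurations differing only in fusion
  strategy share identical backbone initial weights at equal seeds.
* Dataset splits use a seeded shuffle plus largest-remainder rounding
  (deterministic, sizes sum exactly; 200 ids at 70:10:20 → 140/20/40).
* Mask binarization on read divides by the mask's own maximum before
  thresholding at 0.5, robust to 0/255 and 0/1 encodings.
* Summary tables report population standard deviation (switchable to
  sample sd); percentages are rounded to two decimals.

## Known limitations

* The numpy engine trains minutes-scale models; the reference 224×224
  configuration is audited structurally, not trained.
* Min–max normalization ties U_tot to its cohort: scores are comparable
  only within one report, by construction.
* The generator's attribute renderers are stylized; per-attribute IoU
  breakdowns on synthetic data show the reporting machinery, not clinical
  difficulty patterns.
* Only binary (single-channel) segmentation heads are supported.
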