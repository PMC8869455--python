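# Methods

## The model

`edgan` implements a three-stage generative-augmentation pipeline for
class-labeled 2-D grayscale tumor slices (glioma / meningioma /
pituitary):

1. **VAE.** An encoder maps an image x to the parameters (μ, log σ²) of
   a Gaussian approximate posterior q(z|x); a decoder maps latent
   vectors back to pixel space. Training minimizes the negative
   evidence lower bound
   L = −E_{z∼q(z|x)}[log p(x|z)] + KL(q(z|x) ‖ N(0, I)),
   with the KL term in closed form,
   KL = −½ Σᵢ (1 + log σᵢ² − μᵢ² − σᵢ²).
   The reconstruction likelihood is pixel-wise Bernoulli cross-entropy
   on [0,1] intensities (MSE available via `likelihood="mse"`); the
   paper-style formulation never fixes this choice, and Bernoulli is
   the standard for image VAEs.

2. **Decoder–encoder swap ("informative noise").** After training, the
   two halves are applied in reverse: z ∼ N(0, I) → decoder → x̃ →
   encoder → z̃ (posterior mean). The resulting z̃ vectors live on the
   latent image manifold rather than being isotropic: their coordinate
   variances deviate strongly from 1 (measured ≈ 0.6 mean absolute
   deviation on the fixture, versus ≈ 0.02 for a same-size Gaussian
   control). The posterior *mean* is used for determinism; a
   reparameterized sampling mode exists (`sample_posterior=True`).
   Noise is streamed per GAN minibatch rather than precomputed.

3. **Conditional GAN.** A generator consumes (noise ⊕ one-hot label)
   and a discriminator scores (image, label) pairs; the value function
   is the standard min-max form
   min_G max_D E[log D(x|c)] + E[log(1 − D(G(z|c)|c))],
   trained with alternating single D/G steps and the non-saturating
   generator loss (maximize log D(G(z|c)|c)) — the usual stabilization
   of the literal min form. The GAN's input noise comes from the
   informative-noise stream; a `gaussian` mode is the ablation
   baseline.

The downstream experiment trains a residual CNN classifier on scarce
real (phantom) data with and without generated images concatenated to
the training set and compares macro-F1.

## Architecture builders vs. trainable networks

Two network families coexist:

* **Full-scale declarative specs** (`build_generator("paper")`,
  `build_discriminator("paper")`) reproduce a published 256×256 DCGAN
  layout exactly at the parameter-count level: generator
  dense 100→1,310,720 (132,382,720 parameters), reshape 32×32×1280,
  three stride-2 kernel-4 transposed convolutions with 1280 filters
  (26,215,680 each), final kernel-32 convolution to one channel
  (1,310,721); total 212,340,481. Discriminator: stride-2 kernel-3
  convolutions 128/64/32 (1,280 / 73,792 / 18,464), dropout, flatten,
  dense→1 (32,769); total 126,305. Several hyperparameters (noise
  width 100, transposed-conv kernel 4, discriminator kernel 3, final
  kernel 32) are not printed anywhere and were each inferred as the
  unique value consistent with the printed shapes and counts. The
  kernel-32 output convolution is unusual; a conventional head is
  available via `final_kernel=3`, but only kernel 32 reproduces the
  printed count. These totals describe the *unconditional* pair;
  `conditional=True` widens the input (one-hot at the generator input,
  a second image channel at the discriminator), which necessarily adds
  label parameters.
* **Trainable desk-scale networks.** Everything that actually trains in
  the test suite runs on one CPU, so the adversarial pair used for
  experiments is an MLP generator/discriminator (an admissible GAN
  parameterization) at side 32 with hidden width 256, and the VAE is a
  mirrored single-hidden-layer MLP (width 256, latent dimension 16).
  The numpy layer framework (`edgan.nn`) implements dense, conv,
  transposed-conv, residual, activation, and dropout layers with exact
  backpropagation (finite-difference verified) and Adam, so conv
  topologies are trainable too — they are simply too slow on one CPU
  for the adversarial experiments.

## Conditioning details

The generator receives the one-hot class label concatenated to its
noise vector. For convolutional discriminator specs the label enters as
a constant channel map (input 256×256×2 / 64×64×2). For the trainable
MLP discriminator two choices matter in practice and were adopted after
the plain concatenation failed to bind labels at desk scale:

* the label block is a **repeated one-hot** (32 copies per class)
  rather than a single graded level — orthogonal label directions give
  the discriminator a much faster-learnable conditioning signal;
* **mismatched-label real pairs** (a real image with a wrong label) are
  fed to the discriminator as negatives alongside fakes (the
  matching-aware discriminator of Reed et al., 2016). This is what
  forces D — and therefore G — to respect the condition.

A consequence of the mismatch negatives is that the discriminator's
batch is one-third real, so its blind-guess output level is 1/3 and the
healthy-training equilibrium for mean D(fake) sits near 0.18 (measured
0.179–0.189 across seeds), not 0.5. The training-health regression
band is frozen at D(fake) ∈ (0.05, 0.8), D(real) ∈ (0.2, 0.95).

## The phantom generator

Real contrast-enhanced MRI slices are not redistributable, so all
experiments run on synthetic phantoms emulating the gross structure a
slice classifier uses: a bright elliptical skull rim (jittered center
and axes), smooth low-amplitude interior texture, and one
class-dependent lesion:

* **pituitary** — small compact bright blob near the base midline;
* **meningioma** — lens-shaped blob pressed against the inner rim,
  restricted to the superior arc (the typical convexity/parasagittal
  location); the restriction also keeps the class identifiable at the
  coarse resolution a desk-scale generator achieves;
* **glioma** — larger, irregular, 3–5-lobed heterogeneous mass in one
  hemisphere.

Class appearance is location- and scale-coded strongly enough that a
nearest-centroid rule on a 9-feature lesion summary reaches ≈ 98%
5-fold accuracy and a small residual CNN exceeds 90% held-out accuracy
(both tested). What the phantoms do **not** emulate: anatomy (gyri,
ventricles, midline structures), acquisition physics (bias fields,
noise spectra, partial-volume effects), inter-patient correlation
(every phantom is independent; there is no patient-level split
structure), or 3-D continuity across slices. Passing tests therefore
demonstrate that the mechanism works end-to-end on learnable image
classes, not that it reaches any particular accuracy on clinical data.

The dataset split is stratified per class: floor(0.6·n) training, the
remainder halved with the odd unit going to test. This is the unique
simple rounding rule consistent with a 60/20/20 division of class
totals 1426/708/930 into 855/285/286, 424/142/142, 558/186/186.

Classic augmentation is a random rotation (uniform 0–359°, bilinear,
zero fill) followed by isotropic rescaling (default range [0.9, 1.1])
cropped/padded back to the original side. Note that full-circle
rotation destroys the lesion-location coding of the phantom classes, so
on *phantom* data classic augmentation can hurt — an artifact of the
phantom design, not of the augmentation code.

## Default parameters

| parameter | default | why |
|---|---|---|
| image side (desk) | 32 px | smallest power of two the stride-2 stacks accept; keeps CPU runs in seconds |
| VAE latent dim | 16 | enough for the phantom manifold; swap diagnostics (rank > d/2) confirm no collapse |
| VAE training | 60 epochs, Adam 2e-3, batch 32 | converges on 180 phantoms in ~6 s |
| GAN hidden width | 256 | smallest width that reliably binds the label condition |
| GAN training | 1500 steps (fixture), Adam 2e-4, β₁ 0.5, batch 32 | DCGAN-style settings; 800 steps already saturate label fidelity |
| dropout (full-scale D) | 0.3 | the published table lists dropout without a rate |
| leaky-ReLU slope | 0.2 | standard DCGAN value |
| classifier | resnet-small: stride-2 stem, 3 residual stages (8/16/32 ch), Adam, categorical cross-entropy, batch 50, lr 1e-4 | reference classifier settings; experiments use lr 2e-3 to converge in few epochs |

## Numerical choices

* Log-variance clipped to [−10, 10] before exponentiation; the clip is
  straight-through in the backward pass.
* Cross-entropy gradients are taken in logit space ((p − t)/B), never
  through log(sigmoid); probabilities clipped at 1e-12 only for loss
  *reporting*.
* `gan_value` rejects probabilities outside the open interval (0, 1)
  rather than returning ±inf.
* Rates with zero denominators are reported as 0 with a
  `DegenerateRateWarning`; reports carry a `degenerate` flag.
* Average accuracy is micro (trace/total, as a percent); displayed
  percentages are truncated, not rounded (72.6384 → "72.63"), matching
  how the reference values are printed. F1 is the harmonic mean of
  precision and recall.
* Argmax tie-break: lowest class index.
* All randomness flows through `numpy.random.Generator`; single-threaded
  runs are bit-reproducible, and the CLI derives per-stage seeds from
  one global seed by hashing.

## Experiment sizes (the package's own desk defaults)

* Fixture training set: 60 phantoms/class at side 32; VAE and GAN as
  above.
* Auxiliary scorer: residual CNN trained on 200 crisp + 200 blurred
  phantoms per class (Gaussian σ ∈ [0.5, 1.8]) so it stays calibrated
  on the smoother images a desk generator emits.
* Mode-coverage comparison: 10 seeds × {informative, gaussian} at a
  matched 800-step budget, 60 probe images/class.
* Augmentation benefit: 10 seeds; 15 real phantoms/class, 50 generated
  images/class, macro-F1 on 40 held-out phantoms/class.

## Known limitations

* The adversarial experiments use MLP networks at 32×32; conv GANs are
  buildable and trainable in the framework but not exercised
  adversarially in the tests.
* The inception-score scorer is the auxiliary phantom classifier, not
  an Inception network (any calibrated classifier is admissible for the
  score's definition); scores are comparable only within this package.
* Informative-noise and Gaussian-noise GANs both reach full class
  coverage at the desk operating point; the measured advantage of
  informative noise appears under tighter budgets and is reported as a
  directional (≥) comparison.
* The phantom generator's class coding is geometric; none of the
  results here transfer quantitatively to clinical MRI.
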