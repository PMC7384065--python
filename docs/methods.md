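# Methods

## The harmonization model

`dmriharm` treats multi-site diffusion-MRI harmonization as unsupervised
image-to-image translation through a site-invariant representation. Each
white-matter voxel's two-shell signal is summarized by spherical-harmonic
coefficients; a 7-voxel patch vector **x** (center voxel + six face
neighbors, 637 elements) is encoded by q(z|x) into a 32-dimensional
diagonal-Gaussian code z and decoded by p(x|z, s) conditioned on the one-hot
scanner/protocol label s. Invariance of z to s is induced by relaxing the
independence constraint z ⊥ s to the mutual information I(z, s) and
minimizing a variational bound on it: a conditional-reconstruction term
(already part of the conditional VAE objective) plus a compression term,
E_x KL[q(z|x) ‖ q(z)], where q(z) is the marginal (batch mixture) of the
code. At test time the site label fed to the decoder is swapped; by the data
processing inequality the harmonized reconstruction can carry no more site
information than z itself.

Key assumptions:

* site effects are patch-local (a fully connected patch architecture cannot
  remove long-range spatial biases);
* every site acquires the same two shells (b = 1200 and 3000 s/mm²), so a
  shared per-shell SH representation exists; direction counts may differ;
* no paired scans are needed for training — pairing is used only to
  *evaluate* harmonization.

## Signal representation

Shell signals are fitted in the real, antipodally symmetric (even-degree)
orthonormal SH basis of order 8 (45 coefficients per shell), columns ordered
l ascending, m from −l to l. Fits use the Moore–Penrose pseudo-inverse of the
basis matrix: for 30-direction shells (under-determined) this is the
minimum-ℓ2-norm exact interpolant, for ≥45 well-spread directions the
least-squares projection. Singular values below 1e-10 of the largest are
truncated, so degenerate direction sets degrade gracefully. The b0 channel
has no orientation and bypasses the basis entirely (identity pass-through);
multiple b0 volumes are aggregated by their mean. Each shell is fitted
independently (91 = 45 + 45 + 1 features per voxel). Signals are not
normalized by b0 before fitting (a global intensity-normalization option
exists for data whose raw scale is far from unity; the simulator emits
S0 ≈ 1, where it is a no-op).

Projection back to an arbitrary subject-specific scheme evaluates the basis
at that scheme's directions — this both produces outputs in each subject's
native representation and defines the "real-space" projection loss below.

## Objective

The primary network minimizes

L = L_recon + α·L_prior + β·L_proj − γ·L_adv + λ·L_marginal

with α = 1.0, β = 1.0, γ = 10.0, λ = 0.01, where

* **L_recon** — squared error between reconstruction and input patch in SH
  space;
* **L_prior** — KL[q(z|x) ‖ N(0, I)], closed form;
* **L_marginal** — the pairwise closed-form bound
  (1/N²) Σᵢⱼ KL[qᵢ ‖ qⱼ] ≥ (1/N) Σᵢ KL[qᵢ ‖ q(z)] (convexity of KL in its
  second argument), the tractable surrogate for the compression part of the
  I(z, s) bound;
* **L_proj** — squared error of the center voxel after projecting its SH
  coefficients onto the subject's own gradient directions (b0 passing
  through), against the raw per-direction signal;
* **L_adv** — softmax cross-entropy of a 2×32-unit tanh adversary reading the
  SH reconstruction (computed with the true site label); subtracting it
  trains the primary network to defeat the site classifier. The adversary
  itself is trained in alternation, minimizing the same cross-entropy.

Two sign/scale decisions deserve note:

1. **Sign of the λ term.** Written as a reward, the combined objective
  contains −λ·I(z, s); negating the bound into a *loss* makes the
  compression term enter with a **positive** sign. The printed loss with a
  minus sign in front of λ·I(z, s) is read as applying to the maximized
  bound; the minimized training loss adds λ·L_marginal. Implemented as
  +λ, with the equivalent interpretation documented here.
2. **Per-patch sums, not per-channel means.** The hyper-parameters above are
  described as putting the losses "approximately on the same order of
  magnitude". That balance only holds if L_recon and L_proj are summed over
  a patch's channels (batch-averaged), as a Gaussian log-likelihood would
  be: recon then sits at ~5–100, the projection loss ~2–50, the prior KL
  ~5–30 and γ·L_adv ≈ 7. Scored as full means instead, reconstruction is
  two orders of magnitude below the KL terms and the optimum is total
  posterior collapse — the decoder degenerates to a per-site mean predictor
  (we verified the collapsed reconstruction error equals the site-mean
  predictor's exactly). The training objective therefore defaults to
  `loss_scale="feature_sum"`; `"mean"` is available for experimentation.
  The *reported* metric operators (`recon_loss`, `proj_loss`, …) remain
  plain means.

The optional (1+λ) factor on the reconstruction term that a tight derivation
of the combined bound produces is exposed as a flag and off by default; at
λ = 0.01 it is negligible.

## Architecture and training

Encoder 637→256→128→64 (tanh) with a 32-unit Gaussian head: an affine mean
and a sigmoid variance gate, read as σ² = sigmoid(a) (σ ∈ (0, 1); the
alternative reading σ = sigmoid(a) is a config switch). Decoder mirrors it:
(32 + K)→64→128→256→637, linear output because SH coefficients are signed
and unbounded. Adversary: 637→32→32→K, tanh. Weights are fan-in-scaled
Gaussian (std 1/√fan_in), biases zero, from a seeded generator.

Training alternates per mini-batch (size 128, Adam, learning rate 1e-4):
one step on the full loss for the encoder/decoder, then 10 adversary steps
on the same batch with the reconstruction detached ("10 epochs for the
adversary per primary batch" is read as 10 gradient steps on that batch; a
full data pass per batch would be quadratic in the dataset). The two Adam
optimizers own disjoint parameter lists, so neither phase can move the other
network — asserted by parameter-hash tests. Batches mix patches from all
sites; per-site projection matrices handle the differing schemes. Sampling
uses the reparameterization z = μ + σ⊙ε. All randomness — init, shuffling,
ε — derives from the config seed, making training bit-reproducible.

The reference protocol trains for 1000 epochs; the package's desk-scale
default is 50 epochs, the setting used by every synthetic experiment here.
Ablations (`lambda0`, `lambda0_alpha0`) copy the config with λ (and α)
zeroed, everything else — including the seed — identical.

The networks are implemented on a small tape-based reverse-mode autodiff
over numpy (`dmriharm.autodiff`), sufficient for fully connected nets of
this size; every operator's gradient is tested against central finite
differences, as is the composite training loss.

## Synthetic multi-site data

The simulator emulates the structure of a two-scanner, two-protocol study:

* multi-tensor signal S = S0 Σₖ fₖ exp(−b gᵀDₖg) on the two shells;
* white-matter-like single-fiber tensors (eigenvalues 1.7/0.3/0.3 ×10⁻³
  mm²/s) in two oriented regions plus a central band of 90° crossings;
  per-voxel orientation jitter (up to 10°, seeded) makes every phantom
  unique;
* acquisition schemes from seeded antipodal electrostatic repulsion — 30 or
  60 directions per shell plus 4 b0 volumes, mirroring the low/high
  angular-resolution protocols;
* site biases: a multiplicative per-shell gain and Rician (or Gaussian)
  noise at a stated b0 SNR. With gain 1, infinite SNR and a shared scheme,
  two "sites" produce identical volumes (null-bias control); at low SNR and
  b = 3000 the Rician noise floor inflates the mean signal, a real
  high-b artifact.

The standard benchmark (`dmriharm.experiments`) uses a 16³ grid (14³ = 2744
in-mask voxels), site A = 30 directions with gain 1.1, site B = 60
directions with gain 0.9, both SNR 30, two training phantoms per site
("subjects"), and one held-out phantom simulated at both sites for paired
evaluation. Two training phantoms give the 50-epoch protocol roughly 4300
optimizer steps — enough to leave the collapsed regime; with a single
phantom the run stays collapsed throughout. The phantom count and grid size
are the problem sizes used by every experiment and test in the package.

What the phantoms do **not** emulate: spatially varying S0 or T2, gray
matter/CSF compartments, motion, eddy currents, susceptibility distortion,
gradient nonlinearity, or inter-subject anatomical variability. Passing
tests therefore demonstrate that the method removes gain/scheme/noise biases
of the simulated kind — not that it harmonizes any particular real dataset.

## Evaluation

* **RMSE maps** per voxel in the acquisition (DWI) representation.
* **APE / CV / PE** for any scalar measure (as decimals, 1.0 = 100%):
  mean |pred−truth|/|truth| (truths below 1e-6 excluded and counted), RMSE
  divided by the truth mean (relative RMSE; the finite-N correction factor
  is ~1 and omitted), and the signed variant (negative ⇔ truth larger). APE
  inflates when small truths are overestimated while CV stays bounded — the
  metric-divergence pattern the percent-error tables exhibit; a constructed
  test reproduces it.
* **DTI fit** (log-linear least squares) supplies FA/MD; non-positive
  signals are clamped at 1e-10 with a warning. Kurtosis- and
  propagator-based measures (MK, RTOP) are out of scope; the APE/CV/PE
  operators are measure-agnostic.
* **Angular deflection**: SH maxima found on a 724-point antipodally
  symmetric sphere grid, non-maximum suppression within 25°, Nelder–Mead
  refinement in spherical angles, peaks below 0.1× the global maximum
  discarded; each predicted peak is compared with the *closest* truth peak,
  antipodes folded (range 0–90°). When peak counts differ, the per-voxel
  minimum-angle match is reported.
* **Post-hoc adversary**: a fresh 2×32-unit tanh softmax classifier
  (scikit-learn's MLPClassifier with exactly that shape) trained on latent
  codes with a stratified 70/30 split; held-out accuracy near 1/K means the
  representation is site-invariant. The experiments feed *sampled* codes
  z = μ + σ⊙ε — the stochastic representation whose I(z, s) the objective
  bounds. (Classifying the deterministic posterior means instead measures a
  different quantity: any microscopic but systematic site offset in μ is
  perfectly separable regardless of the code's information content, which
  saturates the metric.)
* **ΔRMSE** = RMSE(regular) − RMSE(ablated), negative when the regular model
  is better.

## Numerical choices

| choice | value | rationale |
|---|---|---|
| shell-matching tolerance | 100 s/mm² | shells are nominal labels; real b-values scatter |
| pseudo-inverse cutoff | 1e-10 × σ_max | stated SVD solution, robust to degenerate schemes |
| APE truth floor | 1e-6 | excludes undefined relative errors; exclusions reported |
| peak threshold | 0.1 × global max | suppresses ringing lobes of order-8 fits |
| b0 aggregation | mean of b0 volumes | unbiased under the noise model |
| out-of-mask neighbors | zero-filled | fixed-size input without discarding boundary voxels |
| reassembly | center-voxel write | avoids overlap-averaging ambiguity (averaging variant available) |
| harmonization mode | posterior mean | deterministic harmonizer; `sample` mode available |
| one-hot site labels | K ≥ 2 always | uniform treatment of the two-site and multi-site cases |

## Limitations

* Patch-level fully connected networks: no long-range spatial context.
* The desk-scale protocol (16³ phantoms, 50 epochs) demonstrates mechanism,
  not clinical-grade harmonization; the latent code retains measurable site
  information when the compressive terms are ablated, and some when they are
  not.
* Only two-shell, SH-representable protocols are supported; no odd-order
  bases or q-space models.
* The adversary and post-hoc classifiers lower-bound site information —
  accuracy at chance does not prove independence.
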