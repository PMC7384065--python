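"""Multi-site diffusion-MRI phantoms with known ground-truth pairing.

Real multi-scanner studies differ in acquisition scheme (30 vs 60 directions
per shell), signal gain and noise level.  This module simulates that setting
with a multi-tensor forward model

    S(b, g) = S0 * sum_k f_k * exp(-b * g^T D_k g)

on the two standard shells (b = 1200 and 3000 s/mm^2), producing *paired*
volumes: the same underlying tissue observed through each site's scheme, gain
and noise.  Training data are deliberately unpaired (patches from each site
separately); pairing is retained only for evaluation, mirroring how a
traveling-subject validation set would be used.

White-matter-like defaults: single-fiber tensors with eigenvalues
(1.7, 0.3, 0.3) x 1e-3 mm^2/s and a central band of 90-degree crossings, so
orientation-sensitive metrics (angular deflection) are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import DWIVolume
from .sh import GradientScheme, ShellTable
from .sphere import electrostatic_directions

__all__ = [
    "SiteProfile",
    "PhantomSpec",
    "tensor_signal",
    "make_scheme",
    "make_crossing_phantom",
    "generate_site_volume",
    "make_benchmark",
    "Benchmark",
]

WM_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)  # mm^2/s, white-matter-like


@dataclass(frozen=True)
class SiteProfile:
    """One scanner/protocol context: scheme plus gain and noise biases."""

    name: str
    scheme: GradientScheme
    gain: tuple = (1.0, 1.0)  # multiplicative bias per shell, scheme order
    snr: float = np.inf  # signal-to-noise ratio at b0
    noise_model: str = "rician"

    def __post_init__(self):
        if any(g <= 0 for g in self.gain):
            raise ValueError("gains must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class PhantomSpec:
    """Voxel grid of multi-tensor tissue models.

    fractions: (X, Y, Z, n_comp) volume fractions, summing to 1 in-mask.
    tensors:   (X, Y, Z, n_comp, 3, 3) diffusion tensors in mm^2/s.
    s0:        (X, Y, Z) non-diffusion-weighted signal.
    mask:      (X, Y, Z) boolean analysis mask.
    """

    fractions: np.ndarray
    tensors: np.ndarray
    s0: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        f = self.fractions[self.mask]
        if np.any(f < 0) or not np.allclose(f.sum(axis=-1), 1.0, atol=1e-8):
            raise ValueError("volume fractions must be >= 0 and sum to 1 in-mask")
        evals = np.linalg.eigvalsh(self.tensors[self.mask])
        if np.any(evals < -1e-12):
            raise ValueError("tensor eigenvalues must be non-negative")


def tensor_signal(b, g, fractions, tensors, s0=1.0):
    """Multi-tensor signal S = S0 * sum_k f_k exp(-b g^T D_k g).

    `b` and `g` may be arrays of N acquisition entries; fractions/tensors may
    carry leading voxel dimensions.  Returns the broadcast signal array.
    """
    b = np.asarray(b, dtype=float)
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    norms = np.linalg.norm(g, axis=-1)
    if np.any((b > 0) & (np.abs(norms - 1.0) > 1e-6)):
        raise ValueError("diffusion-weighted directions must be unit norm")
    fractions = np.asarray(fractions, dtype=float)
    tensors = np.asarray(tensors, dtype=float)
    # quadratic form g^T D g for each entry and component
    gdg = np.einsum("ni,...kij,nj->...kn", g, tensors, g)
    att = np.exp(-b * gdg)  # (..., n_comp, N)
    sig = np.einsum("...k,...kn->...n", fractions, att)
    return np.asarray(s0)[..., None] * sig


def _single_fiber_tensor(direction: np.ndarray,
                         eigenvalues=WM_EIGENVALUES) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # complete an orthonormal frame around the fiber axis
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    lam = eigenvalues
    return lam[0] * np.outer(d, d) + lam[1] * np.outer(e1, e1) + lam[2] * np.outer(e2, e2)


def make_scheme(n_directions: int, seed: int, n_b0: int = 4,
                shells=(1200.0, 3000.0)) -> GradientScheme:
    """Two-shell scheme: `n_b0` b0 entries plus `n_directions` per shell."""
    bvals = [0.0] * n_b0
    bvecs = [[0.0, 0.0, 0.0]] * n_b0
    for i, b in enumerate(shells):
        dirs = electrostatic_directions(n_directions, seed=seed * 97 + i)
        bvals.extend([b] * n_directions)
        bvecs.extend(dirs.tolist())
    bvals = np.array(bvals)
    bvecs = np.array(bvecs)
    return GradientScheme(bvals, bvecs, bvals == 0.0)


def make_crossing_phantom(shape=(16, 16, 16), seed: int = 0,
                          orientation_jitter_deg: float = 10.0,
                          eigenvalues=WM_EIGENVALUES) -> PhantomSpec:
    """Fiber phantom: x-fibers, y-fibers, and a central 90-degree crossing band.

    Per-voxel fiber orientations are jittered by a seeded random rotation of up
    to `orientation_jitter_deg`, so phantoms built from different seeds share
    structure but differ voxel-wise (distinct train/test tissue).
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    fractions = np.zeros(shape + (2,))
    tensors = np.zeros(shape + (2, 3, 3))
    s0 = np.ones(shape)
    mask = np.zeros(shape, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True  # exclude a 1-voxel border

    third = max(1, nx // 3)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                u = _jitter(np.array([1.0, 0.0, 0.0]), rng, orientation_jitter_deg)
                v = _jitter(np.array([0.0, 1.0, 0.0]), rng, orientation_jitter_deg)
                if i < third:  # x-fiber region
                    fractions[i, j, k] = (1.0, 0.0)
                elif i >= nx - third:  # y-fiber region
                    fractions[i, j, k] = (0.0, 1.0)
                else:  # crossing band
                    fractions[i, j, k] = (0.5, 0.5)
                tensors[i, j, k, 0] = _single_fiber_tensor(u, eigenvalues)
                tensors[i, j, k, 1] = _single_fiber_tensor(v, eigenvalues)
    return PhantomSpec(fractions, tensors, s0, mask)


def _jitter(direction: np.ndarray, rng: np.random.Generator,
            max_deg: float) -> np.ndarray:
    if max_deg <= 0:
        return direction
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    # Rodrigues rotation
    d = direction
    return (d * np.cos(angle) + np.cross(axis, d) * np.sin(angle)
            + axis * (axis @ d) * (1.0 - np.cos(angle)))


def noise_free_signals(phantom: PhantomSpec, scheme: GradientScheme,
                       gain: tuple = (1.0, 1.0),
                       table: ShellTable = ShellTable()) -> np.ndarray:
    """4-D noise-free signal array on `scheme`, with per-shell gain applied."""
    from .sh import group_shells

    groups = group_shells(scheme, table)
    shape = phantom.s0.shape
    data = np.zeros(shape + (len(scheme),))
    flat_f = phantom.fractions.reshape(-1, phantom.fractions.shape[-1])
    flat_t = phantom.tensors.reshape(-1, *phantom.tensors.shape[-3:])
    flat_s0 = phantom.s0.reshape(-1)
    sig = tensor_signal(scheme.bvals, np.where(scheme.b0_mask[:, None],
                                               [[0.0, 0.0, 1.0]], scheme.bvecs),
                        flat_f, flat_t, flat_s0)
    # b0 entries: direction irrelevant since b=0 makes attenuation 1
    data = sig.reshape(shape + (len(scheme),))
    for shell_i, b in enumerate(table.nominal_bvalues):
        if b in groups:
            data[..., groups[b]] *= gain[shell_i]
    return data


def generate_site_volume(phantom: PhantomSpec, profile: SiteProfile,
                         seed: int, table: ShellTable = ShellTable(),
                         noise_free: bool = False) -> DWIVolume:
    """Simulate `phantom` as observed at `profile`'s site.

    The same phantom passed with different profiles yields paired ground
    truth.  Noise sigma is mean in-mask S0 divided by the profile SNR.
    """
    data = noise_free_signals(phantom, profile.scheme, profile.gain, table)
    if not noise_free and np.isfinite(profile.snr):
        rng = np.random.default_rng(seed)
        sigma = float(phantom.s0[phantom.mask].mean()) / profile.snr
        if profile.noise_model == "gaussian":
            data = data + rng.normal(0.0, sigma, data.shape)
        else:  # rician: magnitude of complex Gaussian noise around the signal
            re = data + rng.normal(0.0, sigma, data.shape)
            im = rng.normal(0.0, sigma, data.shape)
            data = np.sqrt(re**2 + im**2)
    return DWIVolume(data=data, scheme=profile.scheme, mask=phantom.mask,
                     affine=np.eye(4))


@dataclass
class Benchmark:
    """Unpaired training volumes per site plus paired held-out test volumes."""

    profiles: list
    train_volumes: dict  # site name -> list of DWIVolume (noisy, train phantoms)
    test_volumes: dict  # site name -> DWIVolume (noisy, test phantom)
    test_truth: dict  # site name -> DWIVolume (noise-free, test phantom)
    site_names: list = field(init=False)

    def __post_init__(self):
        self.site_names = [p.name for p in self.profiles]


def make_benchmark(profiles, shape=(16, 16, 16), seed: int = 0,
                   n_train: int = 2,
                   table: ShellTable = ShellTable()) -> Benchmark:
    """Build train/test phantoms and simulate them at every site.

    `n_train` phantoms act as the training subjects (the real study pools
    several subjects per site); one further phantom is held out as the paired
    test subject.  Every phantom uses its own seed (distinct voxel-wise
    orientations), so held-out evaluation never sees training tissue.
    """
    train_phantoms = [make_crossing_phantom(shape, seed=seed * 17 + 3 * t + 1)
                      for t in range(n_train)]
    test_phantom = make_crossing_phantom(shape, seed=seed * 17 + 2)
    train_volumes, test_volumes, test_truth = {}, {}, {}
    for i, prof in enumerate(profiles):
        train_volumes[prof.name] = [
            generate_site_volume(ph, prof, seed=seed * 101 + 7 * t + i,
                                 table=table)
            for t, ph in enumerate(train_phantoms)
        ]
        test_volumes[prof.name] = generate_site_volume(
            test_phantom, prof, seed=seed * 211 + i, table=table)
        test_truth[prof.name] = generate_site_volume(
            test_phantom, prof, seed=0, table=table, noise_free=True)
    return Benchmark(list(profiles), train_volumes, test_volumes, test_truth)
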