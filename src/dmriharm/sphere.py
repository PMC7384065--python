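"""Unit-sphere point sets: Fibonacci lattices and electrostatic-repulsion
gradient schemes.

Acquisition schemes in multi-shell dMRI spread directions by minimizing a
Coulomb-like energy over antipodal point pairs; `electrostatic_directions`
reproduces that construction deterministically from a seed so simulated
"sites" get realistic 30- or 60-direction tables.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fibonacci_sphere", "symmetrized_sphere", "electrostatic_directions"]


def fibonacci_sphere(n: int) -> np.ndarray:
    """`n` near-uniform unit vectors from the Fibonacci lattice."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def symmetrized_sphere(n_hemisphere: int = 362) -> np.ndarray:
    """Antipodally symmetric grid: lattice points plus their negations."""
    pts = fibonacci_sphere(n_hemisphere)
    return np.concatenate([pts, -pts], axis=0)


def electrostatic_directions(n: int, seed: int = 0, n_iter: int = 200,
                             step: float = 0.05) -> np.ndarray:
    """`n` diffusion directions by antipodal Coulomb repulsion.

    Starts from a seeded random rotation of the Fibonacci lattice and descends
    the energy sum_{i<j} (1/|v_i - v_j| + 1/|v_i + v_j|) with per-iteration
    step normalization, reprojecting onto the sphere each step.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    # seeded random rotation (QR of a Gaussian matrix) of a well-spread start
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    v = fibonacci_sphere(n) @ q.T
    eye = np.eye(n, dtype=bool)
    for _ in range(n_iter):
        diff = v[:, None, :] - v[None, :, :]
        summ = v[:, None, :] + v[None, :, :]
        d1 = np.maximum(np.linalg.norm(diff, axis=-1), 1e-9)
        d2 = np.maximum(np.linalg.norm(summ, axis=-1), 1e-9)
        d1[eye] = np.inf
        d2[eye] = np.inf
        # energy gradient of the 1/d terms w.r.t. v_i
        g = (-diff / d1[..., None] ** 3 - summ / d2[..., None] ** 3).sum(axis=1)
        gmax = np.linalg.norm(g, axis=1).max()
        v = v - step * g / (gmax + 1e-12)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v
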