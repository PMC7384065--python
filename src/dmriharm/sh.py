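"""Even-order real spherical-harmonic representation of shell signals.

Diffusion-weighted signals are antipodally symmetric, so only even-degree
harmonics are used.  The basis here is the real, orthonormal one: for degree
``l`` and order ``m``,

    Y_lm = Y_l^0                       for m == 0
         = sqrt(2) * (-1)^m * Re(Y_l^m)  for m > 0
         = sqrt(2) * (-1)^m * Im(Y_l^|m|)  for m < 0

with the complex harmonics in the physics convention (Condon-Shortley phase,
orthonormal on the sphere).  Coefficient vectors are ordered with ``l``
ascending (0, 2, 4, ...) and, within each degree, ``m`` from ``-l`` to ``l``;
an 8th-order basis has 45 coefficients.

Fitting uses the Moore-Penrose pseudo-inverse of the design matrix: for
under-determined direction sets (fewer directions than coefficients) this is
the minimum-l2-norm exact interpolant, for over-determined sets the
least-squares fit.  b0 channels are orientation-free and bypass the basis
entirely (identity pass-through).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "GradientScheme",
    "SHBasisSpec",
    "ShellTable",
    "real_sh",
    "sh_index_list",
    "design_matrix",
    "fit_sh",
    "project_sh",
    "pass_through_b0",
    "group_shells",
    "read_bvals_bvecs",
]

_UNIT_TOL = 1e-6
_PINV_RCOND = 1e-10  # relative singular-value cutoff for degenerate schemes


@dataclass(frozen=True)
class GradientScheme:
    """Per-scan acquisition geometry: b-values, directions, b0 flags."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (N, 3), unit norm for diffusion-weighted entries
    b0_mask: np.ndarray  # boolean, True where b ~ 0
    allow_no_b0: bool = False

    def __post_init__(self):
        object.__setattr__(self, "bvals", np.asarray(self.bvals, dtype=float))
        object.__setattr__(self, "bvecs", np.asarray(self.bvecs, dtype=float))
        object.__setattr__(self, "b0_mask", np.asarray(self.b0_mask, dtype=bool))
        n = len(self.bvals)
        if self.bvecs.shape != (n, 3) or len(self.b0_mask) != n:
            raise ValueError("bvals, bvecs and b0_mask lengths must agree")
        dw = ~self.b0_mask
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("non-b0 b-vectors must be unit norm (tol 1e-6)")
        if not self.b0_mask.any() and not self.allow_no_b0:
            raise ValueError(
                "scheme has no b0 entry; pass allow_no_b0=True to accept this"
            )

    def __len__(self) -> int:
        return len(self.bvals)

    @classmethod
    def from_bvals_bvecs(cls, bvals, bvecs, b0_threshold: float = 50.0, **kw):
        bvals = np.asarray(bvals, dtype=float)
        return cls(bvals, np.asarray(bvecs, dtype=float), bvals <= b0_threshold, **kw)


@dataclass(frozen=True)
class SHBasisSpec:
    """Maximum even degree of the basis; order 8 gives 45 coefficients."""

    max_order: int = 8

    def __post_init__(self):
        if self.max_order < 0 or self.max_order % 2:
            raise ValueError("max_order must be an even non-negative integer")

    @property
    def n_coeffs(self) -> int:
        return sum(2 * l + 1 for l in range(0, self.max_order + 1, 2))


@dataclass(frozen=True)
class ShellTable:
    """Nominal shell b-values and the matching tolerance (s/mm^2)."""

    nominal_bvalues: tuple = (1200.0, 3000.0)
    tolerance: float = 100.0

    def __post_init__(self):
        vals = tuple(float(b) for b in self.nominal_bvalues)
        object.__setattr__(self, "nominal_bvalues", vals)
        if any(b <= 0 for b in vals) or len(set(vals)) != len(vals):
            raise ValueError("nominal b-values must be positive and distinct")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


def sh_index_list(max_order: int) -> list[tuple[int, int]]:
    """Fixed (l, m) column ordering: l ascending, m from -l to l."""
    return [(l, m) for l in range(0, max_order + 1, 2) for m in range(-l, l + 1)]


def _to_angles(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, y, z = directions[..., 0], directions[..., 1], directions[..., 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar
    phi = np.arctan2(y, x)
    return theta, phi


def real_sh(l: int, m: int, direction) -> float:
    """Real orthonormal SH basis value at a unit direction; even l only."""
    if l % 2:
        raise ValueError("odd degrees are excluded (dMRI signals are antipodal)")
    if abs(m) > l:
        raise ValueError("|m| must not exceed l")
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > _UNIT_TOL:
        raise ValueError("direction must be unit norm")
    theta, phi = _to_angles(direction)
    if m == 0:
        return float(np.real(sph_harm_y(l, 0, theta, phi)))
    y = sph_harm_y(l, abs(m), theta, phi)
    val = np.real(y) if m > 0 else np.imag(y)
    return float(np.sqrt(2.0) * (-1.0) ** abs(m) * val)


def design_matrix(directions, spec: SHBasisSpec = SHBasisSpec()) -> np.ndarray:
    """Basis evaluation matrix, shape (n_directions, n_coeffs)."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.size == 0:
        raise ValueError("empty direction list")
    norms = np.linalg.norm(directions, axis=1)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        raise ValueError("all directions must be unit norm")
    theta, phi = _to_angles(directions)
    cols = []
    for l, m in sh_index_list(spec.max_order):
        if m == 0:
            cols.append(np.real(sph_harm_y(l, 0, theta, phi)))
        else:
            y = sph_harm_y(l, abs(m), theta, phi)
            part = np.real(y) if m > 0 else np.imag(y)
            cols.append(np.sqrt(2.0) * (-1.0) ** abs(m) * part)
    return np.stack(cols, axis=1)


def fit_sh(signal, directions, spec: SHBasisSpec = SHBasisSpec()) -> np.ndarray:
    """Pseudo-inverse SH fit of one shell's signal.

    Under-determined systems (n_directions < n_coeffs) return the
    minimum-l2-norm exact interpolant; over-determined systems the
    least-squares solution.  `signal` may be 1-D (one voxel) or 2-D
    (n_voxels, n_directions).
    """
    signal = np.asarray(signal, dtype=float)
    B = design_matrix(directions, spec)
    if signal.shape[-1] != B.shape[0]:
        raise ValueError(
            f"signal length {signal.shape[-1]} != {B.shape[0]} directions"
        )
    if not np.any(B):
        raise ValueError("all-zero design matrix")
    Binv = np.linalg.pinv(B, rcond=_PINV_RCOND)
    return signal @ Binv.T


def project_sh(coeffs, target_directions, spec: SHBasisSpec = SHBasisSpec()) -> np.ndarray:
    """Evaluate SH coefficients at target directions (b0 is NOT routed here)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != spec.n_coeffs:
        raise ValueError(f"expected {spec.n_coeffs} coefficients, got {coeffs.shape[-1]}")
    return coeffs @ design_matrix(target_directions, spec).T


def pass_through_b0(b0_value):
    """b0 channels have no orientation; they pass through as-is."""
    return b0_value


def group_shells(scheme: GradientScheme, table: ShellTable = ShellTable()) -> dict:
    """Partition scheme entries into the b0 set and one set per nominal shell.

    Returns ``{"b0": indices, b: indices, ...}`` with shell keys the nominal
    b-values.  An entry matching no shell, or more than one, is an error.
    """
    out: dict = {"b0": np.flatnonzero(scheme.b0_mask)}
    nominal = np.asarray(table.nominal_bvalues)
    dw_idx = np.flatnonzero(~scheme.b0_mask)
    hits = np.abs(scheme.bvals[dw_idx, None] - nominal[None, :]) <= table.tolerance
    n_hits = hits.sum(axis=1)
    if np.any(n_hits != 1):
        bad = scheme.bvals[dw_idx[n_hits != 1]]
        raise ValueError(
            f"b-values {bad.tolist()} match "
            f"{'no' if (n_hits == 0).any() else 'multiple'} nominal shells "
            f"{nominal.tolist()} within tolerance {table.tolerance}"
        )
    for j, b in enumerate(table.nominal_bvalues):
        out[b] = dw_idx[hits[:, j]]
    return out


def read_bvals_bvecs(bvals_path, bvecs_path, b0_threshold: float = 50.0) -> GradientScheme:
    """Read FSL-dialect sidecars: bvals one row, bvecs 3 rows x N columns."""
    bvals = np.loadtxt(bvals_path, ndmin=2).ravel()
    bvecs = np.loadtxt(bvecs_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: rows are x, y, z
    if bvecs.shape != (len(bvals), 3):
        raise ValueError("bvecs shape does not match bvals length")
    b0 = bvals <= b0_threshold
    # FSL writes zero vectors for b0 entries; normalise the rest defensively
    norms = np.linalg.norm(bvecs, axis=1)
    dw = ~b0
    bvecs = bvecs.copy()
    bvecs[dw] /= norms[dw][:, None]
    return GradientScheme(bvals, bvecs, b0)
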