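"""From masked DWI volumes to patch feature vectors and back.

Each in-mask voxel is summarized by a 91-element feature: the order-8 SH
coefficients of the b=1200 shell (45), the coefficients of the b=3000 shell
(45), and one aggregated b0 channel (the mean over all b0 volumes).  A patch
stacks the center voxel with its six face neighbors in the fixed order

    center, -x, +x, -y, +y, -z, +z

giving the 7 x 91 = 637 element input the harmonizer consumes.  Neighbors
outside the mask or the volume contribute zero vectors, so boundary voxels are
kept rather than discarded.

Feature layout is bijective: `split_patch` / `split_voxel_features` invert the
packing exactly.  Reassembly writes only center voxels back, making it a left
inverse of extraction composed with center selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sh import (
    GradientScheme,
    SHBasisSpec,
    ShellTable,
    fit_sh,
    group_shells,
    project_sh,
    read_bvals_bvecs,
)

__all__ = [
    "DWIVolume",
    "PatchFeature",
    "SiteDataset",
    "NEIGHBOR_OFFSETS",
    "voxel_features",
    "volume_features",
    "features_to_signal",
    "extract_patches",
    "reassemble",
    "resample_to_scheme",
    "load_dwi",
    "save_dwi",
    "load_manifest",
]

# fixed, documented patch layout: center first, then face neighbors
NEIGHBOR_OFFSETS = (
    (0, 0, 0),
    (-1, 0, 0),
    (1, 0, 0),
    (0, -1, 0),
    (0, 1, 0),
    (0, 0, -1),
    (0, 0, 1),
)


@dataclass
class DWIVolume:
    """A 4-D diffusion-weighted volume with its scheme and analysis mask."""

    data: np.ndarray  # (x, y, z, n_volumes)
    scheme: GradientScheme
    mask: np.ndarray  # (x, y, z) boolean
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, volumes)")
        if self.data.shape[-1] != len(self.scheme):
            raise ValueError("4th dimension must match the gradient scheme length")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial shape")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def spatial_shape(self):
        return self.data.shape[:3]


@dataclass
class PatchFeature:
    """One 637-element patch vector with its one-hot site label."""

    x: np.ndarray
    site: np.ndarray
    center_index: tuple

    def __post_init__(self):
        if not np.isclose(self.site.sum(), 1.0) or not np.all(
            np.isin(self.site, (0.0, 1.0))
        ):
            raise ValueError("site must be one-hot")


def n_voxel_feats(spec: SHBasisSpec, table: ShellTable) -> int:
    return len(table.nominal_bvalues) * spec.n_coeffs + 1


def volume_features(volume: DWIVolume, spec: SHBasisSpec = SHBasisSpec(),
                    table: ShellTable = ShellTable()) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel features for every masked voxel, vectorized.

    Returns ``(features, centers)`` with features of shape (M, 2*n_coeffs+1)
    and centers the (M, 3) integer voxel coordinates, in C scan order.
    """
    groups = group_shells(volume.scheme, table)
    centers = np.argwhere(volume.mask)
    sig = volume.data[volume.mask]  # (M, n_volumes)
    parts = []
    for b in table.nominal_bvalues:
        idx = groups[b]
        parts.append(fit_sh(sig[:, idx], volume.scheme.bvecs[idx], spec))
    b0_idx = groups["b0"]
    if len(b0_idx):
        parts.append(sig[:, b0_idx].mean(axis=1, keepdims=True))
    else:
        parts.append(np.zeros((sig.shape[0], 1)))
    return np.concatenate(parts, axis=1), centers


def voxel_features(volume: DWIVolume, voxel, spec: SHBasisSpec = SHBasisSpec(),
                   table: ShellTable = ShellTable()) -> np.ndarray:
    """Feature vector [shell-1 coeffs | shell-2 coeffs | mean b0] of one voxel."""
    i, j, k = voxel
    if not volume.mask[i, j, k]:
        raise ValueError(f"voxel {tuple(voxel)} is outside the mask")
    groups = group_shells(volume.scheme, table)
    sig = volume.data[i, j, k]
    parts = []
    for b in table.nominal_bvalues:
        idx = groups[b]
        parts.append(fit_sh(sig[idx], volume.scheme.bvecs[idx], spec))
    b0_idx = groups["b0"]
    b0 = sig[b0_idx].mean() if len(b0_idx) else 0.0
    return np.concatenate(parts + [[b0]])


def split_voxel_features(feat: np.ndarray, spec: SHBasisSpec = SHBasisSpec(),
                         table: ShellTable = ShellTable()):
    """Inverse of the per-voxel packing: per-shell coefficient blocks and b0."""
    nc = spec.n_coeffs
    shells = [feat[..., i * nc:(i + 1) * nc] for i in range(len(table.nominal_bvalues))]
    return shells, feat[..., -1]


def split_patch(x: np.ndarray, spec: SHBasisSpec = SHBasisSpec(),
                table: ShellTable = ShellTable()) -> np.ndarray:
    """Reshape a patch vector to (..., 7, n_voxel_feats); index 0 is the center."""
    nv = n_voxel_feats(spec, table)
    return np.asarray(x).reshape(*np.shape(x)[:-1], len(NEIGHBOR_OFFSETS), nv)


def features_to_signal(feat: np.ndarray, scheme: GradientScheme,
                       spec: SHBasisSpec = SHBasisSpec(),
                       table: ShellTable = ShellTable()) -> np.ndarray:
    """Project a 91-vector (or batch) onto a scheme's per-direction signals.

    Shell coefficients are evaluated at the scheme's directions; the b0
    channel passes through unchanged to every b0 entry.
    """
    feat = np.asarray(feat, dtype=float)
    groups = group_shells(scheme, table)
    shells, b0 = split_voxel_features(feat, spec, table)
    out = np.zeros(feat.shape[:-1] + (len(scheme),))
    for shell_i, b in enumerate(table.nominal_bvalues):
        idx = groups[b]
        if len(idx):
            out[..., idx] = project_sh(shells[shell_i], scheme.bvecs[idx], spec)
    out[..., groups["b0"]] = b0[..., None]
    return out


def extract_patches(volume: DWIVolume, site: np.ndarray,
                    spec: SHBasisSpec = SHBasisSpec(),
                    table: ShellTable = ShellTable()):
    """One patch per masked voxel.

    Returns ``(X, centers, raw_centers)``: the (M, 637) patch matrix, the
    (M, 3) center coordinates, and the (M, n_volumes) raw center-voxel
    signals used by the DWI-space projection loss.
    """
    feats, centers = volume_features(volume, spec, table)
    nv = feats.shape[1]
    shape = volume.spatial_shape
    # voxel -> feature row lookup
    lut = -np.ones(shape, dtype=int)
    lut[tuple(centers.T)] = np.arange(len(centers))
    X = np.zeros((len(centers), len(NEIGHBOR_OFFSETS) * nv))
    for slot, off in enumerate(NEIGHBOR_OFFSETS):
        nb = centers + np.array(off)
        inside = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        rows = np.full(len(centers), -1, dtype=int)
        rows[inside] = lut[tuple(nb[inside].T)]
        valid = rows >= 0
        X[valid, slot * nv:(slot + 1) * nv] = feats[rows[valid]]
    raw_centers = volume.data[volume.mask]
    return X, centers, raw_centers


def reassemble(patch_outputs: dict, reference: DWIVolume,
               target_scheme: GradientScheme | None = None) -> DWIVolume:
    """Write per-center DWI signal vectors back into a 4-D volume.

    `patch_outputs` maps center (i, j, k) tuples to per-direction signal
    vectors in `target_scheme` (default: the reference's own scheme).
    Every masked voxel must appear exactly once; unmasked voxels are zero.
    """
    scheme = target_scheme if target_scheme is not None else reference.scheme
    expected = {tuple(c) for c in np.argwhere(reference.mask)}
    got = {tuple(k) for k in patch_outputs}
    if got != expected:
        missing, extra = expected - got, got - expected
        raise ValueError(
            f"center indices do not tile the mask: {len(missing)} missing, "
            f"{len(extra)} unexpected"
        )
    data = np.zeros(reference.spatial_shape + (len(scheme),))
    for center, sig in patch_outputs.items():
        sig = np.asarray(sig, dtype=float)
        if sig.shape != (len(scheme),):
            raise ValueError("output signal length does not match the target scheme")
        data[center] = sig
    return DWIVolume(data=data, scheme=scheme, mask=reference.mask.copy(),
                     affine=reference.affine.copy(), voxel_size=reference.voxel_size)


def resample_to_scheme(volume: DWIVolume, target_scheme: GradientScheme,
                       spec: SHBasisSpec = SHBasisSpec(),
                       table: ShellTable = ShellTable()) -> DWIVolume:
    """Model-free scheme change: per-voxel SH fit, then projection.

    This is the identity-in-SH baseline a harmonizer must beat: it changes the
    angular sampling but carries every site bias (gain, noise) through.
    """
    feats, centers = volume_features(volume, spec, table)
    signals = features_to_signal(feats, target_scheme, spec, table)
    data = np.zeros(volume.spatial_shape + (len(target_scheme),))
    data[volume.mask] = signals
    return DWIVolume(data=data, scheme=target_scheme, mask=volume.mask.copy(),
                     affine=volume.affine.copy(), voxel_size=volume.voxel_size)


class SiteDataset:
    """Unpaired patches from K >= 2 sites with one-hot site labels.

    Per-site arrays keep each site's own scheme (direction counts differ
    between protocols), which the DWI-space projection loss needs.
    """

    def __init__(self, site_names: list[str]):
        if len(site_names) < 2:
            raise ValueError("a SiteDataset needs at least 2 sites")
        self.site_names = list(site_names)
        self._feats: dict[str, np.ndarray] = {}
        self._centers: dict[str, np.ndarray] = {}
        self._raw: dict[str, np.ndarray] = {}
        self._schemes: dict[str, GradientScheme] = {}
        self.spec = SHBasisSpec()
        self.table = ShellTable()

    @property
    def n_sites(self) -> int:
        return len(self.site_names)

    def one_hot(self, site: str) -> np.ndarray:
        s = np.zeros(self.n_sites)
        s[self.site_names.index(site)] = 1.0
        return s

    def add_volume(self, volume: DWIVolume, site: str,
                   spec: SHBasisSpec = SHBasisSpec(),
                   table: ShellTable = ShellTable()):
        if site not in self.site_names:
            raise ValueError(f"unknown site {site!r}")
        self.spec, self.table = spec, table
        X, centers, raw = extract_patches(volume, self.one_hot(site), spec, table)
        for store, new in ((self._feats, X), (self._centers, centers),
                           (self._raw, raw)):
            store[site] = (np.concatenate([store[site], new])
                          if site in store else new)
        self._schemes[site] = volume.scheme
        return self

    def counts(self) -> dict[str, int]:
        return {s: len(self._feats.get(s, ())) for s in self.site_names}

    def site_arrays(self, site: str):
        return self._feats[site], self._raw[site], self._schemes[site]

    def patches(self, site: str) -> list[PatchFeature]:
        onehot = self.one_hot(site)
        return [
            PatchFeature(x=x, site=onehot.copy(), center_index=tuple(c))
            for x, c in zip(self._feats[site], self._centers[site])
        ]

    def __len__(self) -> int:
        return sum(self.counts().values())


# ----------------------------------------------------------------------------
# NIfTI and manifest I/O


def load_dwi(image_path, bvals_path, bvecs_path, mask_path) -> DWIVolume:
    """Load a NIfTI DWI volume with FSL sidecars and a binary mask."""
    import nibabel as nib

    img = nib.load(str(image_path))
    mask = nib.load(str(mask_path)).get_fdata() > 0.5
    scheme = read_bvals_bvecs(bvals_path, bvecs_path)
    zooms = img.header.get_zooms()[:3]
    return DWIVolume(data=np.asarray(img.get_fdata(), dtype=float), scheme=scheme,
                     mask=mask, affine=np.asarray(img.affine),
                     voxel_size=tuple(float(z) for z in zooms))


def save_dwi(volume: DWIVolume, image_path, bvals_path=None, bvecs_path=None,
             mask_path=None) -> None:
    """Write a DWIVolume as NIfTI, preserving the affine; optional sidecars."""
    import nibabel as nib

    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(tuple(volume.voxel_size) + (1.0,))
    nib.save(img, str(image_path))
    if bvals_path is not None:
        np.savetxt(bvals_path, volume.scheme.bvals[None, :], fmt="%.1f")
    if bvecs_path is not None:
        np.savetxt(bvecs_path, volume.scheme.bvecs.T, fmt="%.8f")
    if mask_path is not None:
        nib.save(nib.Nifti1Image(volume.mask.astype(np.uint8), volume.affine),
                 str(mask_path))


def load_manifest(path) -> SiteDataset:
    """Build a SiteDataset from a YAML manifest.

    Format: ``scans: [{image, bvals, bvecs, mask, site}, ...]``; relative paths
    resolve against the manifest's directory.
    """
    import yaml

    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    scans = doc["scans"]
    sites = sorted({row["site"] for row in scans})
    ds = SiteDataset(sites)
    for row in scans:
        paths = {k: (path.parent / row[k]) for k in ("image", "bvals", "bvecs", "mask")}
        vol = load_dwi(paths["image"], paths["bvals"], paths["bvecs"], paths["mask"])
        ds.add_volume(vol, row["site"])
    return ds
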