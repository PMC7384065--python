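"""Encoder q(z|x), conditional decoder p(x|z, s), and the patch adversary.

Architecture (fully connected, tanh hidden units):

* encoder: 637 -> 256 -> 128 -> 64 -> Gaussian head (32-dim mean, 32-dim
  variance through a sigmoid, so sigma^2 in (0, 1));
* decoder: (32 + K) -> 64 -> 128 -> 256 -> 637, linear output because SH
  coefficients are signed and unbounded;
* adversary: 637 -> 32 -> 32 -> K logits, reading the *reconstructed* patch.

The latent sample uses the reparameterization z = mu + sigma * eps with
eps ~ N(0, I) from a seeded generator, so training is deterministic under a
fixed seed.  At test time the site one-hot fed to the decoder is swapped to
the target site; `harmonize` with ``mode="mean"`` (the default) uses the
posterior mean and is therefore a deterministic harmonizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["LatentCode", "HarmonizerModel", "Linear", "MLP"]

DEFAULT_HIDDEN = (256, 128, 64)
DEFAULT_ADVERSARY_HIDDEN = (32, 32)
DEFAULT_LATENT_DIM = 32


@dataclass
class LatentCode:
    """Diagonal-Gaussian posterior: mean and positive scale per dimension."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must share a shape")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive elementwise")


class Linear:
    """Affine layer with fan-in scaled Gaussian init (W ~ N(0, 1/fan_in))."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.standard_normal((n_in, n_out)) * scale,
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class MLP:
    """Stack of Linear layers with tanh on every hidden layer."""

    def __init__(self, sizes, rng: np.random.Generator, out_tanh: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.out_tanh = out_tanh

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.out_tanh:
                x = x.tanh()
        return x

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]


class HarmonizerModel:
    """Parameters of encoder, conditional decoder, and adversary.

    ``sigma_mode`` resolves the ambiguity of a "sigmoid output for the
    variance": ``"variance"`` (default) reads the sigmoid as sigma^2, so
    sigma = sqrt(sigmoid(a)); ``"scale"`` reads it as sigma directly.
    """

    def __init__(self, n_features: int = 637, n_sites: int = 2,
                 latent_dim: int = DEFAULT_LATENT_DIM,
                 hidden=DEFAULT_HIDDEN,
                 adversary_hidden=DEFAULT_ADVERSARY_HIDDEN,
                 sigma_mode: str = "variance", seed: int = 0,
                 site_names: list[str] | None = None,
                 intensity_scale: float = 1.0):
        if sigma_mode not in ("variance", "scale"):
            raise ValueError("sigma_mode must be 'variance' or 'scale'")
        if site_names is not None and len(site_names) != n_sites:
            raise ValueError("site_names length must equal n_sites")
        self.n_features = n_features
        self.n_sites = n_sites
        self.latent_dim = latent_dim
        self.hidden = tuple(hidden)
        self.adversary_hidden = tuple(adversary_hidden)
        self.sigma_mode = sigma_mode
        self.seed = seed
        self.site_names = site_names or [f"site{i}" for i in range(n_sites)]
        self.intensity_scale = float(intensity_scale)
        self.trained = False

        rng = np.random.default_rng(seed)
        self.encoder_trunk = MLP((n_features, *hidden), rng, out_tanh=True)
        self.head_mu = Linear(hidden[-1], latent_dim, rng)
        self.head_logvar = Linear(hidden[-1], latent_dim, rng)
        self.decoder = MLP((latent_dim + n_sites, *hidden[::-1], n_features), rng)
        self.adversary = MLP((n_features, *adversary_hidden, n_sites), rng)

    # -- parameter groups -----------------------------------------------------
    @property
    def primary_params(self):
        return (self.encoder_trunk.params + self.head_mu.params
                + self.head_logvar.params + self.decoder.params)

    @property
    def adversary_params(self):
        return self.adversary.params

    def n_parameters(self) -> tuple[int, int]:
        """(primary, adversary) parameter counts."""
        return (sum(p.value.size for p in self.primary_params),
                sum(p.value.size for p in self.adversary_params))

    # -- forward passes (Tensor in, Tensor out; accept numpy for convenience) -
    def encode_t(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Posterior (mu, sigma) as Tensors; rows are batch entries."""
        h = self.encoder_trunk(x)
        mu = self.head_mu(h)
        gate = self.head_logvar(h).sigmoid()
        sigma = gate.sqrt() if self.sigma_mode == "variance" else gate
        return mu, sigma

    def decode_t(self, z: Tensor, s: Tensor) -> Tensor:
        return self.decoder(concat([z, s], axis=-1))

    def adversary_logits_t(self, xhat: Tensor) -> Tensor:
        return self.adversary(xhat)

    # -- numpy-facing API -----------------------------------------------------
    def encode(self, x) -> LatentCode:
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("encoder input must be finite")
        mu, sigma = self.encode_t(Tensor(np.atleast_2d(x)))
        if x.ndim == 1:
            return LatentCode(mu.value[0], sigma.value[0])
        return LatentCode(mu.value, sigma.value)

    def sample_z(self, code: LatentCode, seed: int) -> np.ndarray:
        """Reparameterized draw z = mu + sigma * eps, seeded."""
        rng = np.random.default_rng(seed)
        return code.mu + code.sigma * rng.standard_normal(code.mu.shape)

    def decode(self, z, s) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        s = np.asarray(s, dtype=float)
        self._check_one_hot(s)
        out = self.decode_t(Tensor(np.atleast_2d(z)), Tensor(np.atleast_2d(s)))
        return out.value[0] if z.ndim == 1 else out.value

    def adversary_logits(self, xhat) -> np.ndarray:
        xhat = np.asarray(xhat, dtype=float)
        out = self.adversary_logits_t(Tensor(np.atleast_2d(xhat)))
        return out.value[0] if xhat.ndim == 1 else out.value

    def harmonize(self, x, s_target, mode: str = "mean",
                  seed: int = 0, check_trained: bool = True) -> np.ndarray:
        """Re-express patch `x` as if collected at the target site.

        ``mode="mean"`` decodes the posterior mean (deterministic);
        ``mode="sample"`` decodes one reparameterized draw.
        """
        if check_trained and not self.trained:
            raise RuntimeError(
                "model is untrained; train first or pass check_trained=False"
            )
        if mode not in ("mean", "sample"):
            raise ValueError("mode must be 'mean' or 'sample'")
        code = self.encode(x)
        z = code.mu if mode == "mean" else self.sample_z(code, seed)
        x = np.asarray(x)
        s_target = np.asarray(s_target, dtype=float)
        if x.ndim == 2 and s_target.ndim == 1:
            s_target = np.broadcast_to(s_target, (x.shape[0], len(s_target)))
        return self.decode(z, s_target)

    def one_hot(self, site: str) -> np.ndarray:
        if site not in self.site_names:
            raise ValueError(f"unknown site {site!r}; model knows {self.site_names}")
        s = np.zeros(self.n_sites)
        s[self.site_names.index(site)] = 1.0
        return s

    @staticmethod
    def _check_one_hot(s: np.ndarray):
        s2 = np.atleast_2d(s)
        if not (np.all(np.isin(s2, (0.0, 1.0))) and np.all(s2.sum(axis=-1) == 1.0)):
            raise ValueError("s must be one-hot (soft labels are rejected)")

    # -- serialization --------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: one .npz with weights plus JSON architecture metadata."""
        meta = dict(
            n_features=self.n_features, n_sites=self.n_sites,
            latent_dim=self.latent_dim, hidden=list(self.hidden),
            adversary_hidden=list(self.adversary_hidden),
            sigma_mode=self.sigma_mode, seed=self.seed,
            site_names=self.site_names, trained=self.trained,
            intensity_scale=self.intensity_scale,
        )
        arrays = {f"p{i}": p.value for i, p in
                  enumerate(self.primary_params + self.adversary_params)}
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "HarmonizerModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["_meta"].tobytes()).decode())
            model = cls(
                n_features=meta["n_features"], n_sites=meta["n_sites"],
                latent_dim=meta["latent_dim"], hidden=tuple(meta["hidden"]),
                adversary_hidden=tuple(meta["adversary_hidden"]),
                sigma_mode=meta["sigma_mode"], seed=meta["seed"],
                site_names=meta["site_names"],
                intensity_scale=meta["intensity_scale"],
            )
            for i, p in enumerate(model.primary_params + model.adversary_params):
                p.value = npz[f"p{i}"].copy()
        model.trained = meta["trained"]
        return model
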