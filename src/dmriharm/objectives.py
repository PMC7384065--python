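"""Loss terms of the scanner-invariant conditional VAE.

The training objective combines five terms:

    L = L_recon + alpha * L_prior + beta * L_proj - gamma * L_adv
        + lambda * L_marginal

* ``L_recon`` — MSE between the reconstructed and input patch in SH space;
* ``L_prior`` — KL[q(z|x) || N(0, I)], the VAE prior divergence;
* ``L_marginal`` — a closed-form upper bound on the batch-average
  KL[q(z|x_i) || q(z)] (q(z) the batch mixture): the pairwise-KL mean
  (1/N^2) sum_ij KL[q_i || q_j].  This compression term is the variational
  surrogate for the mutual information I(z, s) between code and site; it
  enters the minimized loss with a *positive* sign (see docs/methods.md on
  the sign of the lambda term);
* ``L_proj`` — MSE in each subject's own acquisition domain: the center
  voxel's SH coefficients projected onto that subject's gradient directions
  (b0 passing through) against the raw per-direction signal;
* ``L_adv`` — softmax cross-entropy of the adversary on the reconstruction;
  subtracted so the primary network learns to defeat the site classifier.

Default weights alpha=1.0, beta=1.0, gamma=10.0, lambda=0.01 put the terms on
comparable orders of magnitude.

Each term has a Tensor-level function (suffix ``_t``) used during training and
a numpy-facing wrapper returning floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, logsumexp
from .model import LatentCode
from .sh import GradientScheme, SHBasisSpec, ShellTable, design_matrix, group_shells

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "recon_loss",
    "kl_to_prior",
    "pairwise_gaussian_kl",
    "marginal_kl_bound",
    "proj_loss",
    "adversarial_loss",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Trade-off weights; defaults follow the reference configuration."""

    alpha: float = 1.0  # prior KL
    beta: float = 1.0  # DWI-space projection loss
    gamma: float = 10.0  # adversarial term
    lambda_: float = 0.01  # invariance (marginal-KL) penalty
    recon_one_plus_lambda: bool = False  # optional (1+lambda) recon factor

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.lambda_) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    recon: float
    prior_kl: float
    marginal_kl_bound: float
    proj: float
    adv: float
    total: float


# ----------------------------------------------------------------------------
# Tensor-level terms


def recon_loss_t(xhat: Tensor, x: Tensor) -> Tensor:
    return (xhat - x).square().mean()


def kl_to_prior_t(mu: Tensor, sigma: Tensor) -> Tensor:
    """Mean over batch of KL[N(mu, diag sigma^2) || N(0, I)]."""
    s2 = sigma.square()
    per = (mu.square() + s2 - 1.0 - s2.log()).sum(axis=-1) * 0.5
    return per.mean() if per.value.ndim else per


def marginal_kl_bound_t(mu: Tensor, sigma: Tensor) -> Tensor:
    """(1/N^2) sum_ij KL[q_i || q_j] for diagonal Gaussians, rows = batch."""
    n = mu.value.shape[0]
    if n < 2:
        raise ValueError("marginal KL bound needs a batch of at least 2 codes")
    s2 = sigma.square()
    s2_i, s2_j = s2.expand_dims(1), s2.expand_dims(0)
    dmu = mu.expand_dims(0) - mu.expand_dims(1)  # [i, j, d] = mu_j - mu_i
    ratio = s2_i / s2_j
    kl = 0.5 * ((ratio + dmu.square() / s2_j - 1.0 - ratio.log()).sum(axis=-1))
    return kl.mean()


def proj_matrices(scheme: GradientScheme, spec: SHBasisSpec = SHBasisSpec(),
                  table: ShellTable = ShellTable()):
    """Precompute per-shell design matrices and index groups for proj_loss."""
    groups = group_shells(scheme, table)
    mats = {b: design_matrix(scheme.bvecs[groups[b]], spec)
            for b in table.nominal_bvalues if len(groups[b])}
    return groups, mats


def proj_loss_t(xhat_center: Tensor, raw: Tensor, scheme: GradientScheme,
                spec: SHBasisSpec = SHBasisSpec(),
                table: ShellTable = ShellTable(), _cache=None) -> Tensor:
    """DWI-space MSE of the center voxel against its raw acquisition.

    `xhat_center` is the (B, 2*n_coeffs+1) center-voxel block of the
    reconstruction; `raw` the (B, n_entries) raw signals in scheme order.
    """
    if raw.value.shape[-1] != len(scheme):
        raise ValueError("raw signal length does not match the scheme")
    groups, mats = proj_matrices(scheme, spec, table) if _cache is None else _cache
    nc = spec.n_coeffs
    total = None
    for shell_i, b in enumerate(table.nominal_bvalues):
        idx = groups[b]
        if not len(idx):
            continue
        coeffs = xhat_center[..., shell_i * nc:(shell_i + 1) * nc]
        pred = coeffs @ Tensor(mats[b].T)
        sq = (pred - raw[..., idx]).square().sum()
        total = sq if total is None else total + sq
    b0_idx = groups["b0"]
    if len(b0_idx):
        b0_pred = xhat_center[..., -1:]  # identity pass-through to each b0 entry
        total = total + (b0_pred - raw[..., b0_idx]).square().sum()
    return total / float(raw.value.size)


def adversarial_loss_t(logits: Tensor, s_true: Tensor) -> Tensor:
    """Softmax cross-entropy, mean over the batch."""
    lse = logsumexp(logits, axis=-1)
    picked = (logits * s_true).sum(axis=-1)
    out = lse - picked
    return out.mean() if out.value.ndim else out


def total_loss_t(recon: Tensor, prior_kl: Tensor, marginal: Tensor,
                 proj: Tensor, adv: Tensor, w: LossWeights) -> Tensor:
    rw = (1.0 + w.lambda_) if w.recon_one_plus_lambda else 1.0
    return (rw * recon + w.alpha * prior_kl + w.lambda_ * marginal
            + w.beta * proj - w.gamma * adv)


# ----------------------------------------------------------------------------
# numpy-facing wrappers


def recon_loss(xhat, x) -> float:
    xhat, x = np.asarray(xhat, dtype=float), np.asarray(x, dtype=float)
    if xhat.shape != x.shape:
        raise ValueError("reconstruction and input must have equal shapes")
    return float(recon_loss_t(Tensor(xhat), Tensor(x)).value)


def kl_to_prior(code: LatentCode) -> float:
    return float(kl_to_prior_t(Tensor(code.mu), Tensor(code.sigma)).value)


def pairwise_gaussian_kl(a: LatentCode, b: LatentCode) -> float:
    """Closed-form KL[N(mu_a, sig_a^2) || N(mu_b, sig_b^2)], diagonal."""
    r = a.sigma**2 / b.sigma**2
    return float(0.5 * np.sum(r + (b.mu - a.mu) ** 2 / b.sigma**2 - 1.0 - np.log(r)))


def marginal_kl_bound(codes) -> float:
    """Pairwise-KL bound from a list of LatentCode or a batched LatentCode."""
    if isinstance(codes, LatentCode):
        mu, sigma = np.atleast_2d(codes.mu), np.atleast_2d(codes.sigma)
    else:
        mu = np.stack([c.mu for c in codes])
        sigma = np.stack([c.sigma for c in codes])
    return float(marginal_kl_bound_t(Tensor(mu), Tensor(sigma)).value)


def proj_loss(xhat_center, raw_center_signal, scheme: GradientScheme,
              spec: SHBasisSpec = SHBasisSpec(),
              table: ShellTable = ShellTable()) -> float:
    xhat_center = np.atleast_2d(np.asarray(xhat_center, dtype=float))
    raw = np.atleast_2d(np.asarray(raw_center_signal, dtype=float))
    return float(proj_loss_t(Tensor(xhat_center), Tensor(raw), scheme, spec,
                             table).value)


def adversarial_loss(logits, s_true) -> float:
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    s_true = np.asarray(s_true, dtype=float)
    return float(adversarial_loss_t(Tensor(logits), Tensor(s_true)).value)


def total_loss(recon: float, prior_kl: float, marginal: float, proj: float,
               adv: float, w: LossWeights = LossWeights()) -> LossBreakdown:
    parts = (recon, prior_kl, marginal, proj, adv)
    if not np.all(np.isfinite(parts)):
        raise ValueError("all loss parts must be finite")
    tot = float(total_loss_t(Tensor(recon), Tensor(prior_kl), Tensor(marginal),
                             Tensor(proj), Tensor(adv), w).value)
    return LossBreakdown(recon=recon, prior_kl=prior_kl, marginal_kl_bound=marginal,
                         proj=proj, adv=adv, total=tot)
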