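"""Adversarial objective and training loop for the sinogram inpainter.

The total generator objective is

    L(G, D) = L_cGAN(G, D) + lambda1 * L_sino(G) + lambda2 * L_recon(G)

with the conditional adversarial term, a mean-absolute sinogram-domain term,
and a mean-absolute image-domain term computed through the differentiable
filtered back-projection phi (FBP is linear, so the gradient of L_recon with
respect to the estimated sinogram is the FBP adjoint applied to the error
sign). Published weights: lambda1 = 120, lambda2 = 1e-5; Adam with
beta1 = 0.5, beta2 = 0.999; learning rate 0.002 held for the first half of
training, then decayed linearly to zero.

The discriminator sees channel-concatenated (limited-angle, full) sinogram
pairs, real or generated. The generator's adversarial term defaults to the
non-saturating form -log D(x, G(x, z)); the literal minimax form
log(1 - D(x, G(x, z))) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ImageGrid, ScanGeometry, Sinogram
from .network import (DiscriminatorSpec, GeneratorSpec, PatchDiscriminator,
                      UNetGenerator, build_discriminator, build_generator)
from .nn import Adam
from .phantoms import PairedSample
from .projection import FBPOperator, ramp_filter

__all__ = [
    "TrainConfig", "LossValues", "TrainingHistory",
    "cgan_loss", "sinogram_loss", "reconstruction_loss", "total_objective",
    "learning_rate", "train", "inpaint",
]

LOG_EPS = 1e-7   # probability clamp for the adversarial log terms


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings. Defaults are the published full-scale profile."""

    lambda1: float = 120.0
    lambda2: float = 1e-5
    lr: float = 0.002
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 400
    seed: int = 0
    saturating: bool = False   # literal minimax generator term if True

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        for b in (self.adam_beta1, self.adam_beta2):
            if not (0 <= b < 1):
                raise ValueError("Adam betas must lie in [0, 1)")

    @classmethod
    def desk_profile(cls, **overrides) -> "TrainConfig":
        """Small-instance profile: 64x64 sinograms, batch 8, 30 epochs."""
        kw = dict(batch_size=8, epochs=30)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class LossValues:
    l_cgan: float = 0.0
    l_sino: float = 0.0
    l_recon: float = 0.0
    l_total: float = 0.0
    d_loss: float = 0.0


@dataclass
class TrainingHistory:
    epochs: list[LossValues] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Loss terms
# ---------------------------------------------------------------------------

def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, LOG_EPS, 1.0 - LOG_EPS)


def cgan_loss(d_real: np.ndarray, d_fake: np.ndarray,
              saturating: bool = False) -> tuple[float, float]:
    """Adversarial terms from the two patch probability maps.

    Returns ``(g_term, d_term)``: ``d_term`` is the discriminator's objective
    value ``E[log D(x,y)] + E[log(1 - D(x,G(x,z)))]`` (to be maximised;
    training minimises its negative), and ``g_term`` is the generator's loss
    — non-saturating ``-E[log D(x,G(x,z))]`` by default, or the literal
    minimax ``E[log(1 - D(x,G(x,z)))]``. Probabilities at exactly 0 or 1 are
    clamped by ``1e-7``. Means are taken over patches, then the batch.
    """
    pr = _clamp(np.asarray(d_real, dtype=np.float64))
    pf = _clamp(np.asarray(d_fake, dtype=np.float64))
    d_term = float(np.log(pr).mean() + np.log1p(-pf).mean())
    if saturating:
        g_term = float(np.log1p(-pf).mean())
    else:
        g_term = float(-np.log(pf).mean())
    return g_term, d_term


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Sinogram) else np.asarray(x)


def sinogram_loss(estimated, label) -> float:
    """Mean absolute error over all sinogram entries (the l1 pixel term)."""
    a, b = _values(estimated), _values(label)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.abs(b - a).mean())


def reconstruction_loss(estimated, label, grid: ImageGrid,
                        geometry: ScanGeometry) -> float:
    """Mean absolute error between the FBP reconstructions of both sinograms."""
    phi = FBPOperator(geometry, grid)
    a, b = _values(estimated), _values(label)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.abs(phi(b) - phi(a)).mean())


def reconstruction_loss_grad(estimated, label, grid: ImageGrid,
                             geometry: ScanGeometry) -> np.ndarray:
    """Gradient of :func:`reconstruction_loss` w.r.t. the estimated sinogram.

    ``d/d est mean|phi(y) - phi(est)| = phi^T(sign(phi(est) - phi(y))) / N``
    — exact because phi is linear.
    """
    phi = FBPOperator(geometry, grid)
    a, b = _values(estimated), _values(label)
    err = np.sign(phi(a) - phi(b))
    return phi.adjoint(err) / err.size


def total_objective(losses: LossValues, cfg: TrainConfig) -> float:
    """The combined generator objective ``l_cgan + l1*l_sino + l2*l_recon``."""
    return losses.l_cgan + cfg.lambda1 * losses.l_sino + cfg.lambda2 * losses.l_recon


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """Constant for the first half of training, then linear decay to zero."""
    half = cfg.epochs // 2
    if epoch < half or cfg.epochs <= 1:
        return cfg.lr
    return cfg.lr * (cfg.epochs - epoch) / (cfg.epochs - half)


# ---------------------------------------------------------------------------
# Batched differentiable FBP (training-scale parallel geometry)
# ---------------------------------------------------------------------------

class _BatchFBP:
    """phi and phi^T applied to batches of sinograms via the sparse matrix."""

    def __init__(self, geometry: ScanGeometry, grid: ImageGrid):
        self.op = FBPOperator(geometry, grid)
        self.geometry, self.grid = geometry, grid

    def _ramp(self, batch: np.ndarray) -> np.ndarray:
        sino_like = Sinogram(np.zeros(self.geometry.shape), self.geometry)
        out = np.empty_like(batch)
        for i in range(batch.shape[0]):
            out[i] = ramp_filter(sino_like.with_values(batch[i])).values
        return out

    def phi(self, batch: np.ndarray) -> np.ndarray:
        filt = self._ramp(batch)
        A = self.op.projector.matrix
        flat = filt.reshape(batch.shape[0], -1) @ A   # (B, n_pix)
        return self.op.scale * flat.reshape(batch.shape[0], *self.grid.shape)

    def phi_t(self, images: np.ndarray) -> np.ndarray:
        A = self.op.projector.matrix
        flat = images.reshape(images.shape[0], -1) @ A.T
        sinos = flat.reshape(images.shape[0], *self.geometry.shape)
        return self.op.scale * self._ramp(sinos)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _stack(samples: list[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.input_sino.values for s in samples])[..., None].astype(np.float32)
    y = np.stack([s.label_sino.values for s in samples])[..., None].astype(np.float32)
    return x, y


def train(dataset: list[PairedSample], g_spec: GeneratorSpec,
          d_spec: DiscriminatorSpec, cfg: TrainConfig,
          callback=None) -> tuple[UNetGenerator, PatchDiscriminator,
                                  TrainingHistory]:
    """Alternating D-step / G-step optimisation of the inpainting GAN.

    Per batch the discriminator is updated on a real pair (x, y) and a fake
    pair (x, G(x, z)), then the generator on the combined objective; both use
    Adam(beta1, beta2) with the two-phase learning-rate schedule. Raises
    ``RuntimeError`` on a non-finite loss. Deterministic for a fixed seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(g_spec, seed=int(rng.integers(2**31)))
    disc = build_discriminator(d_spec, seed=int(rng.integers(2**31)))
    opt_g = Adam(gen.params(), cfg.lr, cfg.adam_beta1, cfg.adam_beta2)
    opt_d = Adam(disc.params(), cfg.lr, cfg.adam_beta1, cfg.adam_beta2)

    x_all, y_all = _stack(dataset)
    n = x_all.shape[0]

    fbp = None
    if cfg.lambda2 > 0:
        geometry = dataset[0].input_sino.geometry
        img_shape = dataset[0].source_image.shape
        fbp = _BatchFBP(geometry, ImageGrid(img_shape[0], img_shape[1]))

    history = TrainingHistory()
    for epoch in range(cfg.epochs):
        lr = learning_rate(cfg, epoch)
        order = rng.permutation(n)
        agg = LossValues()
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x, y = x_all[idx], y_all[idx]

            fake = gen.forward(x, train=True)

            # --- discriminator step: maximise log D(real) + log(1 - D(fake))
            opt_d.zero_grad()
            p_real = disc.forward(np.concatenate([x, y], axis=-1), train=True)
            pr = _clamp(p_real)
            disc.backward((-1.0 / pr / pr.size).astype(np.float32))
            p_fake = disc.forward(np.concatenate([x, fake], axis=-1), train=True)
            pf = _clamp(p_fake)
            disc.backward((1.0 / (1.0 - pf) / pf.size).astype(np.float32))
            opt_d.step(lr)

            g_term, d_term = cgan_loss(p_real, p_fake, cfg.saturating)

            # --- generator step against the updated discriminator
            opt_g.zero_grad()
            opt_d.zero_grad()
            p_fake2 = disc.forward(np.concatenate([x, fake], axis=-1), train=True)
            pf2 = _clamp(p_fake2)
            if cfg.saturating:
                dmap = (-1.0 / (1.0 - pf2) / pf2.size).astype(np.float32)
                g_adv = float(np.log1p(-pf2).mean())
            else:
                dmap = (-1.0 / pf2 / pf2.size).astype(np.float32)
                g_adv = float(-np.log(pf2).mean())
            dpair = disc.backward(dmap)
            dfake = dpair[..., 1:2].astype(np.float32)
            opt_d.zero_grad()   # D is frozen during the G step

            diff = fake - y
            l_sino = float(np.abs(diff).mean())
            dfake += (cfg.lambda1 / diff.size) * np.sign(diff, dtype=np.float32)

            l_recon = 0.0
            if fbp is not None:
                rec_fake = fbp.phi(fake[..., 0].astype(np.float64))
                rec_real = fbp.phi(y[..., 0].astype(np.float64))
                err = rec_fake - rec_real
                l_recon = float(np.abs(err).mean())
                n_img = err[0].size * err.shape[0]
                grad_sino = fbp.phi_t(np.sign(err)) / n_img
                dfake += (cfg.lambda2 * grad_sino[..., None]).astype(np.float32)

            gen.backward(dfake)
            opt_g.step(lr)

            l_total = g_adv + cfg.lambda1 * l_sino + cfg.lambda2 * l_recon
            if not np.isfinite(l_total) or not np.isfinite(d_term):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: total={l_total}, "
                    f"d_term={d_term}")
            agg.l_cgan += g_adv
            agg.l_sino += l_sino
            agg.l_recon += l_recon
            agg.l_total += l_total
            agg.d_loss += -d_term
            n_batches += 1

        for name in ("l_cgan", "l_sino", "l_recon", "l_total", "d_loss"):
            setattr(agg, name, getattr(agg, name) / max(n_batches, 1))
        history.epochs.append(agg)
        history.learning_rates.append(lr)
        if callback is not None:
            callback(epoch, agg)
    return gen, disc, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def inpaint(model: UNetGenerator, limited: Sinogram,
            paste_measured: bool = True) -> Sinogram:
    """Estimate the full 180-degree sinogram from a limited-angle input.

    The output is clipped to [0, 1] and flagged fully valid; with
    ``paste_measured`` (default) the measured views are copied back
    bit-exactly, so only the deleted block is network output.
    """
    if limited.values.shape != tuple(model.spec.input_size):
        raise ValueError(
            f"sinogram shape {limited.values.shape} does not match the model's "
            f"training geometry {model.spec.input_size}")
    x = limited.values[None, ..., None].astype(np.float32)
    est = model.forward(x, train=False)[0, ..., 0].astype(np.float64)
    est = np.clip(est, 0.0, 1.0)
    if paste_measured:
        est[limited.valid_mask] = limited.values[limited.valid_mask]
    return Sinogram(est, limited.geometry,
                    np.ones(limited.n_views, dtype=bool), limited.angles_deg)
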