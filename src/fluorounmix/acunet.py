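"""ACU-Net: supervised attenuation correction and unmixing network.

A 1-D residual CNN maps the stacked two-channel input (fluorescence emission
spectrum, white-light reflectance spectrum) to the absolute endmember
abundance vector z >= 0 (PpIX634, PpIX620, lipofuscin, NADH, flavins).  A
rectifier at the output enforces non-negativity.

Training minimizes a two-task loss balanced by learned homoscedastic
uncertainties sigma_C (concentration) and sigma_rec (reconstruction):

    L = (z_1 - c_PpIX)^2 / (2 sigma_C^2)
      + ||B z_hat - phi_tilde||^2 / (2 sigma_rec^2)
      + log(sigma_C * sigma_rec)

where z_hat = z/||z|| and phi_tilde is the unit-l2-normalized measured
fluorescence spectrum.  Both sides of the reconstruction term are normalized
so the term compares spectral shape, avoiding bias toward strong PpIX spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    AdamW,
    Conv1d,
    Flatten,
    Linear,
    MaxPool1d,
    Param,
    ReduceLROnPlateau,
    ReLU,
    ResidualBlock,
    Sequential,
    l2_normalize_rows,
    l2_normalize_rows_backward,
)
from .spectral_core import AbundanceVector, EndmemberLibrary, SpectrumPair

SIGMA_FLOOR = 1e-3  # prevents divergence of the log sigma term
LOG_SIGMA_BOUNDS = (float(np.log(SIGMA_FLOOR)), 10.0)


@dataclass(frozen=True)
class AcunetConfig:
    n_blocks: int = 4
    convs_per_block: int = 2
    kernel_early: int = 5
    kernel_late: int = 3
    #: doubling ladder per block; sized so single-core numpy training of the
    #: full phantom benchmark converges within minutes (see docs/methods.md)
    channels: tuple[int, ...] = (8, 16, 32, 64)
    pool: int = 2
    fc_sizes: tuple[int, ...] = (256, 64)
    K: int = 5
    m: int = 104

    def __post_init__(self) -> None:
        if self.kernel_early % 2 != 1 or self.kernel_late % 2 != 1:
            raise ValueError("kernels must be odd (same-convolution)")
        if len(self.channels) != self.n_blocks:
            raise ValueError("need one channel width per residual block")
        if min(
            self.n_blocks, self.convs_per_block, self.pool, self.K, self.m,
            *self.channels, *self.fc_sizes,
        ) <= 0:
            raise ValueError("all config sizes must be positive")
        if self.m < self.pool**self.n_blocks:
            raise ValueError(
                f"m={self.m} too small for {self.n_blocks} poolings of size {self.pool}"
            )


@dataclass(frozen=True)
class OptimizerConfig:
    lr: float = 2e-3
    batch_size: int = 256
    max_epochs: int = 200
    weight_decay: float = 1e-4
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    plateau_threshold: float = 1e-4
    min_lr: float = 1e-6
    #: sd of fresh Gaussian noise added to the input spectra each batch —
    #: re-sampled camera noise; prevents memorizing individual pixels' noise
    #: (0 disables, e.g. for capacity/memorization checks)
    input_noise_sd: float = 0.004
    #: lognormal sigma of per-sample geometry augmentation: the reflectance
    #: is scaled by a random factor g and the fluorescence by g^(1+x) with
    #: x the dual-band exponent (0.7) — the distance/angle invariance the
    #: correction problem is built on.  The label is invariant, so this
    #: teaches geometry invariance instead of letting the net memorize each
    #: training group's magnitude signature.  0 disables.
    geom_augment_sigma: float = 0.3
    geom_augment_exponent: float = 1.7


class LossWeights:
    """Learned homoscedastic task uncertainties, parameterized as log sigma."""

    def __init__(self, log_sigma_c: float = 0.0, log_sigma_rec: float = 0.0):
        self.log_sigma_c = Param(np.array(log_sigma_c), decay=False, name="log_sigma_c")
        self.log_sigma_rec = Param(np.array(log_sigma_rec), decay=False, name="log_sigma_rec")

    @property
    def sigma_c(self) -> float:
        return float(np.exp(self.log_sigma_c.value))

    @property
    def sigma_rec(self) -> float:
        return float(np.exp(self.log_sigma_rec.value))

    def parameters(self) -> list[Param]:
        return [self.log_sigma_c, self.log_sigma_rec]

    def clamp(self) -> None:
        lo, hi = LOG_SIGMA_BOUNDS
        for p in self.parameters():
            p.value[...] = np.clip(p.value, lo, hi)


class SpectralEncoder:
    """The ACU-Net trunk: residual CNN -> FC head -> rectified abundances.

    ``forward`` returns the rectified abundances; pre-rectifier logits stay
    cached so a weight-sharing twin (softmax head) can reuse the same pass.
    """

    def __init__(self, cfg: AcunetConfig, in_channels: int, seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        kernels = [
            cfg.kernel_early if i < cfg.n_blocks // 2 else cfg.kernel_late
            for i in range(cfg.n_blocks)
        ]
        layers: list = [Conv1d(in_channels, cfg.channels[0], kernels[0], rng), ReLU()]
        L = cfg.m
        for i in range(cfg.n_blocks):
            layers.append(ResidualBlock(cfg.channels[i], kernels[i], cfg.convs_per_block, rng))
            layers.append(MaxPool1d(cfg.pool))
            L //= cfg.pool
            if i < cfg.n_blocks - 1:
                layers.append(Conv1d(cfg.channels[i], cfg.channels[i + 1], kernels[i + 1], rng))
                layers.append(ReLU())
        layers.append(Flatten())
        nin = cfg.channels[-1] * L
        for nout in cfg.fc_sizes:
            layers.append(Linear(nin, nout, rng))
            layers.append(ReLU())
            nin = nout
        # near-zero weights + small positive bias: every rectified output
        # starts alive at ~bias, avoiding dead units at the regression head
        layers.append(Linear(nin, cfg.K, rng, bias_init=0.1, w_scale=0.01))
        self.net = Sequential(*layers)
        self.in_channels = in_channels
        self._logits: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return self.net.parameters()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, in_channels, m) -> rectified abundances (N, K)."""
        # conv stack runs channels-last internally
        self._logits = self.net.forward(np.ascontiguousarray(x.transpose(0, 2, 1)))
        return np.clip(self._logits, 0.0, None)

    @property
    def logits(self) -> np.ndarray:
        assert self._logits is not None, "call forward first"
        return self._logits

    def backward_from_z(self, dz: np.ndarray, dlogits_extra: np.ndarray | None = None) -> np.ndarray:
        """Backprop given dL/dz (through the output rectifier) plus an
        optional direct dL/dlogits contribution (twin softmax head).

        At a dead output (logit <= 0, z = 0) the loss still has a one-sided
        derivative along +z; when that derivative favors reviving the unit
        (dz < 0) it is passed through — a subgradient choice that prevents
        abundance channels from dying irreversibly at the rectified head.
        """
        dlogits = np.where((self._logits > 0) | (dz < 0), dz, 0.0)
        if dlogits_extra is not None:
            dlogits = dlogits + dlogits_extra
        dx = self.net.backward(dlogits)
        return dx.transpose(0, 2, 1)  # back to channels-first

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v


@dataclass
class TrainedModel:
    """Architecture config + learned parameters + learned loss weights."""

    encoder: SpectralEncoder
    loss_weights: LossWeights
    cfg: AcunetConfig
    history: list[float] = field(default_factory=list)
    calibration_scale: float = 1.0
    ppix_index: int = 0


def build_acunet(cfg: AcunetConfig = AcunetConfig(), seed: int = 0) -> TrainedModel:
    """Untrained ACU-Net with two input channels (fluorescence, white)."""
    return TrainedModel(SpectralEncoder(cfg, in_channels=2, seed=seed), LossWeights(), cfg)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def acunet_loss(
    z: np.ndarray | AbundanceVector,
    c_ppix: float,
    phi_fluo: np.ndarray,
    B: EndmemberLibrary,
    w: LossWeights,
    ppix_index: int = 0,
) -> float:
    """Single-sample value of the homoscedastic two-task loss (see module
    docstring).  A zero fluorescence spectrum keeps a zero reconstruction
    target (defined case)."""
    zv = z.z if isinstance(z, AbundanceVector) else np.asarray(z, float)
    zn = np.linalg.norm(zv)
    zhat = zv / zn if zn > 0 else np.zeros_like(zv)
    pn = np.linalg.norm(phi_fluo)
    phi_t = phi_fluo / pn if pn > 0 else np.zeros_like(phi_fluo)
    sc, sr = w.sigma_c, w.sigma_rec
    rc = float(zv[ppix_index] - c_ppix)
    rr = B.B @ zhat - phi_t
    return float(
        rc**2 / (2 * sc**2)
        + rr @ rr / (2 * sr**2)
        + np.log(sc * sr)
    )


def _loss_and_grads(
    z: np.ndarray,
    c: np.ndarray,
    phi_norm: np.ndarray,
    Bmat: np.ndarray,
    w: LossWeights,
    ppix_index: int,
) -> tuple[float, np.ndarray]:
    """Mean batch loss; fills the log-sigma grads, returns (loss, dL/dz)."""
    N = z.shape[0]
    sc2 = np.exp(2 * w.log_sigma_c.value)
    sr2 = np.exp(2 * w.log_sigma_rec.value)
    rc = z[:, ppix_index] - c
    zhat, norms = l2_normalize_rows(z)
    res = zhat @ Bmat.T - phi_norm
    res_sq = (res**2).sum(axis=1)
    loss = float(
        np.mean(rc**2) / (2 * sc2)
        + np.mean(res_sq) / (2 * sr2)
        + w.log_sigma_c.value
        + w.log_sigma_rec.value
    )
    dz = np.zeros_like(z)
    dz[:, ppix_index] += rc / (sc2 * N)
    dzhat = (res @ Bmat) / (sr2 * N)
    dz += l2_normalize_rows_backward(dzhat, z, zhat, norms)
    w.log_sigma_c.grad += -np.mean(rc**2) / sc2 + 1.0
    w.log_sigma_rec.grad += -np.mean(res_sq) / sr2 + 1.0
    return loss, dz


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------


def _stack_inputs(pairs: list[SpectrumPair]) -> np.ndarray:
    from . import nn as _nn

    return np.stack([[p.phi_fluo, p.phi_ref] for p in pairs]).astype(_nn.DTYPE)


def _normalized_fluo(pairs: list[SpectrumPair]) -> np.ndarray:
    from . import nn as _nn

    phi = np.stack([p.phi_fluo for p in pairs])
    n = np.linalg.norm(phi, axis=1, keepdims=True)
    return (phi / np.where(n > 0, n, 1.0)).astype(_nn.DTYPE)


def train_acunet(
    pairs: list[SpectrumPair],
    B: EndmemberLibrary,
    cfg: AcunetConfig = AcunetConfig(),
    opt: OptimizerConfig = OptimizerConfig(),
    seed: int = 17,
) -> TrainedModel:
    """Train on labeled pairs with AdamW and reduce-on-plateau learning rate.

    Returns the model with per-epoch mean training loss in ``history`` and a
    least-squares calibration scale (true concentration vs predicted z_1) fit
    on the training data.
    """
    if any(not p.labeled for p in pairs):
        raise ValueError("training set contains unlabeled pairs")
    if cfg.m != B.grid.n_bands:
        raise ValueError("config m must match the library grid")
    model = build_acunet(cfg, seed=seed)
    model.ppix_index = B.index_of("ppix634")
    from . import nn as _nn

    X = _stack_inputs(pairs)
    c = np.array([p.c_ppix for p in pairs], dtype=_nn.DTYPE)
    phi_norm = _normalized_fluo(pairs)
    Bmat = B.B.astype(_nn.DTYPE)
    _fit_encoder(
        model.encoder, model.loss_weights, X, opt, seed, model.history,
        lambda z, idx: _loss_and_grads(
            z, c[idx], phi_norm[idx], Bmat, model.loss_weights, model.ppix_index
        ),
    )
    pred = _predict_z(model.encoder, X)[:, model.ppix_index]
    denom = float(pred @ pred)
    model.calibration_scale = float(pred @ c) / denom if denom > 0 else 1.0
    return model


def _fit_encoder(encoder, loss_weights, X, opt, seed, history, loss_fn, extra_params=()) -> None:
    """Shared minibatch loop: AdamW + plateau schedule + log-sigma clamping.

    ``loss_fn(z, idx)`` must fill any auxiliary gradients (log sigmas) and
    return (loss, dL/dz) for the batch rows ``idx``.
    """
    params = encoder.parameters() + loss_weights.parameters() + list(extra_params)
    optimizer = AdamW(params, lr=opt.lr, weight_decay=opt.weight_decay)
    sched = ReduceLROnPlateau(
        optimizer,
        factor=opt.plateau_factor,
        patience=opt.plateau_patience,
        threshold=opt.plateau_threshold,
        min_lr=opt.min_lr,
    )
    rng = np.random.default_rng(seed + 1)
    n = X.shape[0]
    bs = min(opt.batch_size, n)
    for _epoch in range(opt.max_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            optimizer.zero_grad()
            xb = X[idx]
            if opt.geom_augment_sigma > 0:
                g = np.exp(rng.normal(0.0, opt.geom_augment_sigma, size=(len(idx), 1)))
                scale = np.stack(
                    [g ** opt.geom_augment_exponent, g], axis=1
                ).astype(xb.dtype)  # (N, 2, 1): fluorescence, reflectance
                xb = xb * scale
            if opt.input_noise_sd > 0:
                xb = np.clip(
                    xb + rng.normal(0.0, opt.input_noise_sd, size=xb.shape).astype(xb.dtype),
                    0.0, None,
                )
            z = encoder.forward(xb)
            loss, dz = loss_fn(z, idx)
            encoder.backward_from_z(dz)
            optimizer.step()
            loss_weights.clamp()
            total += loss * len(idx)
        epoch_loss = total / n
        history.append(epoch_loss)
        sched.step(epoch_loss)
        if sched.done:
            break


def _predict_z(encoder: SpectralEncoder, X: np.ndarray, batch: int = 1024) -> np.ndarray:
    out = [encoder.forward(X[i : i + batch]) for i in range(0, X.shape[0], batch)]
    return np.concatenate(out, axis=0)


def predict(
    model: TrainedModel, pairs: list[SpectrumPair], B: EndmemberLibrary
) -> tuple[list[AbundanceVector], np.ndarray]:
    """Abundances plus corrected-spectrum reconstructions B z_hat (N, m)."""
    X = _stack_inputs(pairs)
    z = _predict_z(model.encoder, X)
    zhat, _ = l2_normalize_rows(z)
    recon = zhat @ B.B.T
    return [AbundanceVector(row) for row in z], recon
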