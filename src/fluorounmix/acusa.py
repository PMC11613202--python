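"""ACU-SA: semi-supervised endmember-guided correction and unmixing.

Two components:

* **HU module** — a hyperspectral-unmixing autoencoder.  The encoder has the
  ACU-Net trunk (single input channel: a corrected-domain spectrum) and a
  rectified K-dimensional output; the decoder is the *fixed* linear map
  z -> B z, so the latent code is forced to mean absolute endmember
  abundance (its magnitude tracks the input intensity).
  A twin encoder sharing all weights receives the pure endmember spectra and
  ends in a softmax scored by cross-entropy against the one-hot identity —
  endmember k must map to the k-th unit abundance.  Stage-1 training is
  self-supervised (reconstruction + endmember guidance, homoscedastically
  weighted) and can pool unlabeled measurements with synthetic mixtures.

* **Normalization module** — a shallow 4-layer 1-D CNN (no residual blocks)
  mapping the stacked raw (fluorescence, white) spectra to a single corrected
  spectrum.  Stage 2 freezes the HU module, attaches the normalization net in
  front, and trains only the latter so that the PpIX634 abundance of the
  composed model matches the known concentration:
  L = ([f(g(phi_fluo, phi_ref))]_1 - c_PpIX)^2.

The corrected spectrum g(.) is an explicit intermediate output, kept
inspectable on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acunet import (
    AcunetConfig,
    OptimizerConfig,
    SpectralEncoder,
    _stack_inputs,
    LOG_SIGMA_BOUNDS,
)
from .nn import (
    AdamW,
    Conv1d,
    Param,
    ReduceLROnPlateau,
    ReLU,
    Sequential,
    l2_normalize_rows,
    log_softmax,
)
from .spectral_core import AbundanceVector, EndmemberLibrary, SpectrumPair
from .synthetic import NoiseModel


@dataclass(frozen=True)
class AcusaConfig:
    hu_cfg: AcunetConfig = AcunetConfig()
    norm_layers: int = 4
    norm_channels: tuple[int, ...] = (16, 16, 8, 1)
    norm_kernel: int = 5
    augment_n: int = 5000
    augment_noise: NoiseModel = NoiseModel(gaussian_sd=0.01)

    def __post_init__(self) -> None:
        if len(self.norm_channels) != self.norm_layers:
            raise ValueError("need one channel width per normalization layer")
        if self.norm_channels[-1] != 1:
            raise ValueError("normalization net must end in a single channel")
        if self.norm_kernel % 2 != 1:
            raise ValueError("kernels must be odd")


class HuLossWeights:
    """Learned log sigmas for endmember guidance and reconstruction."""

    def __init__(self, log_sigma_eg: float = 0.0, log_sigma_rec: float = 0.0):
        self.log_sigma_eg = Param(np.array(log_sigma_eg), decay=False, name="log_sigma_eg")
        self.log_sigma_rec = Param(np.array(log_sigma_rec), decay=False, name="log_sigma_rec")

    @property
    def sigma_eg(self) -> float:
        return float(np.exp(self.log_sigma_eg.value))

    @property
    def sigma_rec(self) -> float:
        return float(np.exp(self.log_sigma_rec.value))

    def parameters(self) -> list[Param]:
        return [self.log_sigma_eg, self.log_sigma_rec]

    def clamp(self) -> None:
        lo, hi = LOG_SIGMA_BOUNDS
        for p in self.parameters():
            p.value[...] = np.clip(p.value, lo, hi)


class NormNet:
    """Shallow same-convolution CNN g: (fluorescence, white) -> corrected
    spectrum, channels-first at the boundary like the encoder.

    The output rectifier keeps the corrected spectrum non-negative; its
    backward uses the same one-sided revival rule as the encoder head so a
    fully dark output can recover during stage-2 training.
    """

    def __init__(self, layers: list):
        self.seq = Sequential(*layers)
        self._pre: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return self.seq.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 2, m) -> (N, 1, m), non-negative."""
        self._pre = self.seq.forward(np.ascontiguousarray(x.transpose(0, 2, 1)))
        return np.clip(self._pre, 0.0, None).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyl = np.ascontiguousarray(dy.transpose(0, 2, 1))
        dpre = np.where((self._pre > 0) | (dyl < 0), dyl, 0.0)
        dx = self.seq.backward(dpre)
        return dx.transpose(0, 2, 1)


@dataclass
class AcusaModel:
    hu_encoder: SpectralEncoder
    norm_net: NormNet
    cfg: AcusaConfig
    hu_weights: HuLossWeights
    library: EndmemberLibrary
    stage1_history: list[float] = field(default_factory=list)
    stage2_history: list[float] = field(default_factory=list)
    calibration_scale: float = 1.0

    @property
    def ppix_index(self) -> int:
        return self.library.index_of("ppix634")


def build_acusa(
    cfg: AcusaConfig, B: EndmemberLibrary, seed: int = 0
) -> AcusaModel:
    """Untrained ACU-SA.  The decoder is B itself (no trainable weights); the
    twin encoder is the HU encoder re-read through a softmax, so there is
    nothing separate to build for either."""
    if np.linalg.matrix_rank(B.B) < B.K:
        raise ValueError("endmember library must have full column rank")
    hu = SpectralEncoder(cfg.hu_cfg, in_channels=1, seed=seed)
    rng = np.random.default_rng(seed + 7)
    layers: list = []
    cin = 2
    for i, cout in enumerate(cfg.norm_channels):
        conv = Conv1d(cin, cout, cfg.norm_kernel, rng)
        # Near-identity start: scale the random weights down and thread the
        # fluorescence channel through feature 0 with a unit center tap, so
        # g(phi_fluo, phi_ref) ~ phi_fluo at initialization.  Stage 2 then
        # starts from the same stand-in target the supervised model uses
        # (the uncorrected fluorescence) instead of an arbitrary spectrum,
        # which keeps the frozen unmixer's gradients informative.
        conv.W.value *= 0.05
        center = cfg.norm_kernel // 2
        conv.W.value[center, 0, 0] = 1.0
        layers.append(conv)
        if i < cfg.norm_layers - 1:
            layers.append(ReLU())
        cin = cout
    return AcusaModel(hu, NormNet(layers), cfg, HuLossWeights(), B)


def decode(B: EndmemberLibrary, zhat: np.ndarray) -> np.ndarray:
    """The fixed linear decoder: relative abundances -> spectrum B z_hat."""
    return zhat @ B.B.T if zhat.ndim == 2 else B.B @ zhat


def twin_probabilities(hu_encoder: SpectralEncoder, spectra: np.ndarray) -> np.ndarray:
    """Twin encoder output: softmax over the shared trunk's logits for
    corrected-domain spectra (N, m)."""
    hu_encoder.forward(spectra[:, None, :])
    return np.exp(log_softmax(hu_encoder.logits))


def endmember_ce(phi_logits: np.ndarray, k: int) -> float:
    """Softmax cross-entropy of logits against the one-hot e_k,
    -log softmax(phi)_k, computed with the log-sum-exp trick."""
    phi_logits = np.asarray(phi_logits, dtype=float)
    return float(-log_softmax(phi_logits[None, :])[0, k])


def augment_mixtures(
    B: EndmemberLibrary,
    n: int,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    support_prob: float = 0.6,
) -> np.ndarray:
    """Synthetic corrected-domain spectra: B z + eps with sparse random z
    (no attenuation — these live in the corrected domain).  Returns (n, m)."""
    rng = np.random.default_rng(seed)
    out = np.zeros((n, B.grid.n_bands))
    for i in range(n):
        support = rng.random(B.K) < support_prob
        z = np.zeros(B.K)
        if support.any():
            k = int(support.sum())
            z[support] = 2.0 * float(np.exp(rng.normal(0.0, 0.5))) * rng.dirichlet(np.ones(k))
        spec = B.B @ z
        if noise.gaussian_sd > 0:
            spec = spec + rng.normal(0.0, noise.gaussian_sd, size=spec.shape)
        out[i] = spec
    return out


# ---------------------------------------------------------------------------
# Stage 1: self-supervised HU training
# ---------------------------------------------------------------------------


def _normalize_spectra(spectra: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(spectra, axis=1, keepdims=True)
    return spectra / np.where(n > 0, n, 1.0)


#: stage-1 default learning rate.  The self-supervised stage (fixed linear
#: decoder + endmember guidance on the shared trunk) is rate-sensitive: a
#: hotter start can leave the encoder in a regime where the downstream
#: stage-2 normalization net cannot recover the concentration scale.
STAGE1_LR = 1e-3


def train_stage1(
    spectra: np.ndarray | list[np.ndarray],
    model: AcusaModel,
    opt: OptimizerConfig | None = None,
    seed: int = 17,
) -> AcusaModel:
    """Self-supervised stage: autoencoder reconstruction through the fixed
    decoder plus per-batch endmember guidance on the K pure spectra.

    ``spectra`` are corrected-domain fluorescence spectra (real unlabeled
    measurements unit-normalized, and/or synthetic mixtures); any labels are
    ignored here.  Inputs are fed at their natural magnitudes and randomly
    rescaled per batch so the encoder behaves well at every intensity the
    stage-2 normalizer may later produce; the reconstruction target is the
    unit-normalized spectral shape, which the rescaling leaves unchanged.
    """
    if opt is None:
        opt = OptimizerConfig(lr=STAGE1_LR)
    from . import nn as _nn

    B = model.library
    S = np.asarray(spectra, dtype=float)
    phi_nat = S.astype(_nn.DTYPE)  # natural-scale inputs and recon targets
    Bmat = B.B.astype(_nn.DTYPE)
    E = np.ascontiguousarray(Bmat.T)  # (K, m) unit-peak pure endmember spectra
    K = B.K
    eye = np.eye(K)
    hu, w = model.hu_encoder, model.hu_weights

    def loss_fn(z: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
        # Absolute-abundance reconstruction ||B z - phi||^2 against the
        # spectrum at its natural scale: ties the latent code's magnitude to
        # the input intensity, which the downstream normalization stage
        # relies on (a shape-only term leaves it unconstrained).
        N = z.shape[0]
        sr2 = np.exp(2 * w.log_sigma_rec.value)
        res = z @ Bmat.T - target
        res_sq = (res**2).sum(axis=1)
        dz = (res @ Bmat) / (sr2 * N)
        recon_loss = float(np.mean(res_sq)) / (2 * sr2)
        w.log_sigma_rec.grad += -float(np.mean(res_sq)) / sr2 + 1.0
        return recon_loss, dz

    params = hu.parameters() + w.parameters()
    optimizer = AdamW(params, lr=opt.lr, weight_decay=opt.weight_decay)
    sched = ReduceLROnPlateau(
        optimizer,
        factor=opt.plateau_factor,
        patience=opt.plateau_patience,
        threshold=opt.plateau_threshold,
        min_lr=opt.min_lr,
    )
    rng = np.random.default_rng(seed + 1)
    n = S.shape[0]
    bs = min(opt.batch_size, n)
    for _epoch in range(opt.max_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            optimizer.zero_grad()
            xb = phi_nat[idx]
            if opt.geom_augment_sigma > 0:
                # random per-sample intensity rescaling: the encoder must
                # behave sensibly at every magnitude the stage-2 normalizer
                # may later produce; input and reconstruction target scale
                # together, so the rescaling is label-free
                g = np.exp(rng.normal(0.0, 0.5, size=(len(idx), 1))).astype(xb.dtype)
                xb = xb * g
            z = hu.forward(xb[:, None, :])
            recon_loss, dz = loss_fn(z, xb)
            hu.backward_from_z(dz)
            # endmember guidance pass
            seg2 = float(np.exp(2 * w.log_sigma_eg.value))
            hu.forward(E[:, None, :])
            logp = log_softmax(hu.logits)
            ce_sum = float(-np.trace(logp))
            eg_loss = ce_sum / (2 * K * seg2)
            dlogits = (np.exp(logp) - eye) / (2 * K * seg2)
            hu.backward_from_z(np.zeros_like(dlogits), dlogits_extra=dlogits)
            w.log_sigma_eg.grad += -ce_sum / (K * seg2) + 1.0
            loss = recon_loss + eg_loss + float(
                w.log_sigma_eg.value + w.log_sigma_rec.value
            )
            optimizer.step()
            w.clamp()
            total += loss * len(idx)
        epoch_loss = total / n
        model.stage1_history.append(epoch_loss)
        sched.step(epoch_loss)
        if sched.done:
            break
    return model


# ---------------------------------------------------------------------------
# Stage 2: supervised normalization training with frozen HU
# ---------------------------------------------------------------------------


def train_stage2(
    pairs: list[SpectrumPair],
    model: AcusaModel,
    opt: OptimizerConfig = OptimizerConfig(),
    seed: int = 17,
) -> AcusaModel:
    """Train the normalization CNN through the frozen HU module so the
    composed model's PpIX634 abundance matches the labels."""
    if any(not p.labeled for p in pairs):
        raise ValueError("stage 2 requires labeled pairs")
    hu, norm = model.hu_encoder, model.norm_net
    i1 = model.ppix_index
    from . import nn as _nn

    X = _stack_inputs(pairs)
    c = np.array([p.c_ppix for p in pairs], dtype=_nn.DTYPE)
    params = norm.parameters()  # HU parameters deliberately excluded: frozen
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
            if opt.geom_augment_sigma > 0:  # distance invariance (see ACU-Net)
                g = np.exp(rng.normal(0.0, opt.geom_augment_sigma, size=(len(idx), 1)))
                scale = np.stack(
                    [g ** opt.geom_augment_exponent, g], axis=1
                ).astype(xb.dtype)
                xb = xb * scale
            if opt.input_noise_sd > 0:  # re-sampled camera noise (augmentation)
                xb = np.clip(
                    xb + rng.normal(0.0, opt.input_noise_sd, size=xb.shape).astype(xb.dtype),
                    0.0, None,
                )
            corrected = norm.forward(xb)  # (N, 1, m)
            z = hu.forward(corrected)
            r = z[:, i1] - c[idx]
            loss = float(np.mean(r**2))
            dz = np.zeros_like(z)
            dz[:, i1] = 2.0 * r / len(idx)
            dcorr = hu.backward_from_z(dz)  # gradient w.r.t. HU input
            norm.backward(dcorr)
            optimizer.step()
            total += loss * len(idx)
        epoch_loss = total / n
        model.stage2_history.append(epoch_loss)
        sched.step(epoch_loss)
        if sched.done:
            break
    preds = predict_acusa(model, pairs)[1]
    z1 = np.array([a.z[i1] for a in preds])
    denom = float(z1 @ z1)
    model.calibration_scale = float(z1 @ c) / denom if denom > 0 else 1.0
    return model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_acusa(
    model: AcusaModel, pairs: list[SpectrumPair], batch: int = 1024
) -> tuple[np.ndarray, list[AbundanceVector], np.ndarray]:
    """Returns (corrected spectra g(.), abundances z, reconstructions B z_hat).

    The corrected spectrum is exposed explicitly — it is the model's
    interpretable intermediate state.
    """
    X = _stack_inputs(pairs)
    corrected, zs = [], []
    for i in range(0, X.shape[0], batch):
        g = model.norm_net.forward(X[i : i + batch])
        corrected.append(g[:, 0, :])
        zs.append(model.hu_encoder.forward(g))
    corrected_arr = np.concatenate(corrected, axis=0)
    z = np.concatenate(zs, axis=0)
    zhat, _ = l2_normalize_rows(z)
    recon = zhat @ model.library.B.T
    return corrected_arr, [AbundanceVector(row) for row in z], recon
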