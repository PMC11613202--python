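"""Comparison methods: partial least squares and a naive MLP.

PLS regresses the concentration directly on the concatenated
(fluorescence, white) feature vector — representative of PCA-family
baselines.  The naive MLP is a fully connected net 2m -> 8 -> K -> 8 -> m
whose K-wide bottleneck is treated as the rectified abundance vector
(supervised on the concentration label) while the final m-wide output is a
reconstruction head supervised against the unit-normalized fluorescence
spectrum; both tasks are balanced by the same learned homoscedastic
uncertainties as the deep model, and the optimizer/schedule contracts match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .acunet import LossWeights, OptimizerConfig
from .nn import AdamW, Linear, Param, ReduceLROnPlateau, ReLU
from .spectral_core import EndmemberLibrary, SpectrumPair


@dataclass(frozen=True)
class MlpConfig:
    hidden: tuple[int, int, int] = (8, 5, 8)
    m: int = 104

    def __post_init__(self) -> None:
        if len(self.hidden) != 3:
            raise ValueError("expected three hidden sizes")
        if min(*self.hidden, self.m) <= 0:
            raise ValueError("sizes must be positive")

    @property
    def K(self) -> int:
        return self.hidden[1]


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------


class PlsPredictor:
    """Thin wrapper mapping SpectrumPairs -> predicted concentration."""

    def __init__(self, model: PLSRegression):
        self.model = model

    def predict(self, pairs: list[SpectrumPair]) -> np.ndarray:
        X = np.stack([np.concatenate([p.phi_fluo, p.phi_ref]) for p in pairs])
        return self.model.predict(X).ravel()


def fit_pls(pairs: list[SpectrumPair], n_components: int = 5) -> PlsPredictor:
    """Latent-variable regression of c_ppix on the stacked spectra."""
    if any(not p.labeled for p in pairs):
        raise ValueError("PLS requires labeled pairs")
    X = np.stack([np.concatenate([p.phi_fluo, p.phi_ref]) for p in pairs])
    y = np.array([p.c_ppix for p in pairs], dtype=float)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={min(X.shape)}"
        )
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, y)
    return PlsPredictor(model)


# ---------------------------------------------------------------------------
# Naive MLP
# ---------------------------------------------------------------------------


class MlpModel:
    """2m -> 8 -> K(bottleneck, rectified = z) -> 8 -> m reconstruction.

    Inputs are z-scored with statistics fit on the training set (stored on
    the model); a narrow fully connected net does not train reliably on raw
    intensity features spanning orders of magnitude.
    """

    def __init__(self, cfg: MlpConfig, seed: int):
        rng = np.random.default_rng(seed)
        h1, K, h2 = cfg.hidden
        self.cfg = cfg
        self.feat_mean = np.zeros(2 * cfg.m, dtype=np.float32)
        self.feat_sd = np.ones(2 * cfg.m, dtype=np.float32)
        self.f1 = Linear(2 * cfg.m, h1, rng)
        self.r1 = ReLU()
        self.f2 = Linear(h1, K, rng, bias_init=0.1, w_scale=0.01)
        self.r2 = ReLU()  # bottleneck rectifier -> z >= 0
        self.f3 = Linear(K, h2, rng)
        self.r3 = ReLU()
        self.f4 = Linear(h2, cfg.m, rng)
        self.r4 = ReLU()  # spectra are non-negative
        self.loss_weights = LossWeights()
        self.history: list[float] = []
        self.calibration_scale = 1.0
        self.ppix_index = 0

    def parameters(self) -> list[Param]:
        return [
            p
            for layer in (self.f1, self.f2, self.f3, self.f4)
            for p in layer.parameters()
        ]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """X (N, 2m, raw features) -> (z (N, K), recon (N, m))."""
        X = (X - self.feat_mean) / self.feat_sd
        z = self.r2.forward(self.f2.forward(self.r1.forward(self.f1.forward(X))))
        recon = self.r4.forward(self.f4.forward(self.r3.forward(self.f3.forward(z))))
        return z, recon

    def backward(self, dz: np.ndarray, drecon: np.ndarray) -> None:
        dz_total = dz + self.f3.backward(
            self.r3.backward(self.f4.backward(self.r4.backward(drecon)))
        )
        # same one-sided revival at the rectified bottleneck as the deep
        # model's abundance head: dead z channels may recover
        db = np.where(self.r2._mask | (dz_total < 0), dz_total, 0.0)
        self.f1.backward(self.r1.backward(self.f2.backward(db)))

    def predict(self, pairs: list[SpectrumPair]) -> tuple[np.ndarray, np.ndarray]:
        from . import nn as _nn

        X = np.stack([np.concatenate([p.phi_fluo, p.phi_ref]) for p in pairs]).astype(_nn.DTYPE)
        return self.forward(X)


def train_mlp(
    pairs: list[SpectrumPair],
    B: EndmemberLibrary,
    cfg: MlpConfig | None = None,
    opt: OptimizerConfig = OptimizerConfig(),
    seed: int = 17,
) -> MlpModel:
    """Train the naive MLP with the homoscedastic two-task loss."""
    if any(not p.labeled for p in pairs):
        raise ValueError("training set contains unlabeled pairs")
    m = B.grid.n_bands
    cfg = cfg or MlpConfig(hidden=(8, B.K, 8), m=m)
    if cfg.m != m:
        raise ValueError("config m must match the library grid")
    from . import nn as _nn

    model = MlpModel(cfg, seed)
    model.ppix_index = B.index_of("ppix634")
    X = np.stack([np.concatenate([p.phi_fluo, p.phi_ref]) for p in pairs]).astype(_nn.DTYPE)
    model.feat_mean = X.mean(axis=0)
    model.feat_sd = X.std(axis=0) + np.asarray(1e-6, dtype=X.dtype)
    c = np.array([p.c_ppix for p in pairs], dtype=_nn.DTYPE)
    phi = np.stack([p.phi_fluo for p in pairs])
    nrm = np.linalg.norm(phi, axis=1, keepdims=True)
    phi_norm = (phi / np.where(nrm > 0, nrm, 1.0)).astype(_nn.DTYPE)
    w = model.loss_weights
    params = model.parameters() + w.parameters()
    optimizer = AdamW(params, lr=opt.lr, weight_decay=opt.weight_decay)
    sched = ReduceLROnPlateau(
        optimizer, factor=opt.plateau_factor, patience=opt.plateau_patience,
        threshold=opt.plateau_threshold, min_lr=opt.min_lr,
    )
    rng = np.random.default_rng(seed + 1)
    n = X.shape[0]
    bs = min(opt.batch_size, n)
    i1 = model.ppix_index
    for _epoch in range(opt.max_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            optimizer.zero_grad()
            z, recon = model.forward(X[idx])
            sc2 = float(np.exp(2 * w.log_sigma_c.value))
            sr2 = float(np.exp(2 * w.log_sigma_rec.value))
            rc = z[:, i1] - c[idx]
            rr = recon - phi_norm[idx]
            rr_sq = (rr**2).sum(axis=1)
            loss = (
                float(np.mean(rc**2)) / (2 * sc2)
                + float(np.mean(rr_sq)) / (2 * sr2)
                + float(w.log_sigma_c.value + w.log_sigma_rec.value)
            )
            N = len(idx)
            dz = np.zeros_like(z)
            dz[:, i1] = rc / (sc2 * N)
            drecon = rr / (sr2 * N)
            model.backward(dz, drecon)
            w.log_sigma_c.grad += -float(np.mean(rc**2)) / sc2 + 1.0
            w.log_sigma_rec.grad += -float(np.mean(rr_sq)) / sr2 + 1.0
            optimizer.step()
            w.clamp()
            total += loss * N
        epoch_loss = total / n
        model.history.append(epoch_loss)
        sched.step(epoch_loss)
        if sched.done:
            break
    pred = model.forward(X)[0][:, i1]
    denom = float(pred @ pred)
    model.calibration_scale = float(pred @ c) / denom if denom > 0 else 1.0
    return model
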