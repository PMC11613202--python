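"""Metrics, statistical tests, group-wise splitting, and method comparison.

The headline quantification metric is the Pearson correlation R between the
predicted PpIX634 abundance and the known concentration on held-out groups;
RMSE is reported in label units after calibrating the prediction with a
single scaling factor fit by least squares on the training split.
Reconstruction MSE (ReMSE) compares B z_hat with the unit-normalized
measured spectrum.  The false-positive rate is the fraction of truly
PpIX-free spectra for which a method reports PpIX above a tolerance
(rectified networks never output exact zeros, so a tolerance is required;
the default is 1 percent of the maximum training-set prediction).

Splits are performed by group (phantom vial / homogenate sample / biopsy),
never by pixel, to avoid leakage between correlated pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import acunet as _acunet
from . import acusa as _acusa
from . import baselines as _baselines
from .acunet import AcunetConfig, OptimizerConfig
from .acusa import AcusaConfig
from .spectral_core import EndmemberLibrary, SpectrumPair, normalize_l2
from .unmix_classical import DualBandConfig, classical_pipeline, correct_dual_band, nnls_unmix

METHODS = ("classical", "acunet", "acusa", "pls", "mlp")


@dataclass
class EvalReport:
    method: str
    pearson_r: float
    r_squared: float
    rmse: float
    remse: float
    fpr: float
    n: int
    split_description: str

    def __post_init__(self) -> None:
        for name in ("pearson_r", "r_squared", "rmse", "remse", "fpr"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n < 2:
            raise ValueError("need n >= 2 for a correlation-based report")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "remse": self.remse,
            "fpr": self.fpr,
            "n": self.n,
            "split_description": self.split_description,
        }


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def pearson_r(pred, truth) -> float:
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("need two equal-length lists of at least 2 values")
    if np.var(pred) == 0 or np.var(truth) == 0:
        raise ValueError("zero variance input to pearson_r")
    return float(stats.pearsonr(pred, truth).statistic)


def fit_calibration_scale(pred, truth) -> float:
    """Least-squares single scaling factor: argmin_s ||s*pred - truth||."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    denom = float(pred @ pred)
    return float(pred @ truth) / denom if denom > 0 else 1.0


def rmse(pred, truth, calibration: float | None = None) -> float:
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    if calibration is not None:
        pred = calibration * pred
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def reconstruction_mse(reconstructions, measured, normalized: bool = True) -> float:
    """Mean over pixels of the mean squared per-band error; both sides
    unit-l2 normalized when ``normalized``."""
    R = np.atleast_2d(np.asarray(reconstructions, float))
    M = np.atleast_2d(np.asarray(measured, float))
    if R.shape != M.shape:
        raise ValueError("shape mismatch")
    if normalized:
        R = np.stack([normalize_l2(r) for r in R])
        M = np.stack([normalize_l2(m) for m in M])
    return float(np.mean(np.mean((R - M) ** 2, axis=1)))


def false_positive_rate(pred_ppix, threshold: float) -> float:
    """Fraction of (truly PpIX-free) predictions exceeding the tolerance."""
    pred = np.asarray(pred_ppix, float)
    if pred.size == 0:
        raise ValueError("false_positive_rate needs at least one prediction")
    return float(np.mean(pred > threshold))


def ks_2sample(a, b) -> tuple[float, float]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_by_group(
    pairs: list[SpectrumPair], test_frac: float = 0.15, seed: int = 0
) -> tuple[list[SpectrumPair], list[SpectrumPair]]:
    """Assign whole groups to train or test (never split a group).

    Groups are shuffled deterministically under ``seed`` and moved into the
    test side until its pixel count reaches the target fraction; the achieved
    fraction is within one group of the target.
    """
    groups = sorted({p.group_id for p in pairs})
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to split")
    if not (0.0 <= test_frac < 1.0):
        raise ValueError("test_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    order = [groups[i] for i in rng.permutation(len(groups))]
    target = test_frac * len(pairs)
    counts = {g: 0 for g in groups}
    for p in pairs:
        counts[p.group_id] += 1
    test_groups: set[str] = set()
    acc = 0
    for g in order:
        if acc >= target:
            break
        test_groups.add(g)
        acc += counts[g]
    train = [p for p in pairs if p.group_id not in test_groups]
    test = [p for p in pairs if p.group_id in test_groups]
    return train, test


# ---------------------------------------------------------------------------
# Method evaluation under one shared split
# ---------------------------------------------------------------------------


def _predict_ppix(
    method: str,
    train: list[SpectrumPair],
    test: list[SpectrumPair],
    B: EndmemberLibrary,
    seed: int,
    opt: OptimizerConfig,
    dual_band: DualBandConfig,
    acusa_cfg: AcusaConfig | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (train z1, test z1, test reconstructions B z_hat)."""
    i1 = B.index_of("ppix634")

    if method == "classical":
        def run(ps):
            zs = np.stack([classical_pipeline(p, B, dual_band).z for p in ps])
            return zs
        ztr, zte = run(train), run(test)
        zhat = zte / np.where(
            np.linalg.norm(zte, axis=1, keepdims=True) > 0,
            np.linalg.norm(zte, axis=1, keepdims=True), 1.0,
        )
        return ztr[:, i1], zte[:, i1], zhat @ B.B.T

    if method == "acunet":
        cfg = AcunetConfig(K=B.K, m=B.grid.n_bands)
        model = _acunet.train_acunet(train, B, cfg, opt, seed=seed)
        ztr = np.stack([a.z for a in _acunet.predict(model, train, B)[0]])
        abund, recon = _acunet.predict(model, test, B)
        zte = np.stack([a.z for a in abund])
        return ztr[:, i1], zte[:, i1], recon

    if method == "acusa":
        cfg = acusa_cfg or AcusaConfig(hu_cfg=AcunetConfig(K=B.K, m=B.grid.n_bands))
        model = _acusa.build_acusa(cfg, B, seed=seed)
        aug = _acusa.augment_mixtures(B, cfg.augment_n, cfg.augment_noise, seed=seed + 11)
        real = np.stack([normalize_l2(p.phi_fluo) for p in train])
        from dataclasses import replace as _replace

        stage1_opt = _replace(opt, lr=_acusa.STAGE1_LR)
        _acusa.train_stage1(np.vstack([aug, real]), model, stage1_opt, seed=seed)
        _acusa.train_stage2(train, model, opt, seed=seed + 1)
        _, abund_tr, _ = _acusa.predict_acusa(model, train)
        _, abund_te, recon = _acusa.predict_acusa(model, test)
        ztr = np.array([a.z[i1] for a in abund_tr])
        zte = np.array([a.z[i1] for a in abund_te])
        return ztr, zte, recon

    if method == "pls":
        predictor = _baselines.fit_pls(train, n_components=min(B.K, len(train) - 1))
        # PLS predicts concentration only; reconstruction via NNLS of the
        # dual-band-corrected spectrum for the ReMSE column
        recon = np.stack(
            [(nnls_unmix(correct_dual_band(p, dual_band), B).z_hat @ B.B.T) for p in test]
        )
        return predictor.predict(train), predictor.predict(test), recon

    if method == "mlp":
        model = _baselines.train_mlp(train, B, opt=opt, seed=seed)
        ztr = model.predict(train)[0][:, model.ppix_index]
        zte, recon = model.predict(test)
        return ztr, zte[:, model.ppix_index], recon

    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def evaluate_method(
    method: str,
    dataset: list[SpectrumPair],
    B: EndmemberLibrary,
    seed: int = 0,
    test_frac: float = 0.15,
    opt: OptimizerConfig = OptimizerConfig(),
    dual_band: DualBandConfig = DualBandConfig(),
    acusa_cfg: AcusaConfig | None = None,
    fpr_threshold_frac: float = 0.01,
    split: tuple[list[SpectrumPair], list[SpectrumPair]] | None = None,
) -> EvalReport:
    """Train (where applicable) and evaluate one method on a group-wise
    85/15 split.  Pass the same ``split`` to compare methods on identical
    test pairs."""
    if any(not p.labeled for p in dataset):
        raise ValueError("evaluation dataset must be labeled")
    train, test = split if split is not None else split_by_group(dataset, test_frac, seed)
    if not train or not test:
        raise ValueError("split produced an empty side")
    ptr, pte, recon = _predict_ppix(
        method, train, test, B, seed, opt, dual_band, acusa_cfg
    )
    c_te = np.array([p.c_ppix for p in test], dtype=float)
    c_tr = np.array([p.c_ppix for p in train], dtype=float)
    scale = fit_calibration_scale(ptr, c_tr)
    measured = np.stack([p.phi_fluo for p in test])
    eps = fpr_threshold_frac * float(ptr.max()) if ptr.max() > 0 else fpr_threshold_frac
    zero_mask = c_te == 0
    if zero_mask.any():
        fpr = false_positive_rate(pte[zero_mask], eps)
        fpr_src = "test"
    else:  # no PpIX-free group landed in the test split
        fpr = false_positive_rate(ptr[c_tr == 0], eps) if (c_tr == 0).any() else 0.0
        fpr_src = "train"
    r = pearson_r(pte, c_te)
    n_groups = len({p.group_id for p in dataset})
    n_test_groups = len({p.group_id for p in test})
    return EvalReport(
        method=method,
        pearson_r=r,
        r_squared=r**2,
        rmse=rmse(pte, c_te, calibration=scale),
        remse=reconstruction_mse(recon, measured, normalized=True),
        fpr=fpr,
        n=len(test),
        split_description=(
            f"group split seed={seed}: {n_test_groups}/{n_groups} groups held out "
            f"({len(test)}/{len(dataset)} pairs); fpr on {fpr_src} zero-conc pairs"
        ),
    )


def evaluate_methods(
    methods: list[str],
    dataset: list[SpectrumPair],
    B: EndmemberLibrary,
    seed: int = 0,
    **kwargs,
) -> dict[str, EvalReport]:
    """Evaluate several methods on one shared group-wise split."""
    split = split_by_group(dataset, kwargs.pop("test_frac", 0.15), seed)
    return {
        m: evaluate_method(m, dataset, B, seed=seed, split=split, **kwargs)
        for m in methods
    }


# ---------------------------------------------------------------------------
# Abundance maps
# ---------------------------------------------------------------------------


def abundance_map(
    z_values: np.ndarray,
    mask: np.ndarray,
    names: tuple[str, ...],
    path: str | None = None,
) -> np.ndarray:
    """Scatter per-pixel abundances back into image space.

    ``z_values`` is (n_pixels, K) aligned with ``mask``'s True pixels in
    row-major order.  Background pixels are NaN.  When ``path`` is given,
    renders one panel per endmember (viridis, NaN transparent) to the file.
    """
    z_values = np.asarray(z_values, float)
    K = z_values.shape[1]
    if len(names) != K:
        raise ValueError("need one name per endmember")
    if int(mask.sum()) != z_values.shape[0]:
        raise ValueError("mask true-count must equal the number of pixel predictions")
    maps = np.full((K, *mask.shape), np.nan)
    rows, cols = np.nonzero(mask)
    for k in range(K):
        maps[k, rows, cols] = z_values[:, k]
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, K, figsize=(3 * K, 3))
        axes = np.atleast_1d(axes)
        for k, ax in enumerate(axes):
            im = ax.imshow(maps[k], cmap="viridis")
            ax.set_title(names[k])
            ax.axis("off")
            fig.colorbar(im, ax=ax, fraction=0.046)
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return maps
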