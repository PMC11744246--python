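"""Wake EEG Similarity Index: a sparse robust logistic wake-likeness score.

Per 3-s window the four relative band powers are logit-transformed,
z-scored with constants estimated on the training split only, and
expanded to 14 predictors (4 linear, 6 pairwise products, 4 squares).
A 15-parameter L1-regularized logistic model with a Huberized loss maps
them to a score in (0, 1); per-stage means of the score are the five
subject-level features, analysed on the logit scale and reported on the
linear scale via a finite-difference back-transform.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

from .spectral import band_powers_from_psd, multitaper_psd
from .types import ArtifactMask, BAND_NAMES, EEGRecording, Hypnogram, STAGES

LOGIT_CLIP = 1e-6
N_BASE = 4
N_FEATURES = 14  # 4 linear + 6 products + 4 squares

#: (i, j) index pairs defining the 6 pairwise products, canonical order.
PRODUCT_PAIRS = [(i, j) for i in range(N_BASE) for j in range(i + 1, N_BASE)]


def window_band_powers_3s(
    recording: EEGRecording,
    mask: ArtifactMask | None = None,
    window_seconds: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative band powers per non-overlapping 3-s window.

    Returns ``(starts, relatives)`` where ``relatives`` is (n, 4);
    windows overlapping an artifact segment are dropped.  C3 and C4
    powers are summed before normalizing.
    """
    fs = recording.sample_rate
    nwin = int(round(window_seconds * fs))
    start0 = int(round(recording.lights_off * fs))
    starts_idx = np.arange(start0, recording.n_samples - nwin + 1, nwin)
    keep, rels = [], []
    for si in starts_idx:
        t = si / fs
        if mask is not None and mask.overlaps_artifact(t, t + window_seconds):
            continue
        total = np.zeros(N_BASE)
        for x in recording.channels.values():
            freqs, psd = multitaper_psd(x[si : si + nwin], fs)
            total += band_powers_from_psd(freqs, psd)
        s = total.sum()
        if s <= 0:
            continue
        keep.append(t)
        rels.append(total / s)
    return np.asarray(keep), np.asarray(rels).reshape(-1, N_BASE)


@dataclass
class Standardization:
    """Per-base-feature mean/SD of the logit powers, fit on training data."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, logits: np.ndarray) -> "Standardization":
        sd = logits.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=logits.mean(axis=0), sd=sd)

    def apply(self, logits: np.ndarray) -> np.ndarray:
        return (logits - self.mean) / self.sd


def logit_powers(relatives: np.ndarray) -> np.ndarray:
    clipped = np.clip(relatives, LOGIT_CLIP, 1.0 - LOGIT_CLIP)
    return logit(clipped)


def build_feature_matrix(relatives: np.ndarray, standardization: Standardization) -> np.ndarray:
    """Expand (n, 4) relative powers into the 14 model predictors.

    Order: 4 z-scored logits, 6 pairwise products, 4 squares; products
    and squares are computed from the z-scored logits and not
    re-standardized.
    """
    z = standardization.apply(logit_powers(np.atleast_2d(relatives)))
    products = np.stack([z[:, i] * z[:, j] for i, j in PRODUCT_PAIRS], axis=1)
    return np.hstack([z, products, z**2])


@dataclass
class WESIModel:
    """Fitted wake-similarity model: intercept + 14 coefficients."""

    intercept: float
    coef: np.ndarray  # (14,)
    standardization: Standardization
    lam: float = 0.1
    delta: float = 3.0
    split: float = 0.8
    seed: int = 0
    loss: str = "huber"
    test_indices: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_parameters(self) -> int:
        return 1 + len(self.coef)

    def decision(self, relatives: np.ndarray) -> np.ndarray:
        X = build_feature_matrix(relatives, self.standardization)
        return self.intercept + X @ self.coef

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coef": self.coef.tolist(),
                "standardization_mean": self.standardization.mean.tolist(),
                "standardization_sd": self.standardization.sd.tolist(),
                "lambda": self.lam,
                "delta": self.delta,
                "split": self.split,
                "seed": self.seed,
                "loss": self.loss,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "WESIModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coef=np.asarray(d["coef"]),
            standardization=Standardization(
                mean=np.asarray(d["standardization_mean"]),
                sd=np.asarray(d["standardization_sd"]),
            ),
            lam=d["lambda"],
            delta=d["delta"],
            split=d["split"],
            seed=d["seed"],
            loss=d["loss"],
        )


def _huberized_nll_and_weight(z: np.ndarray, delta: float, loss: str):
    """Loss per sample for margin z = (2y-1) * eta, plus d loss / d nll.

    For the 'huber' variant the Huber function is applied to the
    deviance residual r = sqrt(2 * nll): quadratic (= plain nll) while
    r <= delta, linear beyond, so only extreme misclassified windows
    are down-weighted.
    """
    nll = np.logaddexp(0.0, -z)
    if loss == "logistic":
        return nll, np.ones_like(nll)
    r = np.sqrt(2.0 * nll)
    big = r > delta
    out = np.where(big, delta * r - 0.5 * delta**2, nll)
    w = np.where(big, delta / np.maximum(r, 1e-12), 1.0)
    return out, w


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float, delta: float, loss: str):
    """L1 logistic via positive/negative split under L-BFGS-B bounds."""
    n, p = X.shape
    s = 2.0 * y - 1.0

    def objective(theta):
        b0 = theta[0]
        beta = theta[1 : p + 1] - theta[p + 1 :]
        eta = b0 + X @ beta
        z = s * eta
        l, w = _huberized_nll_and_weight(z, delta, loss)
        g_eta = -(s * expit(-z) * w) / n
        gb = X.T @ g_eta
        val = l.mean() + lam * theta[1:].sum()
        grad = np.concatenate([[g_eta.sum()], gb + lam, -gb + lam])
        return val, grad

    x0 = np.zeros(1 + 2 * p)
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    theta = res.x
    return float(theta[0]), theta[1 : p + 1] - theta[p + 1 :]


def train_test_split_indices(n: int, groups: np.ndarray | None, split: float, seed: int):
    """80/20 split; subject-wise when ``groups`` is given (no leakage)."""
    rng = np.random.default_rng(seed)
    if groups is None:
        perm = rng.permutation(n)
        cut = int(round(split * n))
        return perm[:cut], perm[cut:]
    uniq = np.unique(groups)
    perm = rng.permutation(len(uniq))
    cut = int(round(split * len(uniq)))
    train_groups = set(uniq[perm[:cut]].tolist())
    is_train = np.array([g in train_groups for g in groups])
    return np.flatnonzero(is_train), np.flatnonzero(~is_train)


def train(
    relatives: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
    split: float = 0.8,
    lam: float = 0.1,
    delta: float = 3.0,
    seed: int = 0,
    loss: str = "huber",
) -> WESIModel:
    """Fit the 15-parameter model on a random 80% split.

    ``labels`` are 1 for wake windows and 0 for sleep windows;
    ``groups`` (e.g. subject ids) makes the split subject-wise.
    Standardization constants come from the training split only.
    """
    relatives = np.asarray(relatives, dtype=float)
    labels = np.asarray(labels, dtype=float)
    tr, te = train_test_split_indices(len(labels), groups, split, seed)
    y_tr = labels[tr]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split contains a single class")
    standardization = Standardization.fit(logit_powers(relatives[tr]))
    X_tr = build_feature_matrix(relatives[tr], standardization)
    b0, coef = _fit_l1(X_tr, y_tr, lam, delta, loss)
    return WESIModel(
        intercept=b0, coef=coef, standardization=standardization,
        lam=lam, delta=delta, split=split, seed=seed, loss=loss, test_indices=te,
    )


def score(model: WESIModel, relatives: np.ndarray) -> np.ndarray:
    """Per-window wake-likeness in (0, 1)."""
    if model.coef is None:
        raise ValueError("model is not fitted")
    return expit(model.decision(np.asarray(relatives, dtype=float)))


def evaluate(model: WESIModel, relatives: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Accuracy at the 0.5 threshold and trapezoidal ROC AUC."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for a one-class test set")
    s = score(model, relatives)
    return {
        "accuracy": float(((s >= 0.5) == (labels == 1)).mean()),
        "auc": float(roc_auc_score(labels, s)),
    }


def stage_means(scores: np.ndarray, window_starts: np.ndarray, hyp: Hypnogram) -> dict[str, float]:
    """Mean score per stage (window assigned to the epoch containing its start)."""
    epochs = np.floor(np.asarray(window_starts) / hyp.epoch_seconds).astype(int)
    in_range = epochs < len(hyp)
    stages = np.array([hyp.stages[e] for e in epochs[in_range]])
    scores = np.asarray(scores)[in_range]
    return {
        st: (float(scores[stages == st].mean()) if (stages == st).any() else np.nan)
        for st in STAGES
    }


def logit_stage_means(means: dict[str, float]) -> dict[str, float]:
    """Logit of the per-stage means (clipped), for the group models."""
    out = {}
    for st, v in means.items():
        out[st] = float(logit(np.clip(v, LOGIT_CLIP, 1 - LOGIT_CLIP))) if np.isfinite(v) else np.nan
    return out


def _sigmoid_second_derivative_fd(m: float, h: float = 1e-4) -> float:
    return (expit(m + h) - 2.0 * expit(m) + expit(m - h)) / h**2


def linear_scale_summary(logit_mean: float, logit_se: float, z: float = 1.96) -> dict[str, float]:
    """Map a logit-scale mean and SE to the score scale.

    The mean uses a second-order finite-difference (delta-method)
    correction ``sigmoid(m) + 0.5 * sigmoid''(m) * se^2``; CI endpoints
    are the sigmoid of the logit-scale CI, so they always lie in (0, 1).
    """
    corr = 0.5 * _sigmoid_second_derivative_fd(logit_mean) * logit_se**2
    return {
        "mean": float(expit(logit_mean) + corr),
        "ci_low": float(expit(logit_mean - z * logit_se)),
        "ci_high": float(expit(logit_mean + z * logit_se)),
    }


def bootstrap_linear_mean(logit_values: np.ndarray, n_boot: int = 10_000, seed: int = 0) -> float:
    """Bootstrap E[sigmoid(sample mean)] over resamples of the logit values."""
    rng = np.random.default_rng(seed)
    vals = np.asarray(logit_values, dtype=float)
    n = len(vals)
    idx = rng.integers(0, n, size=(n_boot, n))
    return float(expit(vals[idx].mean(axis=1)).mean())


def validate_backtransform(logit_values: np.ndarray, n_boot: int = 10_000, seed: int = 0) -> float:
    """|finite-difference mean - bootstrap mean| for one group's logit scores."""
    vals = np.asarray(logit_values, dtype=float)
    m = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    approx = linear_scale_summary(m, se)["mean"]
    boot = bootstrap_linear_mean(vals, n_boot=n_boot, seed=seed)
    return abs(approx - boot)
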