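"""Calibration and distance losses for bag-level training.

For binary category labels y_m the calibration loss of bag m is

    E_m = (y_m - o)^2 / o + (y_m - o)^2 / (1 - o),      o = aggregated output,

summed over bags; with mean aggregation, labels taken as group event
proportions and each term weighted by the bag size n_m this is exactly the
Hosmer-Lemeshow goodness-of-fit statistic, which is what makes the trained
model statistically interpretable.  For vector labels [pR, pT] the loss is
a sum of pairwise distances dist(o-hat_m, y_m); Euclidean (the printed
quadratic form), Mahalanobis (covariance-whitened, for correlated
endpoints) and Minkowski distances are provided, plus the conventional MSE
and cross-entropy baselines used for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "LossSpec",
    "calibration_loss",
    "euclidean_dist",
    "mahalanobis_dist",
    "minkowski_dist",
    "distance_loss",
    "baseline_loss",
    "loss_value_and_grad",
]


@dataclass
class LossSpec:
    """Selects and parameterizes the training loss.

    ``weight_by_bag_size=False`` is the literal summed form; ``True``
    multiplies each bag term by n_m, the variant under which the
    calibration loss coincides with the Hosmer-Lemeshow statistic.
    """

    mode: Literal["category_calibration", "vector_distance", "mse", "cel"] = (
        "category_calibration"
    )
    metric: str = "median"
    distance: Literal["euclidean", "mahalanobis", "minkowski"] = "euclidean"
    V: np.ndarray | None = None
    p: float = 2.0
    eps: float = 1e-7
    weight_by_bag_size: bool = False
    sqrt: bool = False  # metric (square-rooted) form of euclidean/mahalanobis
    ridge: float = 1e-10  # regularization for near-singular V

    def __post_init__(self) -> None:
        if not 0.0 < self.eps <= 0.01:
            raise ValueError("eps must be in (0, 0.01]")
        if self.p <= 0:
            raise ValueError("Minkowski order p must be > 0")
        if self.V is not None:
            self.V = np.asarray(self.V, dtype=float)


def _clip(o: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(o, eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# calibration loss (binary labels)

def calibration_loss(
    y: Sequence[float],
    o_hat: Sequence[float],
    spec: LossSpec | None = None,
    bag_sizes: Sequence[int] | None = None,
) -> float:
    """Sum over bags of (y-o)^2/o + (y-o)^2/(1-o).

    ``y`` are bag labels in {0,1} (group event proportions in [0,1] are
    also accepted for the HL-weighted variant); outputs are clipped to
    [eps, 1-eps] before the divisions.
    """
    value, _ = _calibration_value_grad(y, o_hat, spec or LossSpec(), bag_sizes)
    return value


def _calibration_value_grad(y, o_hat, spec, bag_sizes):
    y = np.asarray(y, dtype=float).ravel()
    o = np.asarray(o_hat, dtype=float).ravel()
    if y.shape != o.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {o.shape} outputs")
    if y.size == 0:
        raise ValueError("need at least one bag")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("calibration labels must lie in [0, 1]")
    w = np.ones_like(y)
    if spec.weight_by_bag_size:
        if bag_sizes is None:
            raise ValueError("weight_by_bag_size=True requires bag_sizes")
        w = np.asarray(bag_sizes, dtype=float)
    oc = _clip(o, spec.eps)
    r = y - oc
    terms = r**2 / oc + r**2 / (1.0 - oc)
    # d/do [r^2/o] = (-2 r o - r^2)/o^2 ; d/do [r^2/(1-o)] = (-2 r (1-o) + r^2)/(1-o)^2
    grad = (-2.0 * r * oc - r**2) / oc**2 + (-2.0 * r * (1.0 - oc) + r**2) / (1.0 - oc) ** 2
    inside = (o > spec.eps) & (o < 1.0 - spec.eps)
    return float(np.sum(w * terms)), w * grad * inside


# ---------------------------------------------------------------------------
# distances

def euclidean_dist(y1, y2, sqrt: bool = False) -> float:
    """(y1-y2)(y1-y2)^T — the printed quadratic form; sqrt=True for the metric."""
    d = np.asarray(y1, dtype=float) - np.asarray(y2, dtype=float)
    if np.asarray(y1).shape != np.asarray(y2).shape:
        raise ValueError("dimension mismatch")
    q = float(d @ d)
    return float(np.sqrt(q)) if sqrt else q


def _check_spd(V: np.ndarray, ridge: float):
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("V must be square")
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValueError("V must be symmetric")
    eigvals = np.linalg.eigvalsh(V)
    if eigvals[0] <= 0:
        raise ValueError(
            f"V is not positive definite: smallest eigenvalue {eigvals[0]:.3g}"
        )
    if eigvals[0] / eigvals[-1] < 1e-12:
        warnings.warn(
            f"V is near-singular (condition {eigvals[-1] / eigvals[0]:.3g}); "
            f"adding ridge {ridge:g}",
            stacklevel=3,
        )
        V = V + ridge * np.eye(V.shape[0])
    return V


def mahalanobis_dist(y1, y2, V, sqrt: bool = False, ridge: float = 1e-10) -> float:
    """(y1-y2) V^-1 (y1-y2)^T; reduces to the Euclidean form when V = I."""
    V = _check_spd(V, ridge)
    d = np.asarray(y1, dtype=float) - np.asarray(y2, dtype=float)
    if d.shape[0] != V.shape[0]:
        raise ValueError("dimension mismatch between vectors and V")
    sol = cho_solve(cho_factor(V), d)
    q = float(d @ sol)
    return float(np.sqrt(max(q, 0.0))) if sqrt else q


def minkowski_dist(y1, y2, p: float = 2.0) -> float:
    """Standard l_p distance (sum |delta_i|^p)^(1/p); p=2 is metric Euclidean."""
    if p <= 0:
        raise ValueError("Minkowski order p must be > 0")
    d = np.abs(np.asarray(y1, dtype=float) - np.asarray(y2, dtype=float))
    if np.asarray(y1).shape != np.asarray(y2).shape:
        raise ValueError("dimension mismatch")
    return float(np.sum(d**p) ** (1.0 / p))


# ---------------------------------------------------------------------------
# distance loss over bags (vector labels)

def distance_loss(
    y_bags: Sequence, o_hat: Sequence, spec: LossSpec | None = None,
    bag_sizes: Sequence[int] | None = None,
) -> float:
    """Sum over bags of dist(o-hat_m, y_m) with the spec's distance."""
    value, _ = _distance_value_grad(y_bags, o_hat, spec or LossSpec(mode="vector_distance"), bag_sizes)
    return value


def _distance_value_grad(y_bags, o_hat, spec, bag_sizes):
    Y = np.atleast_2d(np.asarray(y_bags, dtype=float))
    O = np.atleast_2d(np.asarray(o_hat, dtype=float))
    if Y.shape != O.shape:
        raise ValueError(f"shape mismatch: labels {Y.shape} vs outputs {O.shape}")
    w = np.ones(Y.shape[0])
    if spec.weight_by_bag_size:
        if bag_sizes is None:
            raise ValueError("weight_by_bag_size=True requires bag_sizes")
        w = np.asarray(bag_sizes, dtype=float)
    D = O - Y
    if spec.distance == "euclidean":
        if spec.sqrt:
            norms = np.sqrt(np.sum(D**2, axis=1))
            value = float(np.sum(w * norms))
            safe = np.where(norms > 0, norms, 1.0)[:, None]
            grad = w[:, None] * D / safe
        else:
            value = float(np.sum(w * np.sum(D**2, axis=1)))
            grad = 2.0 * w[:, None] * D
    elif spec.distance == "mahalanobis":
        if spec.V is None:
            raise ValueError("mahalanobis distance requires spec.V")
        V = _check_spd(spec.V, spec.ridge)
        sol = cho_solve(cho_factor(V), D.T).T  # rows: V^-1 (o - y)
        q = np.sum(D * sol, axis=1)
        if spec.sqrt:
            norms = np.sqrt(np.maximum(q, 0.0))
            value = float(np.sum(w * norms))
            safe = np.where(norms > 0, norms, 1.0)[:, None]
            grad = w[:, None] * sol / safe
        else:
            value = float(np.sum(w * q))
            grad = 2.0 * w[:, None] * sol
    elif spec.distance == "minkowski":
        p = spec.p
        absd = np.abs(D)
        s = np.sum(absd**p, axis=1)
        norms = s ** (1.0 / p)
        value = float(np.sum(w * norms))
        safe_s = np.where(s > 0, s, 1.0)
        grad = (
            w[:, None]
            * (safe_s ** (1.0 / p - 1.0))[:, None]
            * absd ** (p - 1.0)
            * np.sign(D)
        )
        grad[s == 0] = 0.0
    else:
        raise ValueError(f"unknown distance {spec.distance!r}")
    return value, grad


# ---------------------------------------------------------------------------
# baselines

def baseline_loss(
    y: Sequence[float], o_hat: Sequence[float], kind: Literal["mse", "cel"],
    eps: float = 1e-7,
) -> float:
    """Conventional comparison losses: summed squared error or cross-entropy."""
    value, _ = _baseline_value_grad(y, o_hat, kind, eps)
    return value


def _baseline_value_grad(y, o_hat, kind, eps):
    y = np.asarray(y, dtype=float).ravel()
    o = np.asarray(o_hat, dtype=float).ravel()
    if y.shape != o.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {o.shape}")
    if kind == "mse":
        return float(np.sum((y - o) ** 2)), 2.0 * (o - y)
    if kind == "cel":
        if np.any((y < 0) | (y > 1)):
            raise ValueError("cross-entropy labels must lie in [0, 1]")
        oc = _clip(o, eps)
        value = float(-np.sum(y * np.log(oc) + (1.0 - y) * np.log(1.0 - oc)))
        inside = (o > eps) & (o < 1.0 - eps)
        grad = (oc - y) / (oc * (1.0 - oc)) * inside
        return value, grad
    raise ValueError(f"unknown baseline loss {kind!r}")


# ---------------------------------------------------------------------------
# unified dispatch used by the trainer

def loss_value_and_grad(
    Y: np.ndarray,
    O_hat: np.ndarray,
    spec: LossSpec,
    bag_sizes: Sequence[int] | None = None,
) -> tuple[float, np.ndarray]:
    """Loss value and gradient d(loss)/d(O_hat), shape matching O_hat."""
    if spec.mode == "vector_distance":
        value, grad = _distance_value_grad(Y, O_hat, spec, bag_sizes)
        return value, grad
    Yf = np.asarray(Y, dtype=float)
    Of = np.asarray(O_hat, dtype=float)
    shape = Of.shape
    if spec.mode == "category_calibration":
        value, grad = _calibration_value_grad(Yf, Of, spec, bag_sizes)
    elif spec.mode in ("mse", "cel"):
        value, grad = _baseline_value_grad(Yf, Of, spec.mode, spec.eps)
    else:
        raise ValueError(f"unknown loss mode {spec.mode!r}")
    return value, grad.reshape(shape)
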