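"""The multiple-instance regression network f: x -> y.

A small fully connected network maps each patient's burden vector to an
output in (0, 1)^k (k = 1 for category labels, k = 2 for [pR, pT] labels);
instance outputs are pooled into a bag prediction by one of four
aggregation metrics (median / maximum / minimum / mean).  Forward and
backward passes are written directly in numpy; gradients through the
non-smooth aggregations use the standard subgradient conventions (selected
instance for max/min with ties averaged, 0.5/0.5 on the central pair for an
even-count median, uniform 1/n for the mean).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import Cohort, FeatureScaler, SubgroupBag, aggregate_metric

__all__ = [
    "MILNetwork",
    "BagPrediction",
    "init_network",
    "predict_bag",
    "aggregation_weights",
    "save_checkpoint",
    "load_checkpoint",
]


class MILNetwork:
    """Fully connected net with tanh hidden layers and logistic outputs.

    ``hidden_widths=[]`` degenerates to plain logistic regression (direct
    input-to-output affine map through the logistic squashing).
    """

    def __init__(
        self,
        input_dim: int,
        hidden_widths: Sequence[int] = (16,),
        output_dim: int = 1,
        seed: int = 0,
    ) -> None:
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if output_dim not in (1, 2):
            raise ValueError("output_dim must be 1 or 2")
        if any(h <= 0 for h in hidden_widths):
            raise ValueError("hidden widths must be positive")
        self.input_dim = int(input_dim)
        self.hidden_widths = [int(h) for h in hidden_widths]
        self.output_dim = int(output_dim)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        sizes = [self.input_dim, *self.hidden_widths, self.output_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # Glorot-uniform: keeps tanh pre-activations in the linear regime
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._cache: list[np.ndarray] | None = None

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    # ----- forward / backward ------------------------------------------------

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        """Instance outputs in (0, 1)^output_dim for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"feature dimension {X.shape[1]} != network input_dim {self.input_dim}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        activations = [X]
        a = X
        n_layers = len(self.weights)
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = _sigmoid(z) if layer == n_layers - 1 else np.tanh(z)
            activations.append(a)
        if cache:
            self._cache = activations
        return a

    def backward(self, grad_out: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Backprop dE/d(output) to parameter gradients; needs a cached forward."""
        if self._cache is None:
            raise RuntimeError("call forward(..., cache=True) before backward()")
        activations = self._cache
        grad_out = np.atleast_2d(np.asarray(grad_out, dtype=float))
        out = activations[-1]
        delta = grad_out * out * (1.0 - out)  # through the logistic output
        gW = [np.empty(0)] * len(self.weights)
        gb = [np.empty(0)] * len(self.biases)
        for layer in range(len(self.weights) - 1, -1, -1):
            a_prev = activations[layer]
            gW[layer] = a_prev.T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (1.0 - a_prev**2)
        return gW, gb

    def apply_gradients(self, gW, gb, learning_rate: float,
                        vW=None, vb=None, momentum: float = 0.0):
        """In-place gradient-descent step, optionally with momentum buffers."""
        for i in range(len(self.weights)):
            if momentum > 0.0 and vW is not None:
                vW[i] = momentum * vW[i] - learning_rate * gW[i]
                vb[i] = momentum * vb[i] - learning_rate * gb[i]
                self.weights[i] += vW[i]
                self.biases[i] += vb[i]
            else:
                self.weights[i] -= learning_rate * gW[i]
                self.biases[i] -= learning_rate * gb[i]

    # ----- (de)serialization helpers ----------------------------------------

    def get_params(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights]
                              + [b.ravel() for b in self.biases])

    def set_params(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=float)
        i = 0
        for w in self.weights:
            w[...] = flat[i : i + w.size].reshape(w.shape)
            i += w.size
        for b in self.biases:
            b[...] = flat[i : i + b.size].reshape(b.shape)
            i += b.size

    def copy(self) -> "MILNetwork":
        net = MILNetwork(self.input_dim, self.hidden_widths, self.output_dim, self.seed)
        net.set_params(self.get_params())
        return net


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_network(
    d: int,
    hidden_widths: Sequence[int] = (16,),
    output_dim: int = 1,
    seed: int = 0,
) -> MILNetwork:
    """Construct a seeded MIL network (default one hidden layer of 16 units)."""
    return MILNetwork(d, hidden_widths, output_dim, seed)


@dataclass
class BagPrediction:
    """Instance outputs o_mi of one bag and their aggregate o-hat_m."""

    bag_id: str
    instance_outputs: np.ndarray  # (n_m, output_dim)
    aggregated: np.ndarray  # (output_dim,)
    metric: str


def predict_bag(
    net: MILNetwork,
    bag: SubgroupBag,
    patients: dict,
    metric: str = "median",
) -> BagPrediction:
    """Forward every member of a bag and pool by the aggregation metric."""
    if bag.n == 0:
        raise ValueError(f"bag {bag.bag_id} is empty")
    X = np.vstack([patients[pid].features for pid in bag.member_ids])
    O = net.forward(X)
    agg = np.atleast_1d(aggregate_metric(O, metric))
    return BagPrediction(bag.bag_id, O, agg, metric)


def aggregation_weights(O: np.ndarray, metric: str) -> np.ndarray:
    """Jacobian weights W with d(aggregate_j)/d(O_ij) = W_ij.

    Columns sum to 1.  For max/min the weight sits on the attaining
    instance(s), averaged over ties; for the median on the central order
    statistic (0.5/0.5 over the central pair when n is even), spread over
    value ties; for the mean uniformly 1/n.
    """
    O = np.atleast_2d(np.asarray(O, dtype=float))
    n, k = O.shape
    W = np.zeros_like(O)
    if metric == "mean":
        W[:] = 1.0 / n
        return W
    for j in range(k):
        col = O[:, j]
        if metric in ("maximum", "minimum"):
            target = col.max() if metric == "maximum" else col.min()
            sel = col == target
            W[sel, j] = 1.0 / sel.sum()
        elif metric == "median":
            order = np.argsort(col, kind="stable")
            if n % 2 == 1:
                centers = {col[order[n // 2]]: 1.0}
            else:
                lo, hi = col[order[n // 2 - 1]], col[order[n // 2]]
                if lo == hi:
                    centers = {lo: 1.0}
                else:
                    centers = {lo: 0.5, hi: 0.5}
            for value, weight in centers.items():
                sel = col == value
                W[sel, j] += weight / sel.sum()
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return W


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(
    net: MILNetwork, path: str | Path, scaler: FeatureScaler | None = None,
    extra: dict | None = None,
) -> None:
    """Write architecture, seed, weights and (optionally) the scaler as JSON."""
    payload = {
        "format": "tmbserval-checkpoint-v1",
        "input_dim": net.input_dim,
        "hidden_widths": net.hidden_widths,
        "output_dim": net.output_dim,
        "seed": net.seed,
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "scaler": scaler.to_dict() if scaler is not None else None,
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(
    path: str | Path, expected_dim: int | None = None
) -> tuple[MILNetwork, FeatureScaler | None, dict]:
    """Load a checkpoint; refuses a mismatched feature dimension."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "tmbserval-checkpoint-v1":
        raise ValueError(f"{path} is not a tmbserval checkpoint")
    if expected_dim is not None and payload["input_dim"] != expected_dim:
        raise ValueError(
            f"checkpoint input_dim {payload['input_dim']} != expected {expected_dim}"
        )
    net = MILNetwork(
        payload["input_dim"], payload["hidden_widths"], payload["output_dim"],
        payload["seed"],
    )
    net.weights = [np.asarray(w, dtype=float) for w in payload["weights"]]
    net.biases = [np.asarray(b, dtype=float) for b in payload["biases"]]
    scaler = (
        FeatureScaler.from_dict(payload["scaler"])
        if payload.get("scaler") is not None
        else None
    )
    return net, scaler, payload.get("extra", {})
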