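"""Training (full-batch gradient descent over bag aggregates), k-fold
cross-validation, learning curves, the Hosmer-Lemeshow test and the
four-learner comparison.

Training minimizes the selected bag-level loss: each epoch forwards every
patient, pools instance outputs into one prediction per bag, computes the
loss against the bag labels and backpropagates through the aggregation
(subgradient weights) and the network.  Cross-validation splits *within*
bags — every fold retains all bags, each contributing ~1/k of its members —
because the bags themselves carry the supervision and there are only a
handful of them.
"""

from __future__ import annotations

import time as _time
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort import Cohort, FeatureScaler, PatientRecord, SubgroupBag
from .losses import LossSpec, loss_value_and_grad
from .network import MILNetwork, aggregation_weights, init_network

__all__ = [
    "TrainConfig",
    "TrainReport",
    "HLResult",
    "train",
    "kfold_cv",
    "learning_curve",
    "hosmer_lemeshow",
    "compare_learners",
    "split_train_test",
    "evaluate_loss",
]


@dataclass
class TrainConfig:
    """Gradient-descent hyperparameters (full-batch, per the global loss E)."""

    learning_rate: float = 0.2
    max_epochs: int = 5000
    tolerance: float = 1e-3  # stop when E <= tolerance
    momentum: float = 0.0
    seed: int = 0
    patience: int | None = None  # early stop on non-improving training loss

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class TrainReport:
    loss_trace: list[float]
    final_train_loss: float
    n_epochs: int
    seed: int
    wall_clock_s: float
    validation_loss: float | None = None
    test_loss: float | None = None


@dataclass
class HLResult:
    """Hosmer-Lemeshow goodness-of-fit result."""

    statistic: float
    groups: int
    df: int
    p_value: float
    table: pd.DataFrame  # per group: n, observed, expected, mean_pred


def _bag_targets(bags: Sequence[SubgroupBag], output_dim: int) -> np.ndarray:
    Y = np.empty((len(bags), output_dim))
    for i, b in enumerate(bags):
        if b.label is None:
            raise ValueError(f"bag {b.bag_id} has no label")
        Y[i] = np.atleast_1d(np.asarray(b.label, dtype=float))
    return Y


def _forward_bags(net, X, bag_slices, metric):
    """One cohort forward pass + per-bag aggregation with gradient weights."""
    O = net.forward(X, cache=True)
    M = len(bag_slices)
    O_hat = np.empty((M, net.output_dim))
    weights = []
    for i, idx in enumerate(bag_slices):
        W = aggregation_weights(O[idx], metric)
        O_hat[i] = (W * O[idx]).sum(axis=0)
        weights.append(W)
    return O, O_hat, weights


def train(
    net: MILNetwork,
    bags: Sequence[SubgroupBag],
    patients: dict[str, PatientRecord],
    loss_spec: LossSpec,
    config: TrainConfig | None = None,
) -> tuple[MILNetwork, TrainReport]:
    """Full-batch gradient descent on the bag-level loss until E <= tolerance.

    Deterministic given the network seed and input ordering.  Aborts with a
    diagnostic naming the offending bag if the loss goes non-finite.
    """
    config = config or TrainConfig()
    order = [pid for b in bags for pid in b.member_ids]
    X = np.vstack([patients[pid].features for pid in order])
    bag_slices = []
    start = 0
    for b in bags:
        bag_slices.append(np.arange(start, start + b.n))
        start += b.n
    Y = _bag_targets(bags, net.output_dim)
    bag_sizes = [b.n for b in bags]

    vW = [np.zeros_like(w) for w in net.weights]
    vb = [np.zeros_like(b) for b in net.biases]
    trace: list[float] = []
    best, since_best = np.inf, 0
    t_start = _time.perf_counter()
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        O, O_hat, agg_w = _forward_bags(net, X, bag_slices, loss_spec.metric)
        value, grad_bags = loss_value_and_grad(Y, O_hat, loss_spec, bag_sizes)
        if not np.isfinite(value):
            per_bag = [
                loss_value_and_grad(Y[i : i + 1], O_hat[i : i + 1], loss_spec,
                                    bag_sizes[i : i + 1])[0]
                for i in range(len(bags))
            ]
            bad = bags[int(np.argmax(~np.isfinite(per_bag)))].bag_id
            raise RuntimeError(
                f"non-finite loss at epoch {epoch} (first offending bag {bad})"
            )
        trace.append(value)
        if value <= config.tolerance:
            break
        # distribute bag-level gradients to instances via aggregation weights
        grad_O = np.zeros_like(O)
        for i, idx in enumerate(bag_slices):
            grad_O[idx] += agg_w[i] * grad_bags[i]
        gW, gb = net.backward(grad_O)
        net.apply_gradients(gW, gb, config.learning_rate, vW, vb, config.momentum)
        if config.patience is not None:
            if value < best - 1e-12:
                best, since_best = value, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    report = TrainReport(
        loss_trace=trace,
        final_train_loss=trace[-1] if trace else np.nan,
        n_epochs=epoch,
        seed=config.seed,
        wall_clock_s=_time.perf_counter() - t_start,
    )
    return net, report


def evaluate_loss(
    net: MILNetwork,
    bags: Sequence[SubgroupBag],
    patients: dict[str, PatientRecord],
    loss_spec: LossSpec,
) -> float:
    """Bag-level loss of a fixed network on a (sub)cohort."""
    order = [pid for b in bags for pid in b.member_ids]
    X = np.vstack([patients[pid].features for pid in order])
    bag_slices, start = [], 0
    for b in bags:
        bag_slices.append(np.arange(start, start + b.n))
        start += b.n
    _, O_hat, _ = _forward_bags(net, X, bag_slices, loss_spec.metric)
    Y = _bag_targets(bags, net.output_dim)
    value, _ = loss_value_and_grad(Y, O_hat, loss_spec, [b.n for b in bags])
    return value


# ---------------------------------------------------------------------------
# splits

def _within_bag_folds(bags: Sequence[SubgroupBag], k: int, rng) -> dict[str, int]:
    """Fold id per patient; every bag spreads its members over all k folds."""
    fold_of: dict[str, int] = {}
    for b in bags:
        if b.n < k:
            raise ValueError(
                f"bag {b.bag_id} has {b.n} members < k={k}; lower k"
            )
        members = list(b.member_ids)
        rng.shuffle(members)
        for i, pid in enumerate(members):
            fold_of[pid] = i % k
    return fold_of


def split_train_test(
    cohort: Cohort, fraction: float, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Bag-stratified disjoint train/test split; `fraction` goes to train."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for b in cohort.bags:
        members = list(b.member_ids)
        rng.shuffle(members)
        n_train = int(round(fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_ids.extend(members[:n_train])
        test_ids.extend(members[n_train:])
    if not train_ids or not test_ids:
        raise ValueError("fraction produces an empty split")
    return cohort.subset(train_ids), cohort.subset(test_ids)


def _scaled_view(cohort: Cohort, scaler: FeatureScaler) -> dict[str, PatientRecord]:
    """Patients with standardized features (originals untouched)."""
    import dataclasses as _dc

    Z = scaler.transform(cohort.feature_matrix())
    return {
        p.patient_id: _dc.replace(p, features=Z[i])
        for i, p in enumerate(cohort.patients)
    }


def _fit_eval_split(
    train_cohort: Cohort, val_cohort: Cohort, loss_spec: LossSpec,
    config: TrainConfig, hidden_widths, output_dim: int, seed: int,
) -> tuple[float, float, MILNetwork, FeatureScaler]:
    scaler = FeatureScaler().fit(train_cohort.feature_matrix())
    net = init_network(train_cohort.d, hidden_widths, output_dim, seed=seed)
    net, report = train(
        net, train_cohort.bags, _scaled_view(train_cohort, scaler), loss_spec, config
    )
    val = evaluate_loss(net, val_cohort.bags, _scaled_view(val_cohort, scaler), loss_spec)
    return report.final_train_loss, val, net, scaler


def kfold_cv(
    cohort: Cohort,
    loss_spec: LossSpec,
    train_config: TrainConfig | None = None,
    k: int = 10,
    seed: int = 0,
    hidden_widths: Sequence[int] = (16,),
    output_dim: int | None = None,
) -> dict:
    """k-fold cross-validation with within-bag patient splitting.

    The scaler is refit on each fold's training split.  Returns per-fold and
    mean validation losses (and the matching training losses).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    train_config = train_config or TrainConfig()
    if output_dim is None:
        output_dim = np.atleast_1d(np.asarray(cohort.bags[0].label)).size
    rng = np.random.default_rng(seed)
    fold_of = _within_bag_folds(cohort.bags, k, rng)
    fold_losses, train_losses = [], []
    for fold in range(k):
        val_ids = [pid for pid, f in fold_of.items() if f == fold]
        train_ids = [pid for pid, f in fold_of.items() if f != fold]
        tr, va = cohort.subset(train_ids), cohort.subset(val_ids)
        tr_loss, va_loss, _, _ = _fit_eval_split(
            tr, va, loss_spec, train_config, hidden_widths, output_dim,
            seed=train_config.seed + fold,
        )
        train_losses.append(tr_loss)
        fold_losses.append(va_loss)
    return {
        "fold_losses": fold_losses,
        "mean_loss": float(np.mean(fold_losses)),
        "train_losses": train_losses,
        "mean_train_loss": float(np.mean(train_losses)),
        "k": k,
        "seed": seed,
    }


def learning_curve(
    cohort: Cohort,
    sizes: Sequence[int],
    loss_spec: LossSpec,
    train_config: TrainConfig | None = None,
    repeats: int = 3,
    val_fraction: float = 0.25,
    seed: int = 0,
    hidden_widths: Sequence[int] = (16,),
    output_dim: int | None = None,
) -> pd.DataFrame:
    """Train/validation loss versus training-set size (bag proportions kept).

    For each size, training patients are subsampled from a fixed
    bag-stratified training split and the loss on the held-out validation
    split is recorded, averaged over `repeats` subsample draws.
    """
    train_config = train_config or TrainConfig()
    if output_dim is None:
        output_dim = np.atleast_1d(np.asarray(cohort.bags[0].label)).size
    sizes = sorted(sizes)
    rows = []
    for rep in range(repeats):
        tr_full, va = split_train_test(cohort, 1.0 - val_fraction, seed=seed + rep)
        if sizes[-1] > tr_full.n:
            raise ValueError(
                f"largest size {sizes[-1]} exceeds training pool {tr_full.n}"
            )
        rng = np.random.default_rng(seed + 1000 * rep)
        for size in sizes:
            sub_ids = []
            for b in tr_full.bags:
                n_b = max(2, int(round(size * b.n / tr_full.n)))
                members = list(b.member_ids)
                rng.shuffle(members)
                sub_ids.extend(members[: min(n_b, b.n)])
            tr = tr_full.subset(sub_ids)
            tr_loss, va_loss, _, _ = _fit_eval_split(
                tr, va, loss_spec, train_config, hidden_widths, output_dim,
                seed=train_config.seed + rep,
            )
            rows.append(
                {"size": size, "n_used": tr.n, "repeat": rep,
                 "train_loss": tr_loss, "validation_loss": va_loss}
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby("size", as_index=False)
        .agg(n_used=("n_used", "mean"), train_loss=("train_loss", "mean"),
             validation_loss=("validation_loss", "mean"))
    )


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow

def hosmer_lemeshow(
    y_true: Sequence[float], p_pred: Sequence[float], groups: int = 10,
    eps: float = 1e-7,
) -> HLResult:
    """Hosmer-Lemeshow chi-square test on g equal-count risk groups.

    Subjects are sorted by predicted probability and split into g near-equal
    groups (ties kept in one group); the statistic sums
    (O_g - n_g p_g)^2 / (n_g p_g) + ((n_g - O_g) - n_g (1 - p_g))^2 / (n_g (1 - p_g))
    with p_g the group mean prediction, and is referred to chi-square with
    g - 2 degrees of freedom.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(p_pred, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError("y_true and p_pred lengths differ")
    if groups < 3:
        raise ValueError("need at least 3 groups (df = g - 2 >= 1)")
    if y.size < groups:
        raise ValueError("fewer subjects than groups")
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    # near-equal group boundaries, moved forward so tied p stay together
    bounds = [round(i * y.size / groups) for i in range(1, groups)]
    cuts = []
    for b in bounds:
        while 0 < b < y.size and ps[b] == ps[b - 1]:
            b += 1
        if b < y.size and (not cuts or b > cuts[-1]):
            cuts.append(b)
    rows, stat = [], 0.0
    for lo, hi in zip([0, *cuts], [*cuts, y.size]):
        n_g = hi - lo
        p_bar = float(ps[lo:hi].mean())
        obs = float(ys[lo:hi].sum())
        exp = n_g * p_bar
        if p_bar <= 0.0 or p_bar >= 1.0:
            warnings.warn(
                f"degenerate HL group with mean prediction {p_bar}; eps-guarded",
                stacklevel=2,
            )
            p_bar = min(max(p_bar, eps), 1.0 - eps)
        stat += (obs - exp) ** 2 / (n_g * p_bar) + (
            (n_g - obs) - n_g * (1.0 - p_bar)
        ) ** 2 / (n_g * (1.0 - p_bar))
        rows.append({"n": n_g, "observed": obs, "expected": exp, "mean_pred": p_bar})
    g_eff = len(rows)
    df = g_eff - 2
    p_value = float(chi2.sf(stat, df)) if df >= 1 else np.nan
    return HLResult(
        statistic=float(stat), groups=g_eff, df=df, p_value=p_value,
        table=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# learner comparison

def compare_learners(
    cohort: Cohort,
    seed: int = 0,
    train_fraction: float = 0.7,
    train_config: TrainConfig | None = None,
    hidden_widths: Sequence[int] = (),
    hl_groups: Sequence[int] = (10, 20),
    metric: str = "mean",
) -> pd.DataFrame:
    """Calibration-loss MIL vs MSE MIL vs CEL MIL vs instance-level SVM.

    All three MIL learners are trained on identical splits toward the bags'
    responder fractions (the scalar ORR label) with the same architecture;
    the SVM baseline is fit on per-patient binary responses with Platt
    probability outputs.  Each learner's per-patient predicted probability
    is scored against the binary response by the Hosmer-Lemeshow test on
    train / test / all slices at each group setting.

    The default architecture here is the degenerate hidden-free network
    (logistic regression): bag-level supervision leaves within-bag instance
    outputs unconstrained, so a high-capacity network can drive them to 0/1
    while still matching every bag mean, which makes patient-level
    calibration of *any* loss meaningless.  The linear instance model keeps
    the comparison about the loss functions themselves.
    """
    train_config = train_config or TrainConfig()
    tr, te = split_train_test(cohort, train_fraction, seed=seed)
    scaler = FeatureScaler().fit(tr.feature_matrix())

    def orr_bags(c: Cohort) -> list[SubgroupBag]:
        by_id = c.by_id()
        out = []
        for b in c.bags:
            frac = float(np.mean([by_id[pid].response for pid in b.member_ids]))
            out.append(SubgroupBag(b.bag_id, list(b.member_ids), frac))
        return out

    slices = {
        "train": tr,
        "test": te,
        "all": cohort,
    }
    responses = {
        name: np.array([p.response for p in c.patients]) for name, c in slices.items()
    }
    Z = {name: scaler.transform(c.feature_matrix()) for name, c in slices.items()}

    predictions: dict[str, dict[str, np.ndarray]] = {}
    specs = {
        "calibration": LossSpec(mode="category_calibration", metric=metric),
        "mse": LossSpec(mode="mse", metric=metric),
        "cel": LossSpec(mode="cel", metric=metric),
    }
    for name, spec in specs.items():
        net = init_network(cohort.d, hidden_widths, 1, seed=train_config.seed)
        net, _ = train(net, orr_bags(tr), _scaled_view(tr, scaler), spec, train_config)
        predictions[name] = {
            s: net.forward(Z[s]).ravel() for s in slices
        }

    from sklearn.svm import SVC

    svm = SVC(kernel="rbf", probability=True, random_state=train_config.seed)
    svm.fit(Z["train"], (responses["train"] >= 0.5).astype(int))
    predictions["svm"] = {
        s: svm.predict_proba(Z[s])[:, 1] for s in slices
    }

    rows = []
    for learner in ("calibration", "mse", "cel", "svm"):
        for s in slices:
            for g in hl_groups:
                hl = hosmer_lemeshow(
                    (responses[s] >= 0.5).astype(float), predictions[learner][s],
                    groups=g,
                )
                rows.append(
                    {
                        "learner": learner,
                        "slice": s,
                        "groups": g,
                        "df": hl.df,
                        "hl_statistic": hl.statistic,
                        "p_value": hl.p_value,
                    }
                )
    return pd.DataFrame(rows)
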