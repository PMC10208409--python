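"""Patients, subgroup bags and prognosis labels.

A cohort is a set of patients, each carrying a d-dimensional mutation-burden
feature vector and clinical endpoints (tumor response, time-to-event,
censoring flag).  Patients are partitioned into subgroup *bags*; the bag is
the unit of supervision.  Two labeling schemes are supported:

* expert **category** labels in {0, 1} (or {-1, 0, 1}) driven by response
  proportion and median progression-free survival;
* objective **probabilistic** labels [pR, pT]: the subgroup response
  probability and the probability of surviving beyond a horizon t0, the
  latter estimated per patient from a Cox proportional-hazards fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "SubgroupBag",
    "LabelConfig",
    "Cohort",
    "FeatureScaler",
    "aggregate_metric",
    "assign_category_label",
    "estimate_pT",
    "probabilistic_label",
    "scale_features",
]

Metric = Literal["median", "maximum", "minimum", "mean"]

_METRIC_FUNCS = {
    "median": np.median,
    "maximum": np.max,
    "minimum": np.min,
    "mean": np.mean,
}


@dataclass
class PatientRecord:
    """One patient: burden features plus clinical endpoints.

    ``response`` is the binary tumor-response indicator (CR/PR -> 1,
    SD/PD -> 0) or, in simulation, the retained response probability in
    [0, 1].  ``p_survival`` (pT) is the probability of surviving beyond the
    configured horizon, filled by :func:`estimate_pT` or by the simulator.
    """

    patient_id: str
    features: np.ndarray
    response: float
    time: float
    event: int
    p_survival: float | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        if not 0.0 <= self.response <= 1.0:
            raise ValueError(f"response {self.response} outside [0, 1]")


@dataclass
class SubgroupBag:
    """A patient subgroup G_m with its prognosis label y_m."""

    bag_id: str
    member_ids: list[str]
    label: float | np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.member_ids)


@dataclass
class LabelConfig:
    """Parameters of the subgroup labeling rules.

    t0 is the survival horizon in days; the default, 183 days (six months),
    is the conventional cut beyond which progression-free survival is
    considered favorable.
    """

    mode: Literal["category", "probabilistic"] = "probabilistic"
    metric: Metric = "median"
    t0: float = 183.0
    pfs_favorable_days: float = 183.0
    response_threshold: float = 0.5
    three_class: bool = False
    low_response_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.metric not in _METRIC_FUNCS:
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class Cohort:
    """A list of patients together with their bag partition."""

    patients: list[PatientRecord]
    bags: list[SubgroupBag]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids")
        member_ids = [pid for b in self.bags for pid in b.member_ids]
        if len(set(member_ids)) != len(member_ids):
            raise ValueError("a patient appears in more than one bag")
        unknown = set(member_ids) - set(ids)
        if unknown:
            raise ValueError(f"bag members not in cohort: {sorted(unknown)[:5]}")

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def d(self) -> int:
        return len(self.patients[0].features)

    def by_id(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def feature_matrix(self) -> np.ndarray:
        return np.vstack([p.features for p in self.patients])

    def subset(self, patient_ids: Sequence[str]) -> "Cohort":
        """Restrict to the given patients; bags keep labels, drop empty bags."""
        keep = set(patient_ids)
        patients = [p for p in self.patients if p.patient_id in keep]
        bags = []
        for b in self.bags:
            members = [pid for pid in b.member_ids if pid in keep]
            if members:
                bags.append(SubgroupBag(b.bag_id, members, b.label))
        return Cohort(patients, bags)


def aggregate_metric(values, metric: Metric):
    """Aggregate scalars or k-vectors by median / maximum / minimum / mean.

    Vector inputs are aggregated componentwise.  An even-count median is the
    midpoint of the central pair.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty list")
    if arr.ndim not in (1, 2):
        raise ValueError("values must be scalars or equal-length vectors")
    out = _METRIC_FUNCS[metric](arr, axis=0)
    return float(out) if np.ndim(out) == 0 else out


def assign_category_label(
    bag: SubgroupBag, patients: dict[str, PatientRecord], config: LabelConfig
) -> int:
    """Expert-style category label for a bag.

    Two-class rule: label 1 iff the bag response proportion reaches
    ``response_threshold`` *and* the bag median PFS exceeds
    ``pfs_favorable_days``; else 0.  The three-class variant adds an
    intermediate band (label 0) between clearly favorable (1) and clearly
    unfavorable (-1) bags.  All thresholds live in the config so the rule is
    explicit and auditable.
    """
    members = [patients[pid] for pid in bag.member_ids]
    responses = [m.response for m in members]
    times = [m.time for m in members]
    prop = float(np.mean(responses))
    med_pfs = float(np.median(times))
    favorable = prop >= config.response_threshold and med_pfs > config.pfs_favorable_days
    if not config.three_class:
        return 1 if favorable else 0
    if favorable:
        return 1
    if prop < config.low_response_threshold and med_pfs <= config.pfs_favorable_days:
        return -1
    return 0


def estimate_pT(
    patients: Sequence[PatientRecord], t0: float = 183.0, penalizer: float = 0.0
) -> np.ndarray:
    """Per-patient probability of surviving beyond t0 from a Cox-PH fit.

    Fits time ~ features by Cox partial likelihood (lifelines), estimates the
    baseline survival curve and returns S_i(t0) for every patient, also
    writing it into each record's ``p_survival``.  A singular/collinear
    design triggers a ridge-penalized refit with a warning.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    events = np.array([p.event for p in patients])
    if events.sum() == 0:
        raise ValueError("all patients censored: no events to fit a Cox model")
    X = np.vstack([p.features for p in patients])
    varying = X.std(axis=0) > 0
    if not varying.all():
        warnings.warn(
            f"zero-variance feature dimension(s) "
            f"{np.flatnonzero(~varying).tolist()} dropped from the Cox design",
            stacklevel=2,
        )
    X = X[:, varying]
    times_arr = np.array([p.time for p in patients], dtype=float)

    def _step_eval(surv: pd.DataFrame) -> np.ndarray:
        # step-function evaluation at t0: last estimated value at time <= t0
        times = surv.index.values
        mask = times <= t0
        if not mask.any():
            return np.ones(surv.shape[1])
        return surv.iloc[mask.argmin() - 1 if not mask.all() else -1].values

    if X.shape[1] == 0:
        # no informative covariates: the survival curve is the pooled
        # Kaplan-Meier estimate, identical for every patient
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(times_arr, events)
        p_t0 = np.full(len(patients), _step_eval(km.survival_function_)[0])
    else:
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
        df["time"] = times_arr
        df["event"] = events

        def _fit(pen: float) -> CoxPHFitter:
            cph = CoxPHFitter(penalizer=pen)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            return cph

        try:
            cph = _fit(penalizer)
        except (ConvergenceError, np.linalg.LinAlgError):
            warnings.warn(
                "Cox fit failed (collinear or separable design); refitting "
                "with ridge penalizer",
                stacklevel=2,
            )
            try:
                cph = _fit(max(penalizer, 0.1))
            except (ConvergenceError, np.linalg.LinAlgError):
                cph = _fit(max(penalizer, 10.0))

        # product-limit form of the Breslow baseline: per distinct event
        # time s, hazard increment h_s = d_s / sum_{j in R(s)} exp(eta_j),
        # and S_i(t0) = prod_{s <= t0} (1 - h_s)^{exp(eta_i)}.  Unlike the
        # exponentiated cumulative-hazard form this reaches 0 when the risk
        # set is exhausted, and it agrees with Kaplan-Meier when all eta = 0.
        eta = X @ cph.params_.values
        eta = eta - eta.mean()  # anchor the baseline at the mean predictor
        w = np.exp(eta)
        log_s0 = 0.0
        for s in np.unique(times_arr[(events == 1) & (times_arr <= t0)]):
            d_s = float(((times_arr == s) & (events == 1)).sum())
            at_risk = w[times_arr >= s].sum()
            h_s = min(d_s / at_risk, 1.0)
            log_s0 += np.log1p(-h_s) if h_s < 1.0 else -np.inf
        with np.errstate(over="ignore"):
            p_t0 = np.exp(w * log_s0)
    p_t0 = np.clip(np.asarray(p_t0, dtype=float), 0.0, 1.0)
    for patient, p in zip(patients, p_t0):
        patient.p_survival = float(p)
    return p_t0


def probabilistic_label(
    bag: SubgroupBag, patients: dict[str, PatientRecord], config: LabelConfig
) -> np.ndarray:
    """Objective [pR, pT] label: aggregated response and survival probabilities.

    With metric="mean" the pR component is exactly the bag's responder
    fraction (the ORR).  Requires ``p_survival`` filled by :func:`estimate_pT`
    (or the simulator).
    """
    if config.mode != "probabilistic":
        raise ValueError("probabilistic_label requires config.mode='probabilistic'")
    members = [patients[pid] for pid in bag.member_ids]
    missing = [m.patient_id for m in members if m.p_survival is None]
    if missing:
        raise ValueError(f"p_survival missing for {missing[:5]}; run estimate_pT first")
    p_r = aggregate_metric([m.response for m in members], config.metric)
    p_t = aggregate_metric([m.p_survival for m in members], config.metric)
    return np.array([p_r, p_t], dtype=float)


class FeatureScaler:
    """Per-dimension standardization (z-scoring) fitted on training data only.

    Zero-variance dimensions are centered but not scaled (scale 1), with a
    warning.  Serializable to a plain dict for checkpointing.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        zero = std == 0.0
        if zero.any():
            warnings.warn(
                f"zero-variance feature dimension(s) {np.flatnonzero(zero).tolist()}: "
                "centered only",
                stacklevel=2,
            )
        self.scale_ = np.where(zero, 1.0, std)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_

    def to_dict(self) -> dict:
        self._check_fitted()
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        s = cls()
        s.mean_ = np.asarray(d["mean"], dtype=float)
        s.scale_ = np.asarray(d["scale"], dtype=float)
        return s

    def _check_fitted(self) -> None:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")


def scale_features(cohort: Cohort) -> tuple[Cohort, FeatureScaler]:
    """Standardize features across the cohort; returns new cohort + scaler."""
    scaler = FeatureScaler().fit(cohort.feature_matrix())
    Z = scaler.transform(cohort.feature_matrix())
    patients = [
        replace(p, features=Z[i]) for i, p in enumerate(cohort.patients)
    ]
    return Cohort(patients, [SubgroupBag(b.bag_id, list(b.member_ids), b.label) for b in cohort.bags]), scaler
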