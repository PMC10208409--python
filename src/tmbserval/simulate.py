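"""Synthetic immunotherapy cohort generator.

Emulates, at the burden-vector level, a cohort of patients whose
multidimensional tumor mutation burden drives two endpoints: a dichotomous
logistic tumor response and a Cox proportional-hazards progression-free
survival time with exponential baseline and independent exponential
censoring.  The default preset produces 660 patients in five prognosis
subgroups of sizes 90 / 212 / 64 / 202 / 92 with subgroup [pR, pT] labels

    (0.223, 0.246), (0.326, 0.397), (0.461, 0.558),
    (0.654, 0.733), (0.908, 0.922),

pR being the subgroup response probability and pT the probability of
surviving beyond t0 = 183 days.  Burden counts are drawn from overdispersed
negative-binomial distributions with subgroup-specific means and a
multiplicative log-normal noise term standing in for assay measurement
error; the logistic and hazard intercepts of each subgroup are calibrated
by monotone root-finding so the subgroup-mean latent probabilities hit the
target labels exactly.  The latent response probability of every patient is
retained in the ground-truth table (the response endpoint is characterized
by the probability of remission itself, not only the binary draw).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Cohort, PatientRecord, SubgroupBag

__all__ = [
    "SimConfig",
    "CalibrationError",
    "default_config",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

DEFAULT660_SIZES = (90, 212, 64, 202, 92)
DEFAULT660_LABELS = (
    (0.223, 0.246),
    (0.326, 0.397),
    (0.461, 0.558),
    (0.654, 0.733),
    (0.908, 0.922),
)


class CalibrationError(RuntimeError):
    """A subgroup's target probability is unreachable by intercept tuning."""


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort.

    feature_means[m] is the mean count vector (snv, ins, del) of subgroup m:
    better-prognosis subgroups carry higher burdens, matching the positive
    burden-benefit association the model is meant to learn.  dispersion is
    the negative-binomial size parameter (smaller = more overdispersed);
    count_noise_sd is the log-normal sigma of the multiplicative
    measurement-error term.  logistic_slopes / hazard_slopes act on
    cohort-standardized features; intercepts are calibrated per subgroup.
    """

    subgroup_sizes: tuple[int, ...] = DEFAULT660_SIZES
    target_labels: tuple[tuple[float, float], ...] = DEFAULT660_LABELS
    classes: tuple[str, ...] = ("snv", "ins", "del")
    feature_means: tuple[tuple[float, ...], ...] = (
        (8.0, 2.0, 1.5),
        (14.0, 3.5, 2.5),
        (20.0, 5.0, 4.0),
        (27.0, 7.0, 5.5),
        (36.0, 9.5, 7.5),
    )
    dispersion: float = 8.0
    count_noise_sd: float = 0.1
    logistic_slopes: tuple[float, ...] = (0.9, 0.5, 0.4)
    hazard_slopes: tuple[float, ...] = (-0.8, -0.45, -0.35)
    baseline_rate: float = 0.00385  # per day; ~ln(2)/180, median PFS ~6 months
    censor_rate: float = 0.2
    t0: float = 183.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subgroup_sizes) != len(self.target_labels):
            raise ValueError("subgroup_sizes and target_labels lengths differ")
        if len(self.feature_means) != len(self.subgroup_sizes):
            raise ValueError("feature_means must have one row per subgroup")
        if any(s <= 0 for s in self.subgroup_sizes):
            raise ValueError("subgroup sizes must be positive")
        for pr, pt in self.target_labels:
            if not (0.0 < pr < 1.0 and 0.0 < pt < 1.0):
                raise ValueError("target probabilities must lie in (0, 1)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")

    @property
    def d(self) -> int:
        return len(self.classes)

    @property
    def n_total(self) -> int:
        return int(sum(self.subgroup_sizes))

    def scaled(self, factor: float) -> "SimConfig":
        """Multiply subgroup sizes (rounded) for convergence studies."""
        sizes = tuple(max(1, round(s * factor)) for s in self.subgroup_sizes)
        return dataclasses.replace(self, subgroup_sizes=sizes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("subgroup_sizes", "classes", "logistic_slopes", "hazard_slopes"):
            d[key] = tuple(d[key])
        d["target_labels"] = tuple(tuple(t) for t in d["target_labels"])
        d["feature_means"] = tuple(tuple(t) for t in d["feature_means"])
        return cls(**d)


def default_config() -> SimConfig:
    """The 660-patient five-subgroup preset (3 burden dimensions, t0=183 d)."""
    return SimConfig()


# ---------------------------------------------------------------------------

def _calibrate_intercept(fn, target: float, label: str, lo=-30.0, hi=30.0) -> float:
    """Solve fn(b) = target for the intercept b; fn must be monotone in b."""
    flo, fhi = fn(lo) - target, fn(hi) - target
    if flo * fhi > 0:
        raise CalibrationError(
            f"target {target} unreachable for {label}: intercept range "
            f"[{lo}, {hi}] brackets [{fn(lo):.4f}, {fn(hi):.4f}]"
        )
    return brentq(lambda b: fn(b) - target, lo, hi, xtol=1e-12)


def simulate_cohort(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its ground-truth table.

    Returns the cohort (patients with raw count features, binary response,
    censored time and event flag; bags labeled with the configured target
    pairs) and a per-patient truth table with the latent response
    probability, latent survival probability at t0, latent event time and
    subgroup intercepts realized by the calibration.
    """
    config = config or default_config()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    sizes = config.subgroup_sizes
    n_total = config.n_total

    # --- burden features: negative-binomial counts + multiplicative noise
    features = np.empty((n_total, config.d))
    group_of = np.empty(n_total, dtype=int)
    row = 0
    for m, n_m in enumerate(sizes):
        mu = np.asarray(config.feature_means[m], dtype=float)
        r = config.dispersion
        # numpy negative_binomial parameterized by (n=r, p=r/(r+mu))
        counts = rng.negative_binomial(r, r / (r + mu), size=(n_m, config.d))
        if config.count_noise_sd > 0:
            noise = rng.lognormal(0.0, config.count_noise_sd, size=(n_m, config.d))
            counts = np.rint(counts * noise)
        features[row : row + n_m] = np.maximum(counts, 0)
        group_of[row : row + n_m] = m
        row += n_m

    # linear predictors act on cohort-standardized features
    z = (features - features.mean(axis=0)) / np.maximum(features.std(axis=0), 1e-12)
    eta_r = z @ np.asarray(config.logistic_slopes)
    eta_h = z @ np.asarray(config.hazard_slopes)

    # --- response: per-subgroup logistic intercept calibrated to target pR
    p_response = np.empty(n_total)
    intercepts_r = np.empty(len(sizes))
    for m in range(len(sizes)):
        sel = group_of == m
        target = config.target_labels[m][0]
        b0 = _calibrate_intercept(
            lambda b, sel=sel: float(np.mean(expit(b + eta_r[sel]))),
            target, f"subgroup {m} response",
        )
        intercepts_r[m] = b0
        p_response[sel] = expit(b0 + eta_r[sel])
    response = rng.binomial(1, p_response).astype(float)

    # --- survival: exponential-baseline PH, intercept calibrated to target pT
    lam0, t0 = config.baseline_rate, config.t0
    p_survive = np.empty(n_total)
    hazards = np.empty(n_total)
    intercepts_h = np.empty(len(sizes))
    for m in range(len(sizes)):
        sel = group_of == m
        target = config.target_labels[m][1]

        def mean_surv(c0, sel=sel):
            return float(np.mean(np.exp(-lam0 * np.exp(c0 + eta_h[sel]) * t0)))

        c0 = _calibrate_intercept(mean_surv, target, f"subgroup {m} survival")
        intercepts_h[m] = c0
        hazards[sel] = lam0 * np.exp(c0 + eta_h[sel])
        p_survive[sel] = np.exp(-hazards[sel] * t0)
    latent_time = rng.exponential(1.0 / hazards)

    # --- independent exponential censoring calibrated to the overall rate
    if config.censor_rate > 0:
        mu = _calibrate_intercept(
            lambda log_mu: float(np.mean(np.exp(log_mu) / (hazards + np.exp(log_mu)))),
            config.censor_rate, "censoring rate",
        )
        censor_time = rng.exponential(np.exp(-mu), size=n_total)
        event = (latent_time <= censor_time).astype(int)
        time = np.minimum(latent_time, censor_time)
    else:
        event = np.ones(n_total, dtype=int)
        time = latent_time.copy()
    time = np.maximum(time, 1e-3)  # strictly positive days

    # --- assemble
    patients, bags = [], []
    truth_rows = []
    idx = 0
    for m, n_m in enumerate(sizes):
        member_ids = []
        for _ in range(n_m):
            pid = f"P{idx:04d}"
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    features=features[idx],
                    response=float(response[idx]),
                    time=float(time[idx]),
                    event=int(event[idx]),
                    p_survival=float(p_survive[idx]),
                )
            )
            truth_rows.append(
                {
                    "patient_id": pid,
                    "bag_id": f"G{m}",
                    "p_response": p_response[idx],
                    "p_survive_t0": p_survive[idx],
                    "latent_time": latent_time[idx],
                    "linear_predictor_hazard": np.log(hazards[idx] / lam0),
                }
            )
            member_ids.append(pid)
            idx += 1
        bags.append(
            SubgroupBag(
                bag_id=f"G{m}",
                member_ids=member_ids,
                label=np.asarray(config.target_labels[m], dtype=float),
            )
        )
    truth = pd.DataFrame(truth_rows)
    return Cohort(patients, bags), truth


# ---------------------------------------------------------------------------
# on-disk round trip

def write_cohort(
    cohort: Cohort, truth: pd.DataFrame | None, config: SimConfig | None,
    out_dir: str | Path,
) -> None:
    """Emit features/clinical/bags(/truth) TSVs plus the config as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classes = config.classes if config is not None else tuple(
        f"x{j}" for j in range(cohort.d)
    )
    feat = pd.DataFrame(cohort.feature_matrix(), columns=list(classes))
    feat.insert(0, "patient_id", [p.patient_id for p in cohort.patients])
    feat.to_csv(out / "features.tsv", sep="\t", index=False)

    clin = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort.patients],
            "response": [p.response for p in cohort.patients],
            "time_days": [p.time for p in cohort.patients],
            "event": [p.event for p in cohort.patients],
        }
    )
    clin.to_csv(out / "clinical.tsv", sep="\t", index=False)

    rows = []
    for b in cohort.bags:
        label = np.atleast_1d(b.label) if b.label is not None else []
        for pid in b.member_ids:
            rows.append(
                {
                    "patient_id": pid,
                    "bag_id": b.bag_id,
                    **{f"label_{i}": v for i, v in enumerate(label)},
                }
            )
    pd.DataFrame(rows).to_csv(out / "bags.tsv", sep="\t", index=False)

    if truth is not None:
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    if config is not None:
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))


def read_cohort(in_dir: str | Path) -> Cohort:
    """Rebuild a cohort from the TSVs written by :func:`write_cohort`."""
    src = Path(in_dir)
    feat = pd.read_csv(src / "features.tsv", sep="\t")
    clin = pd.read_csv(src / "clinical.tsv", sep="\t").set_index("patient_id")
    bags_df = pd.read_csv(src / "bags.tsv", sep="\t")
    truth_path = src / "truth.tsv"
    p_surv = None
    if truth_path.exists():
        p_surv = pd.read_csv(truth_path, sep="\t").set_index("patient_id")[
            "p_survive_t0"
        ]
    patients = []
    for _, row in feat.iterrows():
        pid = row["patient_id"]
        c = clin.loc[pid]
        patients.append(
            PatientRecord(
                patient_id=pid,
                features=row.drop("patient_id").to_numpy(dtype=float),
                response=float(c["response"]),
                time=float(c["time_days"]),
                event=int(c["event"]),
                p_survival=float(p_surv.loc[pid]) if p_surv is not None else None,
            )
        )
    label_cols = sorted(c for c in bags_df.columns if c.startswith("label_"))
    bags = []
    for bag_id, grp in bags_df.groupby("bag_id", sort=True):
        label = None
        if label_cols:
            vals = grp.iloc[0][label_cols].to_numpy(dtype=float)
            label = float(vals[0]) if len(vals) == 1 else vals
        bags.append(SubgroupBag(bag_id, grp["patient_id"].tolist(), label))
    return Cohort(patients, bags)
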