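"""Synthetic two-group cohorts with the statistical structure the analysis
pipeline assumes.

Each subject gets (i) ground-truth PVL parameters drawn from group-specific
truncated normals, (ii) covariates (KEAT-26, SDS, STAI state/trait, age,
BMI) drawn from group-specific truncated normals, with KEAT-26 constrained
to the correct side of the high-risk threshold, and (iii) a full simulated
IGT session (20 practice + 100 experimental trials) generated by the PVL
agent on the default payoff schedule. Ground-truth parameters are stored so
estimators can be validated by parameter recovery.

Truncation shifts moments, so the generator numerically moment-matches the
underlying untruncated (mu, sigma) to the configured mean/SD. Where a target
is unattainable for a truncated normal — a normal truncated at 0 has
coefficient of variation < 1, which the loss-aversion moments exceed — the
closest achievable moments are used (mean matched, SD slightly under
target); ``moment_match`` reports what was achieved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import truncnorm

from .igt_task import (
    DECKS,
    KEAT26_THRESHOLD,
    LossMode,
    PayoffSchedule,
    build_default_schedule,
    label_risk_group,
    score_trials,
)
from .pvl_model import (
    DEFAULT_PAYOFF_SCALE,
    PARAM_BOUNDS,
    PARAM_NAMES,
    ChoiceSequence,
    ThetaRule,
)

HIGH_RISK = "high_risk"
CONTROL = "control"

#: group-level PVL parameter means (SDs) the generator reproduces
DEFAULT_PARAM_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    HIGH_RISK: {"a": (0.249, 0.084), "lam": (0.355, 0.390), "A": (0.377, 0.115), "c": (0.393, 0.418)},
    CONTROL: {"a": (0.268, 0.092), "lam": (0.523, 0.639), "A": (0.464, 0.188), "c": (0.634, 0.478)},
}

#: group-level covariate means (SDs)
DEFAULT_COVARIATE_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    HIGH_RISK: {
        "keat26": (31.60, 8.18),
        "sds": (47.74, 8.74),
        "stai_state": (56.02, 11.23),
        "stai_trait": (51.81, 11.86),
        "age": (21.43, 2.28),
        "bmi": (19.90, 1.97),
    },
    CONTROL: {
        "keat26": (3.12, 2.56),
        "sds": (40.14, 6.00),
        "stai_state": (49.98, 14.12),
        "stai_trait": (38.35, 9.93),
        "age": (20.70, 1.90),
        "bmi": (20.27, 1.87),
    },
}

#: instrument / plausibility ranges used for covariate truncation
COVARIATE_BOUNDS: dict[str, tuple[float, float]] = {
    "keat26": (0.0, 78.0),
    "sds": (20.0, 80.0),
    "stai_state": (20.0, 80.0),
    "stai_trait": (20.0, 80.0),
    "age": (17.0, 45.0),
    "bmi": (13.0, 40.0),
}

COVARIATES = tuple(COVARIATE_BOUNDS)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; the defaults are the study conditions."""

    n_high_risk: int = 42
    n_control: int = 43
    param_moments: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_PARAM_MOMENTS.items()})
    covariate_moments: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COVARIATE_MOMENTS.items()})
    n_experimental: int = 100
    n_practice: int = 20
    payoff_scale: float = DEFAULT_PAYOFF_SCALE
    theta_rule: ThetaRule = ThetaRule.AS_PRINTED
    loss_mode: LossMode = LossMode.DETERMINISTIC_CYCLE
    keat26_threshold: float = KEAT26_THRESHOLD
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high_risk < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")
        for g in (HIGH_RISK, CONTROL):
            for name, (m, s) in self.param_moments[g].items():
                if s < 0:
                    raise ValueError(f"SD for {g}/{name} must be >= 0")


@dataclass(frozen=True)
class MomentMatch:
    """Underlying normal (mu, sigma) whose truncation to [lo, hi] comes
    closest to the target mean/SD, plus the moments actually achieved."""

    mu: float
    sigma: float
    lo: float
    hi: float
    achieved_mean: float
    achieved_sd: float


@lru_cache(maxsize=512)
def moment_match(mean: float, sd: float, lo: float, hi: float) -> MomentMatch:
    """Least-squares moment matching of a truncated normal to (mean, sd)."""
    if not lo <= mean <= hi:
        raise ValueError(f"target mean {mean} outside truncation range [{lo}, {hi}]")
    if sd == 0:
        return MomentMatch(mean, 0.0, lo, hi, mean, 0.0)

    def achieved(mu: float, sig: float) -> tuple[float, float]:
        a, b = (lo - mu) / sig, (hi - mu) / sig
        with np.errstate(all="ignore"):
            m, v = truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return float(m), float(np.sqrt(max(float(v), 0.0)))

    # mean mismatch weighted above SD mismatch: for targets whose SD/mean
    # ratio no truncated normal can reach, the mean is matched and the SD
    # settles at the largest value the family admits
    def loss(theta: np.ndarray) -> float:
        m, s = achieved(theta[0], np.exp(theta[1]))
        return 10.0 * ((m - mean) / sd) ** 2 + ((s - sd) / sd) ** 2

    bounds = [(lo - 30 * sd, hi + 30 * sd), (np.log(sd / 50), np.log(50 * sd))]
    best = None
    for mu0, lsig0 in ((mean, np.log(sd)), (lo - 2 * sd, np.log(3 * sd))):
        res = minimize(loss, np.array([mu0, lsig0]), method="Nelder-Mead", bounds=bounds,
                       options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    mu, sig = best.x[0], float(np.exp(best.x[1]))
    m, s = achieved(mu, sig)
    return MomentMatch(mu, sig, lo, hi, m, s)


def _draw_truncated(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    mm = moment_match(mean, sd, lo, hi)
    if mm.sigma == 0:
        return np.full(size, mm.mu)
    a, b = (lo - mm.mu) / mm.sigma, (hi - mm.mu) / mm.sigma
    return truncnorm.rvs(a, b, loc=mm.mu, scale=mm.sigma, size=size, random_state=rng)


@dataclass
class CohortDataset:
    """Subjects table + trial-level table for one synthetic cohort."""

    subjects: pd.DataFrame
    trials: pd.DataFrame
    config: CohortConfig

    def sequences(self, group: str | None = None) -> list[ChoiceSequence]:
        """Experimental-trial choice sequences, in subjects-table order."""
        subs = self.subjects if group is None else self.subjects[self.subjects["group"] == group]
        exp = self.trials[~self.trials["is_practice"].astype(bool)]
        by_subject = dict(tuple(exp.groupby("subject_id", sort=False)))
        return [
            ChoiceSequence.from_frame(
                by_subject[sid], payoff_scale=self.config.payoff_scale, drop_practice=False
            )
            for sid in subs["subject_id"]
        ]

    def scores(self) -> pd.DataFrame:
        return score_trials(self.trials)

    def write_dir(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.trials.to_csv(out / "trials.csv", index=False)


def simulate_agents_batch(
    a: np.ndarray,
    lam: np.ndarray,
    A: np.ndarray,
    c: np.ndarray,
    n_trials: int,
    rng: np.random.Generator,
    schedule: PayoffSchedule | None = None,
    payoff_scale: float = DEFAULT_PAYOFF_SCALE,
    theta_rule: ThetaRule | str = ThetaRule.AS_PRINTED,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-simulate many PVL agents at once (vectorised over subjects).

    Returns (decks, gains, losses), each (n_subjects, n_trials). Semantics
    are identical to ``pvl_model.simulate_agent`` run per subject; the batch
    form exists so cohort generation and Monte-Carlo calibration stay cheap.
    """
    schedule = schedule or build_default_schedule()
    rule = ThetaRule(theta_rule)
    S = len(a)
    gain_vec = np.array([schedule.deck(d).gain_per_selection for d in DECKS])
    lossmag = np.array([schedule.deck(d).mean_loss_per_event for d in DECKS])
    k_vec = np.array([schedule.deck(d).loss_events_per_cycle for d in DECKS])
    hit_table = np.zeros((4, 10), dtype=bool)
    for j, d in enumerate(DECKS):
        for pos in schedule.loss_positions(d):
            hit_table[j, pos - 1] = True

    E = np.zeros((S, 4))
    counts = np.zeros((S, 4), dtype=np.int64)
    decks = np.empty((S, n_trials), dtype=np.int64)
    gains = np.empty((S, n_trials))
    losses = np.empty((S, n_trials))
    theta_const = 3.0**c - 1.0
    idx = np.arange(S)
    for t in range(n_trials):
        theta = theta_const if rule is ThetaRule.AS_PRINTED else ((t + 1) / 10.0) ** c
        z = theta[:, None] * E
        z = z - z.max(axis=1, keepdims=True)
        w = np.exp(z)
        p = w / w.sum(axis=1, keepdims=True)
        u01 = rng.random((S, 1))
        j = (u01 > np.cumsum(p, axis=1)).sum(axis=1)
        j = np.minimum(j, 3)
        counts[idx, j] += 1
        if schedule.loss_mode is LossMode.DETERMINISTIC_CYCLE:
            pos = (counts[idx, j] - 1) % 10
            hit = hit_table[j, pos]
        else:
            hit = rng.random(S) < k_vec[j] / 10.0
        g = gain_vec[j]
        l = -lossmag[j] * hit
        decks[:, t], gains[:, t], losses[:, t] = j, g, l
        x = (g + l) * payoff_scale
        xa = np.abs(x) ** a
        u = np.where(x > 0, xa, np.where(x < 0, -lam * xa, 0.0))
        E *= A[:, None]
        E[idx, j] += u
    return decks, gains, losses


def _trials_frame(
    subject_ids: np.ndarray,
    groups: np.ndarray,
    decks: np.ndarray,
    gains: np.ndarray,
    losses: np.ndarray,
    is_practice: np.ndarray,
) -> pd.DataFrame:
    S, T = decks.shape
    return pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, T),
            "group": np.repeat(groups, T),
            "trial": np.tile(np.arange(1, T + 1), S),
            "deck": np.array(DECKS)[decks.ravel()],
            "gain": gains.ravel(),
            "loss": losses.ravel(),
            "net": (gains + losses).ravel(),
            "is_practice": np.repeat(is_practice[None, :], S, axis=0).ravel(),
        }
    )


def _generate(
    config: CohortConfig,
    seed: int | None,
    group_specs: list[tuple[str, str, int, dict, dict]],
    simulate_choices: bool,
) -> CohortDataset:
    master = config.master_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(master))
    schedule = build_default_schedule(config.loss_mode)

    sub_rows = []
    all_params = []
    ids_all, groups_all = [], []
    for label, prefix, n, pmoms, cmoms in group_specs:
        params = {
            name: np.clip(
                _draw_truncated(*pmoms[name], *PARAM_BOUNDS[name], n, rng),
                *PARAM_BOUNDS[name],
            )
            for name in PARAM_NAMES
        }
        covs = {}
        for cov in COVARIATES:
            lo, hi = COVARIATE_BOUNDS[cov]
            if cov == "keat26":
                # constrain to the correct side of the high-risk threshold
                thr = config.keat26_threshold
                lo, hi = (thr, hi) if label == HIGH_RISK else (lo, min(hi, thr))
                mean, sd = cmoms[cov]
                if sd == 0 and not lo <= mean <= hi:
                    raise ValueError(
                        f"KEAT-26 constraint unsatisfiable for group {label!r}: "
                        f"degenerate mean {mean} outside ({lo}, {hi})"
                    )
            covs[cov] = _draw_truncated(*cmoms[cov], lo, hi, n, rng)
        ids = np.array([f"{prefix}{i + 1:03d}" for i in range(n)])
        ids_all.append(ids)
        groups_all.append(np.full(n, label, dtype=object))
        all_params.append(params)
        sub = pd.DataFrame({"subject_id": ids, "group": label})
        for cov in COVARIATES:
            sub[cov] = covs[cov]
        for name in PARAM_NAMES:
            sub[f"true_{'lambda' if name == 'lam' else name}"] = params[name]
        sub_rows.append(sub)

    subjects = pd.concat(sub_rows, ignore_index=True)
    ids_cat = np.concatenate(ids_all)
    groups_cat = np.concatenate(groups_all)
    a = np.concatenate([p["a"] for p in all_params])
    lam = np.concatenate([p["lam"] for p in all_params])
    A = np.concatenate([p["A"] for p in all_params])
    c = np.concatenate([p["c"] for p in all_params])

    if simulate_choices:
        dp, gp, lp = simulate_agents_batch(
            a, lam, A, c, config.n_practice, rng, schedule, config.payoff_scale, config.theta_rule
        )
        de, ge, le = simulate_agents_batch(
            a, lam, A, c, config.n_experimental, rng, schedule, config.payoff_scale, config.theta_rule
        )
        decks = np.concatenate([dp, de], axis=1)
        gains = np.concatenate([gp, ge], axis=1)
        losses = np.concatenate([lp, le], axis=1)
        is_practice = np.concatenate(
            [np.ones(config.n_practice, bool), np.zeros(config.n_experimental, bool)]
        )
        trials = _trials_frame(ids_cat, groups_cat, decks, gains, losses, is_practice)
    else:
        trials = pd.DataFrame(
            columns=["subject_id", "group", "trial", "deck", "gain", "loss", "net", "is_practice"]
        )
    return CohortDataset(subjects=subjects, trials=trials, config=config)


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    simulate_choices: bool = True,
) -> CohortDataset:
    """Generate a high-risk (n=42) vs control (n=43) synthetic cohort.

    Per-subject PVL parameters and covariates are drawn from the configured
    group moments; choices are simulated by the PVL agent on the default
    schedule. Fully reproducible from the master seed.
    """
    config = config or CohortConfig()
    specs = [
        (HIGH_RISK, "hr", config.n_high_risk, config.param_moments[HIGH_RISK],
         config.covariate_moments[HIGH_RISK]),
        (CONTROL, "ct", config.n_control, config.param_moments[CONTROL],
         config.covariate_moments[CONTROL]),
    ]
    return _generate(config, seed, specs, simulate_choices)


def generate_null_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    simulate_choices: bool = True,
) -> CohortDataset:
    """Null cohort: both groups drawn from the control distribution.

    Group labels are arbitrary bookkeeping ("group1"/"group2"); any test
    that rejects more than its nominal rate on these cohorts is
    miscalibrated.
    """
    config = config or CohortConfig()
    pm = config.param_moments[CONTROL]
    cm = config.covariate_moments[CONTROL]
    specs = [
        ("group1", "n1", config.n_high_risk, pm, cm),
        ("group2", "n2", config.n_control, pm, cm),
    ]
    return _generate(config, seed, specs, simulate_choices)
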