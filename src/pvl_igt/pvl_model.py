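"""Prospect Valence Learning (PVL) model of Iowa Gambling Task choices.

The model maps each trial's net outcome x(t) to a subjective valence with a
prospect-theory utility,

    u(t) = x(t)^a            if x(t) >= 0
         = -λ |x(t)|^a       if x(t) <  0,

decays and updates per-deck expectancies with a delta-rule,

    E_j(t) = A · E_j(t-1) + δ_j(t) · u(t),

where δ_j(t) indicates the chosen deck, and turns expectancies into choice
probabilities with a softmax whose sensitivity is θ = 3^c − 1:

    Pr[D(t+1) = j] ∝ exp(θ · E_j(t)).

Parameters: feedback sensitivity a ∈ [0,1], loss aversion λ ∈ [0,5],
learning/decay A ∈ [0,1], response consistency c ∈ [0,5]. The same recursion
serves as generative agent (:func:`simulate_agent`) and as likelihood
(:func:`log_likelihood`); both share the kernels in ``_kernels``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .igt_task import (
    DECK_INDEX,
    DECKS,
    N_EXPERIMENTAL_TRIALS,
    N_PRACTICE_TRIALS,
    LossMode,
    PayoffSchedule,
    build_default_schedule,
    draw_outcome,
)

#: net outcomes are multiplied by this before entering the utility; keeps
#: θ·E in a numerically benign range and matches the scale on which the
#: parameter ranges are conventionally reported
DEFAULT_PAYOFF_SCALE = 0.01

PARAM_NAMES = ("a", "lam", "A", "c")
PARAM_BOUNDS = {"a": (0.0, 1.0), "lam": (0.0, 5.0), "A": (0.0, 1.0), "c": (0.0, 5.0)}


class ThetaRule(str, enum.Enum):
    """Softmax sensitivity rule: the constant 3^c − 1 form, or a genuinely
    trial-dependent (t/10)^c alternative."""

    AS_PRINTED = "as_printed"
    TRIAL_DEPENDENT = "trial_dependent"

    @property
    def code(self) -> int:
        return (
            _kernels.THETA_AS_PRINTED
            if self is ThetaRule.AS_PRINTED
            else _kernels.THETA_TRIAL_DEPENDENT
        )


@dataclass(frozen=True)
class PVLParameters:
    """The four PVL parameters with their admissible ranges."""

    a: float
    lam: float
    A: float
    c: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            lo, hi = PARAM_BOUNDS[name]
            if not (lo <= value <= hi) or not np.isfinite(value):
                raise ValueError(f"parameter {name}={value} outside [{lo}, {hi}]")

    def as_dict(self) -> dict[str, float]:
        return {"a": self.a, "lam": self.lam, "A": self.A, "c": self.c}

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.lam, self.A, self.c])


@dataclass(frozen=True)
class ExpectancyState:
    """Per-deck expectancy valences after trial ``t`` (t=0: before trial 1)."""

    E: np.ndarray = field(default_factory=lambda: np.zeros(4))
    t: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "E", np.asarray(self.E, dtype=float))
        if self.E.shape != (4,) or not np.all(np.isfinite(self.E)):
            raise ValueError("expectancies must be 4 finite reals")


@dataclass
class ChoiceSequence:
    """One subject's ordered trials as parallel arrays.

    ``nets`` holds the signed net outcome x(t) = gain + loss (loss stored
    non-positive); ``payoff_scale`` multiplies x(t) before the utility.
    """

    decks: np.ndarray  # int codes 0..3
    gains: np.ndarray
    losses: np.ndarray
    subject_id: str = "s0"
    payoff_scale: float = DEFAULT_PAYOFF_SCALE

    def __post_init__(self) -> None:
        self.decks = np.asarray(self.decks, dtype=np.int64)
        self.gains = np.asarray(self.gains, dtype=float)
        self.losses = np.asarray(self.losses, dtype=float)
        if not ((self.decks >= 0) & (self.decks <= 3)).all():
            raise ValueError("deck codes must be 0..3")
        if self.payoff_scale <= 0:
            raise ValueError("payoff_scale must be positive")

    def __len__(self) -> int:
        return len(self.decks)

    @property
    def nets(self) -> np.ndarray:
        return self.gains + self.losses

    @property
    def deck_letters(self) -> np.ndarray:
        return np.array(DECKS)[self.decks]

    def to_frame(self, group: str | None = None, is_practice: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "trial": np.arange(1, len(self) + 1),
                "deck": self.deck_letters,
                "gain": self.gains,
                "loss": self.losses,
                "net": self.nets,
                "is_practice": is_practice,
            }
        )
        if group is not None:
            df.insert(1, "group", group)
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        subject_id: str | None = None,
        payoff_scale: float = DEFAULT_PAYOFF_SCALE,
        drop_practice: bool = True,
    ) -> "ChoiceSequence":
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        elif df["subject_id"].nunique() > 1:
            raise ValueError("frame holds several subjects; pass subject_id")
        if drop_practice and "is_practice" in df.columns:
            df = df[~df["is_practice"].astype(bool)]
        df = df.sort_values("trial")
        decks = np.array([DECK_INDEX[d] for d in df["deck"]])
        return cls(
            decks=decks,
            gains=df["gain"].to_numpy(float),
            losses=df["loss"].to_numpy(float),
            subject_id=str(df["subject_id"].iloc[0]),
            payoff_scale=payoff_scale,
        )


def utility(x: float, a: float, lam: float) -> float:
    """Prospect-theory valence of a net outcome (u(0) = 0 by convention)."""
    if x > 0:
        return x**a
    if x == 0:
        return 0.0
    return -lam * (-x) ** a


def update_expectancies(
    state: ExpectancyState, chosen: str | int, u: float, A: float
) -> ExpectancyState:
    """Decay all expectancies by A and credit the chosen deck with u."""
    if not 0 <= A <= 1:
        raise ValueError("learning parameter A must be in [0, 1]")
    j = DECK_INDEX[chosen] if isinstance(chosen, str) else int(chosen)
    if not 0 <= j <= 3:
        raise KeyError(f"unknown deck {chosen!r}")
    E = A * state.E
    E[j] += u
    return ExpectancyState(E=E, t=state.t + 1)


def consistency_theta(
    c: float, t: int = 1, rule: ThetaRule | str = ThetaRule.AS_PRINTED
) -> float:
    """Softmax sensitivity θ for consistency c at trial t (1-based)."""
    rule = ThetaRule(rule)
    if rule is ThetaRule.AS_PRINTED:
        return 3.0**c - 1.0
    return (t / 10.0) ** c


def choice_probabilities(
    state: ExpectancyState, c: float, rule: ThetaRule | str = ThetaRule.AS_PRINTED
) -> np.ndarray:
    """Softmax choice probabilities over the four decks (max-stabilised)."""
    theta = consistency_theta(c, max(state.t + 1, 1), rule)
    z = theta * state.E
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def simulate_agent(
    params: PVLParameters,
    schedule: PayoffSchedule | None = None,
    n_trials: int = N_EXPERIMENTAL_TRIALS,
    seed: int | np.random.Generator | None = None,
    rule: ThetaRule | str = ThetaRule.AS_PRINTED,
    payoff_scale: float = DEFAULT_PAYOFF_SCALE,
    subject_id: str = "s0",
) -> ChoiceSequence:
    """Generate one agent's choice sequence by forward simulation.

    Each trial samples a deck from the current choice probabilities, draws
    the outcome from the payoff schedule (tracking per-deck selection counts
    for the loss cycles), and updates the expectancies. Reproducible given
    the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    schedule = schedule or build_default_schedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rule = ThetaRule(rule)
    state = ExpectancyState()
    counts = {d: 0 for d in DECKS}
    decks = np.empty(n_trials, dtype=np.int64)
    gains = np.empty(n_trials)
    losses = np.empty(n_trials)
    for t in range(n_trials):
        p = choice_probabilities(state, params.c, rule)
        j = int(rng.choice(4, p=p))
        letter = DECKS[j]
        counts[letter] += 1
        gain, loss = draw_outcome(schedule, letter, counts[letter], rng)
        decks[t], gains[t], losses[t] = j, gain, loss
        u = utility((gain + loss) * payoff_scale, params.a, params.lam)
        state = update_expectancies(state, j, u, params.A)
    return ChoiceSequence(
        decks=decks, gains=gains, losses=losses, subject_id=subject_id, payoff_scale=payoff_scale
    )


def log_likelihood(
    seq: ChoiceSequence,
    params: PVLParameters,
    rule: ThetaRule | str = ThetaRule.AS_PRINTED,
) -> float:
    """Σ_t log Pr[deck_t | expectancies before trial t].

    The first trial sees all-zero expectancies, hence contributes log(1/4).
    Probabilities are floored at 1e-12 so in-range parameters never yield −∞.
    """
    if len(seq) == 0:
        raise ValueError("choice sequence is empty")
    if not isinstance(params, PVLParameters):
        params = PVLParameters(*params)
    rule = ThetaRule(rule)
    x = seq.nets * seq.payoff_scale
    return float(
        _kernels.loglik_seq(seq.decks, x, params.a, params.lam, params.A, params.c, rule.code)
    )


def log_likelihood_many(
    sequences: list[ChoiceSequence],
    params_matrix: np.ndarray,
    subject_index: np.ndarray | None = None,
    rule: ThetaRule | str = ThetaRule.AS_PRINTED,
) -> np.ndarray:
    """Batch log-likelihoods: row r of ``params_matrix`` (a, λ, A, c) is
    scored against sequence ``subject_index[r]`` (identity by default).

    All sequences must share a common trial count (the fitting surface for a
    cohort of equal-length runs); this is the code path both fitters use.
    """
    n_trials = {len(s) for s in sequences}
    if len(n_trials) != 1:
        raise ValueError("all sequences must have equal length for batch evaluation")
    decks2d = np.stack([s.decks for s in sequences])
    x2d = np.stack([s.nets * s.payoff_scale for s in sequences])
    params_matrix = np.asarray(params_matrix, dtype=float)
    if subject_index is None:
        subject_index = np.arange(len(sequences))
    subject_index = np.asarray(subject_index, dtype=np.int64)
    rule = ThetaRule(rule)
    return _kernels.loglik_batch(decks2d, x2d, subject_index, params_matrix, rule.code)


def simulate_practice_and_task(
    params: PVLParameters,
    schedule: PayoffSchedule | None = None,
    seed: int | np.random.Generator | None = None,
    n_practice: int = N_PRACTICE_TRIALS,
    n_experimental: int = N_EXPERIMENTAL_TRIALS,
    rule: ThetaRule | str = ThetaRule.AS_PRINTED,
    payoff_scale: float = DEFAULT_PAYOFF_SCALE,
    subject_id: str = "s0",
) -> pd.DataFrame:
    """120-trial session: 20 flagged practice trials then 100 experimental.

    The experimental run restarts from zero expectancies and fresh deck
    cycles, so scoring and fitting (which drop practice rows) see a
    self-contained task instance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    practice = simulate_agent(
        params, schedule, n_practice, rng, rule, payoff_scale, subject_id
    ).to_frame(is_practice=True)
    task = simulate_agent(
        params, schedule, n_experimental, rng, rule, payoff_scale, subject_id
    ).to_frame(is_practice=False)
    task["trial"] = task["trial"] + n_practice
    return pd.concat([practice, task], ignore_index=True)
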