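"""Iowa Gambling Task environment and behavioural scoring.

The IGT presents four card decks. Every selection pays a fixed gain; losses
arrive on a subset of selections. Decks A and B pay large gains but lose more
than they gain over a full cycle of selections (expected value −$250 per 10
selections), decks C and D pay small gains but come out ahead (+$250 per 10
selections). Decision-making is scored by the *net score*: selections from the
advantageous decks C and D minus selections from the disadvantageous decks A
and B, in total and per 20-trial block.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

DECKS = ("A", "B", "C", "D")
DECK_INDEX = {d: i for i, d in enumerate(DECKS)}

#: trials per scoring block
BLOCK_SIZE = 20
#: experimental trials scored per subject
N_EXPERIMENTAL_TRIALS = 100
#: practice trials preceding the experimental trials
N_PRACTICE_TRIALS = 20

#: KEAT-26 total strictly above this value labels a subject high-risk
KEAT26_THRESHOLD = 22


class LossMode(str, enum.Enum):
    """How loss events are placed within a deck's 10-selection cycle."""

    DETERMINISTIC_CYCLE = "deterministic_cycle"
    BERNOULLI = "bernoulli"


@dataclass(frozen=True)
class DeckSchedule:
    """Payoff rule for one deck.

    ``loss_events_per_cycle`` losses of magnitude ``mean_loss_per_event``
    occur per 10 consecutive selections of the deck; gains are constant.
    """

    gain_per_selection: float
    loss_events_per_cycle: int
    mean_loss_per_event: float

    def __post_init__(self) -> None:
        if self.gain_per_selection <= 0:
            raise ValueError("gain_per_selection must be positive")
        if not 0 <= self.loss_events_per_cycle <= 10:
            raise ValueError("loss_events_per_cycle must be in [0, 10]")
        if self.mean_loss_per_event < 0:
            raise ValueError("mean_loss_per_event is a positive magnitude")


@dataclass(frozen=True)
class PayoffSchedule:
    """Payoff schedules for the four decks plus the loss-timing mode."""

    decks: dict[str, DeckSchedule]
    loss_mode: LossMode = LossMode.DETERMINISTIC_CYCLE

    def __post_init__(self) -> None:
        if set(self.decks) != set(DECKS):
            raise ValueError(f"schedule must define exactly the decks {DECKS}")

    def deck(self, deck: str) -> DeckSchedule:
        try:
            return self.decks[deck]
        except KeyError:
            raise KeyError(f"unknown deck {deck!r}; decks are {DECKS}") from None

    def loss_positions(self, deck: str) -> frozenset[int]:
        """1-based within-cycle positions carrying a loss (deterministic mode).

        The k loss events are spread evenly over the 10-selection cycle:
        positions {10·i/k : i = 1..k} (so one loss lands at position 10,
        five losses at 2, 4, 6, 8, 10).
        """
        k = self.deck(deck).loss_events_per_cycle
        return frozenset(round(10 * i / k) for i in range(1, k + 1)) if k else frozenset()

    def to_yaml(self, path) -> None:
        data = {
            "loss_mode": self.loss_mode.value,
            "decks": {
                d: {
                    "gain_per_selection": s.gain_per_selection,
                    "loss_events_per_cycle": s.loss_events_per_cycle,
                    "mean_loss_per_event": s.mean_loss_per_event,
                }
                for d, s in self.decks.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "PayoffSchedule":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            decks={d: DeckSchedule(**v) for d, v in data["decks"].items()},
            loss_mode=LossMode(data.get("loss_mode", "deterministic_cycle")),
        )


def build_default_schedule(loss_mode: LossMode | str = LossMode.DETERMINISTIC_CYCLE) -> PayoffSchedule:
    """The standard computerised-IGT payoff schedule.

    A: +100 per pick, 5 losses of 250 per 10 picks; B: +100, 1 loss of 1250;
    C: +50, 5 losses of 50; D: +50, 1 loss of 250. Expected values per
    10-selection cycle: −250, −250, +250, +250.
    """
    return PayoffSchedule(
        decks={
            "A": DeckSchedule(100.0, 5, 250.0),
            "B": DeckSchedule(100.0, 1, 1250.0),
            "C": DeckSchedule(50.0, 5, 50.0),
            "D": DeckSchedule(50.0, 1, 250.0),
        },
        loss_mode=LossMode(loss_mode),
    )


def draw_outcome(
    schedule: PayoffSchedule,
    deck: str,
    deck_selection_count: int,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Gain and (non-positive) loss for the n-th selection of a deck.

    ``deck_selection_count`` counts this selection among all selections of
    this deck so far (1-based). In deterministic-cycle mode the loss falls
    exactly on the schedule's designated within-cycle positions; in bernoulli
    mode it occurs with probability loss_events_per_cycle/10 (requires rng).
    """
    ds = schedule.deck(deck)
    if deck_selection_count < 1:
        raise ValueError("deck_selection_count is 1-based and must be >= 1")
    gain = ds.gain_per_selection
    if schedule.loss_mode is LossMode.DETERMINISTIC_CYCLE:
        position = (deck_selection_count - 1) % 10 + 1
        hit = position in schedule.loss_positions(deck)
    else:
        if rng is None:
            raise ValueError("bernoulli loss mode requires an rng")
        hit = rng.random() < ds.loss_events_per_cycle / 10.0
    loss = -ds.mean_loss_per_event if hit else 0.0
    return gain, loss


def expected_value_per_cycle(schedule: PayoffSchedule, deck: str) -> float:
    """Net payoff accumulated over one full 10-selection cycle of a deck."""
    ds = schedule.deck(deck)
    return 10.0 * ds.gain_per_selection - ds.loss_events_per_cycle * ds.mean_loss_per_event


@dataclass(frozen=True)
class NetScoreSummary:
    """Behavioural summary of one subject's experimental trials."""

    total_net: int
    block_nets: tuple[int, ...]
    deck_counts: dict[str, int] = field(default_factory=dict)
    n_trials: int = N_EXPERIMENTAL_TRIALS


def _net_score(decks: np.ndarray) -> int:
    # (C + D) − (A + B)
    good = np.isin(decks, ("C", "D")).sum()
    return int(good - (decks.size - good))


def compute_net_scores(decks, *, allow_any_multiple: bool = False) -> NetScoreSummary:
    """Total and per-block net scores plus deck counts for one subject.

    ``decks`` is the ordered sequence of chosen deck letters over the
    experimental trials (practice trials already removed). Exactly 100 trials
    are required unless ``allow_any_multiple`` permits any positive multiple
    of the 20-trial block size.
    """
    decks = np.asarray(list(decks), dtype="U1")
    n = decks.size
    if not np.isin(decks, DECKS).all():
        bad = sorted(set(decks) - set(DECKS))
        raise ValueError(f"invalid deck labels {bad}; decks are {DECKS}")
    if n != N_EXPERIMENTAL_TRIALS and not (
        allow_any_multiple and n > 0 and n % BLOCK_SIZE == 0
    ):
        raise ValueError(
            f"expected {N_EXPERIMENTAL_TRIALS} experimental trials, got {n} "
            f"(pass allow_any_multiple=True for other multiples of {BLOCK_SIZE})"
        )
    blocks = tuple(
        _net_score(decks[i : i + BLOCK_SIZE]) for i in range(0, n, BLOCK_SIZE)
    )
    counts = {d: int((decks == d).sum()) for d in DECKS}
    return NetScoreSummary(
        total_net=_net_score(decks), block_nets=blocks, deck_counts=counts, n_trials=n
    )


def label_risk_group(keat26_total: float, threshold: float = KEAT26_THRESHOLD) -> str:
    """Cohort label from the KEAT-26 total: strictly above 22 is high-risk."""
    if keat26_total < 0:
        raise ValueError("KEAT-26 total score cannot be negative")
    return "high_risk" if keat26_total > threshold else "control"


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject net-score table from a trial-level table.

    Expects columns subject_id, trial, deck and (optionally) is_practice;
    practice trials are dropped before scoring. Returns one row per subject:
    subject_id, total_net, block1..block5, count_A..count_D.
    """
    df = trials
    if "is_practice" in df.columns:
        df = df[~df["is_practice"].astype(bool)]
    rows = []
    for sid, sub in df.sort_values("trial").groupby("subject_id", sort=False):
        s = compute_net_scores(sub["deck"].to_numpy())
        row = {"subject_id": sid, "total_net": s.total_net}
        if "group" in sub.columns:
            row["group"] = sub["group"].iloc[0]
        row.update({f"block{i + 1}": b for i, b in enumerate(s.block_nets)})
        row.update({f"count_{d}": s.deck_counts[d] for d in DECKS})
        rows.append(row)
    return pd.DataFrame(rows)
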