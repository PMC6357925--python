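"""Score the cohort's IGT behaviour.

Computes each subject's total net score, the five 20-trial block net scores
and the per-deck selection counts from the experimental trials, and writes
results/scores.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from pvl_igt import igt_task as it


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--trials", type=Path, default=Path("results/cohort/trials.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/scores.csv"))
    args = ap.parse_args()

    trials = pd.read_csv(args.trials)
    scores = it.score_trials(trials)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(args.out, index=False)

    print(f"scored {len(scores)} subjects -> {args.out}")
    cols = ["total_net"] + [f"block{i}" for i in range(1, 6)]
    print("\nGroup mean net scores:")
    print(scores.groupby("group")[cols].mean().round(2).to_string())
    print("\nGroup mean deck selection counts:")
    print(scores.groupby("group")[[f"count_{d}" for d in "ABCD"]].mean().round(2).to_string())


if __name__ == "__main__":
    main()
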