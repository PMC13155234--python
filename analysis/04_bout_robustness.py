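"""Does computing the exponent from 11 instead of 15 bouts matter?

The short overground walkway limits how many 8-stride bouts some
participants provide, motivating an 11-bout protocol over the 15-bout
convention. This script repeats the comparison on simulated cohorts: for
each replicate, 16 trials long enough for 15 bouts are simulated, the
exponent is computed under both bout plans, and a paired t-test with
Cohen's d summarizes the difference.
"""

import argparse
from pathlib import Path

import gaitdyn as gd

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--replicates", type=int, default=20)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    df = gd.bout_robustness(
        n_replicates=args.replicates, n_participants=16, n_strides=135,
        seed=args.seed,
    )
    df.to_csv(OUT / "bout_robustness.csv", index=False)
    small = ((df["d"].abs() < 0.3) & (df["p"] > 0.05)).mean()
    print(f"median |d| = {df['d'].abs().median():.3f}, "
          f"median p = {df['p'].median():.3f}")
    print(f"{small:.0%} of replicates show |d| < 0.3 and p > 0.05")
    print("(a paired-t d on 16 null differences scatters as t(15)/4, so "
          "~75% is the expected fraction for an unbiased estimator)")
    print(f"-> {OUT / 'bout_robustness.csv'}")


if __name__ == "__main__":
    main()
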