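"""Impact of training-set imbalance on each decoder.

Reduces one condition's training trials by 10-50% while keeping the test
sets balanced, and measures the paired performance drop per decoder.
Writes results/imbalance_sweep.csv.
"""

import argparse
import time
from pathlib import Path

from popdecode.classifiers import DecoderSpec
from popdecode.experiments import sweep_imbalance
from popdecode.rng import child_seed
from popdecode.synth import GeneratorConfig, generate_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"

SVM_GRID = dict(c_grid=(0.125, 2.0, 32.0, 512.0), gamma_grid=(0.004, 0.06, 1.0))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-seeds", type=int, default=10)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    ds = generate_dataset(
        GeneratorConfig.for_variable(
            "endogenous", rng_seed=child_seed(args.seed, "gen-endogenous")
        )
    )
    specs = [
        DecoderSpec("svm", params=SVM_GRID, rng_seed=args.seed),
        DecoderSpec("reservoir", rng_seed=args.seed),
        DecoderSpec("r_ole", rng_seed=args.seed),
        DecoderSpec("bayes", rng_seed=args.seed),
        DecoderSpec("ann_ole", rng_seed=args.seed),
    ]
    t0 = time.time()
    table = sweep_imbalance(
        ds, specs, master_seed=child_seed(args.seed, "imbalance"),
        n_seeds=args.n_seeds,
    )
    table.to_csv(RESULTS / "imbalance_sweep.csv", index=False)
    print(f"== imbalance sweep (t={time.time() - t0:.0f}s) ==")
    print(table.round(2).to_string(index=False))
    print("\nThe equal-priors Bayes decoder is structurally indifferent to "
          "class frequencies, so its drop stays small; regression- and "
          "margin-based readouts shift toward the majority class instead.")


if __name__ == "__main__":
    main()
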