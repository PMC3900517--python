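"""Generate the two synthetic recording sessions and summarize them.

One dataset per decoded variable: the exogenous (stream-position) session
uses the abundant trial counts typical of a stimulus-driven analysis, the
endogenous (attention-position) session the scarcer correct-trial counts.
Writes a population summary table under results/ and, with --save-rasters,
the full plain-text raster layout (large) for reuse by external tools.
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from popdecode.rng import child_seed
from popdecode.synth import GeneratorConfig, generate_dataset, save_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--save-rasters", action="store_true")
    args = parser.parse_args()

    rows = []
    for variable in ("exogenous", "endogenous"):
        cfg = GeneratorConfig.for_variable(
            variable, rng_seed=child_seed(args.seed, f"gen-{variable}")
        )
        ds = generate_dataset(cfg)
        classes = Counter(c.selectivity_class for c in ds.cells)
        n_trials = [labs.size for labs in ds.labels]
        rows.append(
            dict(
                variable=variable,
                n_cells=ds.n_cells,
                visual_cells=classes["visual"] + classes["mixed"],
                attention_cells=classes["attention"] + classes["mixed"],
                mean_trials_per_condition=sum(n_trials) / len(n_trials) / 2,
                min_trials_per_condition=min(n_trials) // 2,
                max_trials_per_condition=max(n_trials) // 2,
                trial_duration_ms=ds.trial_duration,
            )
        )
        if args.save_rasters:
            save_dataset(ds, RESULTS / "data" / variable)
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "datasets.csv", index=False)
    print(table.to_string(index=False))
    print("\nBoth sessions share the 131-cell composition: 111 visually "
          "driven cells (one also attention-driven) and 21 attention cells.")


if __name__ == "__main__":
    main()
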