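#!/usr/bin/env python
"""Replicate the published benchmark runs on the real datasets.

Requires a manual download of the public "sEMG for Basic Hand movements"
repository (UCI Machine Learning Repository) and is therefore NOT part
of the test suite. Expected layout::

    <root>/DB1/*.mat   five per-subject files, 30 trials/class/channel
    <root>/DB2/*.mat   three per-day files, 100 trials/class/channel

Usage::

    python examples/replicate_uci.py <root> --out results_uci

Runs the full pipeline on DB1 (900 trials), DB2 (1800) and their fusion
DB3 (2700) with the default configuration and prints each summary. The
published accuracies for comparison are 98.89% (DB1), 94.94% (DB2) and
95.30% (DB3); exact equality is not expected because fold assignment,
the standard-deviation convention and the SVM kernel-scale heuristic
are implementation choices.
"""

import argparse
from pathlib import Path

from grasptex import PipelineConfig, build_db3, load_basic_hand_movements, run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("root", type=Path, help="directory containing DB1/ and DB2/")
    parser.add_argument("--out", type=Path, default=Path("results_uci"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    db1 = load_basic_hand_movements(args.root / "DB1", dataset_id="DB1")
    db2 = load_basic_hand_movements(args.root / "DB2", dataset_id="DB2")
    datasets = {"DB1": db1, "DB2": db2, "DB3": build_db3(db1, db2)}

    for name, dataset in datasets.items():
        print(f"=== {name}: {len(dataset)} trials ===")
        results = run_pipeline(
            dataset, PipelineConfig(seed=args.seed), outdir=args.out / name
        )
        print(results.summary())
        print()


if __name__ == "__main__":
    main()
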