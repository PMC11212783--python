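#!/usr/bin/env python
"""Run the three-phase measure screening over the evaluated values tables.

Duplicates and complements are detected on the probe table (removal only
for formula-confirmed equivalences); the 5%-NA / infinite-mean rule runs on
the raw and centered tables of the three non-cultural datasets; the
degeneracy rule runs on their centered tables; the two cultural datasets
serve as a warn-only out-of-sample check.  Writes screening_report.csv and
screening_summary.txt and prints the retained count with removal reasons.
"""

import argparse
from pathlib import Path

from profilesim import catalog_ids, run_selection
from profilesim.io import read_values_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--na-threshold", type=float, default=0.05)
    parser.add_argument("--min-datasets", type=int, default=2)
    args = parser.parse_args()

    load = lambda stem: read_values_table(args.results / f"{stem}.csv")
    screen_ids = ("esm", "vmr", "lab")
    holdout_ids = ("cult14", "cult20")
    report = run_selection(
        catalog_ids(),
        probe_values=load("values_probes"),
        screen_tables={i: [load(f"values_{i}_raw"),
                           load(f"values_{i}_centered")]
                       for i in screen_ids},
        degenerate_tables={i: load(f"values_{i}_centered")
                           for i in screen_ids},
        holdout_tables={i: [load(f"values_{i}_raw"),
                            load(f"values_{i}_centered")]
                        for i in holdout_ids},
        na_threshold=args.na_threshold, min_datasets=args.min_datasets)

    report.export_csv(args.results / "screening_report.csv")
    (args.results / "screening_summary.txt").write_text(
        report.summary_text() + "\n")
    print(report.summary_text())


if __name__ == "__main__":
    main()
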