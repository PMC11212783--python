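#!/usr/bin/env python
"""Evaluate the full measure catalog on every dataset, raw and centered.

Reads dataset_<id>.csv from the results directory, builds pairs and
evaluation contexts, and writes values_<id>_raw.csv / values_<id>_centered.csv
(long format) plus values_probes.csv — the probe table (first dataset's
centered pairs + seeded random nonnegative integer probe pairs) used by the
duplicate/complement screening step.  Prints per-dataset missing-value
summaries, which preview the screening outcome.
"""

import argparse
from pathlib import Path

import numpy as np

from profilesim import catalog_ids
from profilesim.io import read_long_dataset, write_values_table
from profilesim.pipeline import _probe_values, prepare_dataset
from profilesim.synthetic import SUITE_DESIGNS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1,
                        help="seed for the random probe pairs")
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    ids = catalog_ids()
    first_bundle = None
    for name in SUITE_DESIGNS:
        ds = read_long_dataset(args.results / f"dataset_{name}.csv")
        bundle = prepare_dataset(ds, ids)
        if first_bundle is None:
            first_bundle = bundle
        write_values_table(bundle.raw_values,
                           args.results / f"values_{name}_raw.csv")
        write_values_table(bundle.centered_values,
                           args.results / f"values_{name}_centered.csv")
        na_raw = bundle.raw_values.isna().mean()
        na_cen = bundle.centered_values.isna().mean()
        worst = (np.maximum(na_raw, na_cen)).sort_values(ascending=False)
        print(f"{name:7s} pairs={len(bundle.centered_values):5d} "
              f"measures={len(ids)}  highest missing fractions: "
              + ", ".join(f"{m}={v:.2f}" for m, v in worst.head(3).items()))

    probes = _probe_values(first_bundle, ids, n_probes=100, seed=args.seed)
    write_values_table(probes, args.results / "values_probes.csv")
    print(f"probe table: {len(probes)} observations "
          f"(centered pairs of {first_bundle.raw.dataset_id} + 100 probes)")


if __name__ == "__main__":
    main()
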