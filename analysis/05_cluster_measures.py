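#!/usr/bin/env python
"""Cluster the retained measures by behavioural similarity, per dataset.

For every dataset: multilevel-Spearman 1-|rho| distances between the
retained measures' centered value columns, Ward clustering, and a
longest-gap dendrogram cut.  Then labels cross-dataset consistency and
writes distance matrices (CSV), dendrograms (Newick), partitions.csv and
cluster_summary.yaml.  Prints the per-dataset main-cluster counts, the
modal count, and the measures whose cluster membership is inconsistent.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from profilesim import (cross_dataset_consistency, cut_longest,
                        measure_distance_matrix, ward_cluster)
from profilesim.io import read_long_dataset, read_values_table
from profilesim.synthetic import SUITE_DESIGNS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--min-agree", type=int, default=4)
    args = parser.parse_args()

    screening = pd.read_csv(args.results / "screening_report.csv")
    retained = screening.loc[screening.status == "retained",
                             "measure"].tolist()
    print(f"clustering {len(retained)} retained measures")

    partitions = {}
    rows = []
    for name in SUITE_DESIGNS:
        ds = read_long_dataset(args.results / f"dataset_{name}.csv")
        values = read_values_table(
            args.results / f"values_{name}_centered.csv")[retained]
        if ds.design == "lab_like":
            groups = np.repeat("all", len(values))   # no nesting
        else:
            groups = values.index.get_level_values("group_id").to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            D = measure_distance_matrix(values, groups)
        dend = ward_cluster(D)
        part = cut_longest(dend)
        partitions[name] = part
        D.to_csv(args.results / f"distance_{name}.csv")
        (args.results / f"dendrogram_{name}.nwk").write_text(
            dend.to_newick() + "\n")
        print(f"  {name:7s} main clusters: {len(set(part.values()))}")
        rows.extend((m, name, c) for m, c in part.items())

    groups_out, inconsistent = cross_dataset_consistency(
        list(partitions.values()), min_agree=args.min_agree)
    part_frame = pd.DataFrame(rows, columns=["measure_id", "dataset_id",
                                             "cluster"])
    part_frame["consistent_flag"] = ~part_frame.measure_id.isin(inconsistent)
    part_frame.to_csv(args.results / "partitions.csv", index=False)

    counts = [len(set(p.values())) for p in partitions.values()]
    modal = max(set(counts), key=counts.count)
    summary = {
        "cluster_counts": {n: len(set(p.values()))
                           for n, p in partitions.items()},
        "modal_main_cluster_count": int(modal),
        "consistent_group_sizes": sorted((len(g) for g in groups_out),
                                         reverse=True),
        "inconsistent_measures": sorted(inconsistent),
        "min_agree": args.min_agree,
    }
    (args.results / "cluster_summary.yaml").write_text(
        yaml.safe_dump(summary, sort_keys=False))
    print(f"modal main-cluster count: {modal}")
    print(f"consistent group sizes: {summary['consistent_group_sizes']}")
    print(f"inconsistent measures: {summary['inconsistent_measures']}")


if __name__ == "__main__":
    main()
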