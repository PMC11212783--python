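"""End-to-end pipeline: simulate, center, pair, evaluate, screen, cluster.

:func:`run_pipeline` ties the modules together exactly in the order the
analysis prescribes: generate (or accept) the five datasets, center each
with its design-matched scheme, form profile pairs, evaluate the full
measure catalog on raw and centered pairs, run the three-phase screening on
the non-cultural datasets with the cultural ones as a warn-only out-of-sample
check, compute per-dataset 1-|rho| distance matrices over the retained
measures, cluster with Ward's criterion, cut each dendrogram at the longest
height gap, and label cross-dataset consistency.  All randomness flows from
a single seed; a re-run with the same configuration reproduces every number
bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import catalog_ids, export_catalog_csv
from .clustering import (cross_dataset_consistency, cut_longest,
                         measure_distance_matrix, ward_cluster)
from .io import write_long_dataset, write_values_table
from .measures import MeasureContext, compute_values_table
from .preprocessing import LongDataset, PairSet, center, cultural_norms, \
    make_pairs
from .screening import ScreeningReport, run_selection
from .synthetic import default_suite

log = logging.getLogger("profilesim")

__all__ = ["PipelineConfig", "DatasetBundle", "PipelineResult",
           "prepare_dataset", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; defaults mirror the analysis."""

    seed: int = 0
    output_dir: Optional[Path] = None
    measures: Optional[Sequence[str]] = None
    datasets: Optional[Sequence[LongDataset]] = None
    na_threshold: float = 0.05
    min_datasets: int = 2
    constant_fraction: float = 0.5
    ward_dialect: str = "d2"
    min_agree: Optional[int] = None  # default: n_datasets - 1
    n_probe_pairs: int = 100

    def __post_init__(self):
        for name in ("na_threshold", "constant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class DatasetBundle:
    """One dataset with everything the later stages need."""

    raw: LongDataset
    centered: LongDataset
    raw_pairs: PairSet
    centered_pairs: PairSet
    raw_ctx: MeasureContext
    centered_ctx: MeasureContext
    raw_values: pd.DataFrame
    centered_values: pd.DataFrame
    grouping: np.ndarray


@dataclass
class PipelineResult:
    bundles: dict[str, DatasetBundle]
    screening: ScreeningReport
    distances: dict[str, pd.DataFrame]
    dendrograms: dict
    partitions: dict[str, dict[str, int]]
    consistent_groups: list[list[str]]
    inconsistent: list[str]
    summary: dict
    manifest: list[str] = field(default_factory=list)


def _centered_midpoints(raw: LongDataset) -> np.ndarray:
    """Scale midpoints expressed in centered coordinates: the midpoint minus
    the per-variable raw grand mean (the average shift centering applies)."""
    lo, hi = raw.scale
    grand = np.nanmean(raw.values(), axis=0)
    return (lo + hi) / 2.0 - grand


def prepare_dataset(ds: LongDataset, measure_ids: Sequence[str]
                    ) -> DatasetBundle:
    """Center, pair and evaluate one dataset (raw and centered routes)."""
    spec = ds.default_centering
    if spec is None:
        raise ValueError(f"dataset {ds.dataset_id} has no centering spec")
    centered = center(ds, spec)
    if ds.design == "culture_like":
        raw_pairs = make_pairs(ds, cultural_norms(ds))
        centered_pairs = make_pairs(centered, cultural_norms(centered))
    else:
        raw_pairs = make_pairs(ds)
        centered_pairs = make_pairs(centered)
    raw_ctx = MeasureContext.from_values(ds.values(), scale=ds.scale)
    centered_ctx = MeasureContext.from_values(
        centered.values(), midpoints=_centered_midpoints(ds))
    raw_values = compute_values_table(raw_pairs, measure_ids, raw_ctx)
    centered_values = compute_values_table(centered_pairs, measure_ids,
                                           centered_ctx)
    if ds.design == "lab_like" or ds.frame.groupby("group_id").size().max() <= 1:
        # cross-sectional dyads: no nesting, a single constant group
        grouping = np.repeat("all", len(centered_pairs))
    else:
        grouping = np.asarray(centered_pairs.group_ids)
    return DatasetBundle(ds, centered, raw_pairs, centered_pairs, raw_ctx,
                         centered_ctx, raw_values, centered_values, grouping)


def _probe_values(first: DatasetBundle, measure_ids: Sequence[str],
                  n_probes: int, seed: int) -> pd.DataFrame:
    """Probe table for duplicate/complement detection: the first dataset's
    centered pairs plus seeded random nonnegative integer probe pairs.

    Probes are drawn on a 0..6 integer grid: rating-like, nonnegative (so
    that complement identities that hold on positive scores are exercised)
    and tied (so that tie-sensitive measures are separated).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1097]))
    p = len(first.raw.variables)
    X = rng.integers(0, 7, size=(n_probes, p)).astype(float)
    Y = rng.integers(0, 7, size=(n_probes, p)).astype(float)

    class _Probes:
        dataset_id = "probes"
        pair_ids = np.array([f"probe{i}" for i in range(n_probes)])
        group_ids = np.repeat("probe", n_probes)

    probes = _Probes()
    probes.X, probes.Y = X, Y
    probe_tab = compute_values_table(probes, measure_ids, first.centered_ctx)
    return pd.concat([first.centered_values, probe_tab])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    measure_ids = list(config.measures) if config.measures is not None \
        else catalog_ids()
    datasets = list(config.datasets) if config.datasets is not None \
        else default_suite(config.seed)
    log.info("pipeline: %d datasets, %d measures, seed=%d",
             len(datasets), len(measure_ids), config.seed)

    bundles: dict[str, DatasetBundle] = {}
    for ds in datasets:
        bundles[ds.dataset_id] = prepare_dataset(ds, measure_ids)
        log.info("dataset %s: %d raw pairs, %d centered pairs",
                 ds.dataset_id, len(bundles[ds.dataset_id].raw_pairs),
                 len(bundles[ds.dataset_id].centered_pairs))

    # screening: non-cultural datasets screen, cultural ones are held out
    screen_ids = [d.dataset_id for d in datasets
                  if d.design != "culture_like"]
    if len(screen_ids) < 2:
        screen_ids = [d.dataset_id for d in datasets]
    holdout_ids = [d.dataset_id for d in datasets
                   if d.dataset_id not in screen_ids]
    first = bundles[datasets[0].dataset_id]
    probe_values = _probe_values(first, measure_ids, config.n_probe_pairs,
                                 config.seed)
    report = run_selection(
        measure_ids, probe_values,
        screen_tables={i: [bundles[i].raw_values, bundles[i].centered_values]
                       for i in screen_ids},
        degenerate_tables={i: bundles[i].centered_values
                           for i in screen_ids},
        holdout_tables={i: [bundles[i].raw_values,
                            bundles[i].centered_values]
                        for i in holdout_ids} or None,
        na_threshold=config.na_threshold,
        min_datasets=config.min_datasets,
        constant_fraction=config.constant_fraction)
    log.info("screening: %d retained, %d removed",
             len(report.retained), len(report.removed))

    # clustering per dataset over the retained measures
    distances, dendrograms, partitions = {}, {}, {}
    for ds_id, bundle in bundles.items():
        D = measure_distance_matrix(bundle.centered_values[report.retained],
                                    bundle.grouping)
        dend = ward_cluster(D, dialect=config.ward_dialect)
        distances[ds_id] = D
        dendrograms[ds_id] = dend
        partitions[ds_id] = cut_longest(dend)

    min_agree = config.min_agree if config.min_agree is not None \
        else max(2, len(bundles) - 1)
    groups, inconsistent = cross_dataset_consistency(
        list(partitions.values()), min_agree=min_agree)

    cluster_counts = {ds_id: len(set(p.values()))
                      for ds_id, p in partitions.items()}
    counts = list(cluster_counts.values())
    modal = max(set(counts), key=counts.count)
    summary = {
        "seed": config.seed,
        "n_measures_input": len(measure_ids),
        "n_retained": len(report.retained),
        "removed": {m: [list(r) for r in reasons]
                    for m, reasons in report.removed.items()},
        "cluster_counts": cluster_counts,
        "modal_main_cluster_count": int(modal),
        "n_consistent_groups": len(groups),
        "consistent_group_sizes": sorted((len(g) for g in groups),
                                         reverse=True),
        "inconsistent_measures": sorted(inconsistent),
        "min_agree": min_agree,
    }

    result = PipelineResult(bundles, report, distances, dendrograms,
                            partitions, groups, inconsistent, summary)
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest = []

    def record(path: Path):
        manifest.append(str(path.relative_to(out)))

    cat = out / "catalog.csv"
    export_catalog_csv(cat)
    record(cat)
    for ds_id, b in result.bundles.items():
        for tag, ds in (("raw", b.raw), ("centered", b.centered)):
            p = out / f"dataset_{ds_id}_{tag}.csv"
            write_long_dataset(ds, p)
            record(p)
        for tag, tab in (("raw", b.raw_values),
                         ("centered", b.centered_values)):
            p = out / f"values_{ds_id}_{tag}.csv"
            write_values_table(tab, p)
            record(p)
        p = out / f"distance_{ds_id}.csv"
        result.distances[ds_id].to_csv(p)
        record(p)
        p = out / f"dendrogram_{ds_id}.nwk"
        p.write_text(result.dendrograms[ds_id].to_newick() + "\n")
        record(p)
    p = out / "screening_report.csv"
    result.screening.export_csv(p)
    record(p)
    p = out / "screening_summary.txt"
    p.write_text(result.screening.summary_text() + "\n")
    record(p)
    rows = []
    for ds_id, part in result.partitions.items():
        for m, c in part.items():
            rows.append((m, ds_id, c,
                         m not in result.inconsistent))
    p = out / "partitions.csv"
    pd.DataFrame(rows, columns=["measure_id", "dataset_id", "cluster",
                                "consistent_flag"]).to_csv(p, index=False)
    record(p)
    p = out / "summary.yaml"
    p.write_text(yaml.safe_dump(result.summary, sort_keys=False))
    record(p)
    result.manifest = manifest
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
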