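"""Rule-based measure screening.

The selection procedure reduces a candidate catalog in three phases:

1. duplicate and complement detection on a probe set of profile pairs —
   measures whose value columns coincide (or sum to one) are flagged, and a
   flagged measure is *removed* only when the catalog records the
   equivalence as confirmed at the formula level (``duplicate_of`` /
   ``complement_of``), since numerically coincident values alone cannot
   prove two formulas equivalent;
2. the NA / infinite screen: a measure is excluded when it yields at least
   5% missing values, or an (almost) infinite column mean, in at least two
   of the screening datasets (raw or centered counts both count against a
   dataset);
3. the degeneracy screen: a measure whose single most frequent value covers
   more than half of the non-missing observations allows almost no
   differentiation and is excluded.

Surviving measures are then re-checked on held-out datasets with the same
criteria, warn-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import get_definition

__all__ = [
    "ScreeningReport",
    "detect_duplicates",
    "detect_complements",
    "na_screen",
    "degenerate_screen",
    "run_selection",
]

DEFAULT_TOL = 1e-9
MIN_SHARED = 10
INF_MEAN = 1e12


def _close(a: np.ndarray, b: np.ndarray, tol: float) -> bool:
    scale = np.maximum(np.abs(a), np.abs(b))
    return bool(np.all(np.abs(a - b) <= tol * np.maximum(scale, 1.0)))


def _joint(values: pd.DataFrame, m1: str, m2: str):
    a = values[m1].to_numpy(dtype=float)
    b = values[m2].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def detect_duplicates(values: pd.DataFrame, tol: float = DEFAULT_TOL,
                      min_shared: int = MIN_SHARED) -> list[list[str]]:
    """Partition the measure columns into numerical-equality classes.

    Two measures join a class when their columns agree within relative
    tolerance ``tol`` at every jointly non-missing observation and share at
    least ``min_shared`` such observations.  Returns the full partition in
    column order (singleton classes included).
    """
    cols = list(values.columns)
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, m1 in enumerate(cols):
        for m2 in cols[i + 1:]:
            if find(m1) == find(m2):
                continue
            a, b = _joint(values, m1, m2)
            if a.size >= min_shared and _close(a, b, tol):
                parent[find(m2)] = find(m1)
    classes: dict[str, list[str]] = {}
    for c in cols:
        classes.setdefault(find(c), []).append(c)
    return [classes[r] for r in cols if r in classes]


def detect_complements(values: pd.DataFrame, tol: float = DEFAULT_TOL,
                       min_shared: int = MIN_SHARED
                       ) -> list[tuple[str, str, str]]:
    """Flag measure pairs whose values sum to 1 everywhere on the probes.

    Returns ``(m1, m2, retained)`` triples where ``retained`` is the member
    whose catalog direction is ``similarity`` (the information-preserving
    choice when one of the two is dropped).
    """
    cols = list(values.columns)
    out = []
    for i, m1 in enumerate(cols):
        for m2 in cols[i + 1:]:
            a, b = _joint(values, m1, m2)
            if a.size >= min_shared and _close(a + b, np.ones_like(a), tol):
                d1 = get_definition(m1)
                retained = m1 if d1.direction == "similarity" else m2
                out.append((m1, m2, retained))
    return out


def _na_fraction(col: pd.Series) -> float:
    return float(np.mean(np.isnan(col.to_numpy(dtype=float))))


def _inf_mean(col: pd.Series, cutoff: float = INF_MEAN) -> bool:
    v = col.to_numpy(dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return False
    with np.errstate(over="ignore", invalid="ignore"):
        m = v.mean()
    return bool(np.isinf(m) or np.isnan(m) or np.abs(m) > cutoff)


def na_screen(tables: Mapping[str, pd.DataFrame | Sequence[pd.DataFrame]],
              threshold: float = 0.05, min_datasets: int = 2,
              inf_cutoff: float = INF_MEAN
              ) -> tuple[list[str], pd.DataFrame]:
    """Apply the 5%-NA / (almost) infinite-mean rule across datasets.

    ``tables`` maps dataset id to one values table or a sequence of them
    (e.g. raw and centered); a dataset counts against a measure when any of
    its tables trips the threshold.  Returns the excluded measures plus a
    per-(measure, dataset) detail frame.
    """
    if len(tables) < 2:
        raise ValueError("na_screen needs at least 2 datasets")
    records = []
    hit_counts: dict[str, int] = {}
    for ds, tabs in tables.items():
        if isinstance(tabs, pd.DataFrame):
            tabs = [tabs]
        measures = list(tabs[0].columns)
        for m in measures:
            na = max(_na_fraction(t[m]) for t in tabs)
            inf = any(_inf_mean(t[m], inf_cutoff) for t in tabs)
            hit = na >= threshold or inf
            records.append((m, ds, na, inf, hit))
            if hit:
                hit_counts[m] = hit_counts.get(m, 0) + 1
    detail = pd.DataFrame(records, columns=["measure", "dataset",
                                            "na_fraction", "inf_flag", "hit"])
    order = list(dict.fromkeys(detail["measure"]))
    excluded = [m for m in order if hit_counts.get(m, 0) >= min_datasets]
    return excluded, detail


def degenerate_screen(values: pd.DataFrame, constant_fraction: float = 0.5,
                      decimals: int = 9) -> list[str]:
    """Flag measures whose modal value covers more than ``constant_fraction``
    of the non-missing observations (e.g. a similarity stuck at 1)."""
    flagged = []
    for m in values.columns:
        v = values[m].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        _, counts = np.unique(np.round(v, decimals), return_counts=True)
        if counts.max() / v.size > constant_fraction:
            flagged.append(m)
    return flagged


@dataclass
class ScreeningReport:
    """Outcome of :func:`run_selection`.

    Every input measure appears exactly once: either in ``retained`` or in
    ``removed`` with at least one (phase, reason) record.  ``warnings``
    collects flags that did not lead to removal (unconfirmed duplicates or
    complements, out-of-sample re-checks).
    """

    retained: list[str]
    removed: dict[str, list[tuple[str, str]]]
    duplicate_classes: list[list[str]]
    complement_pairs: list[tuple[str, str, str]]
    na_detail: pd.DataFrame
    degenerate_flags: dict[str, list[str]]
    warnings: list[str] = field(default_factory=list)

    def removal_reason(self, measure: str) -> Optional[list[tuple[str, str]]]:
        return self.removed.get(measure)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.retained:
            rows.append((m, "retained", "", ""))
        for m, reasons in self.removed.items():
            for phase, reason in reasons:
                rows.append((m, "removed", phase, reason))
        return pd.DataFrame(rows, columns=["measure", "status", "phase",
                                           "reason"])

    def export_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_text(self) -> str:
        lines = [f"retained measures: {len(self.retained)}",
                 f"removed measures: {len(self.removed)}"]
        for m, reasons in self.removed.items():
            for phase, reason in reasons:
                lines.append(f"  - {m}: [{phase}] {reason}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def run_selection(measure_ids: Sequence[str], probe_values: pd.DataFrame,
                  screen_tables: Mapping[str, Sequence[pd.DataFrame]],
                  degenerate_tables: Mapping[str, pd.DataFrame],
                  holdout_tables: Optional[Mapping[str, Sequence[pd.DataFrame]]] = None,
                  na_threshold: float = 0.05, min_datasets: int = 2,
                  constant_fraction: float = 0.5,
                  tol: float = DEFAULT_TOL) -> ScreeningReport:
    """Run the full three-phase selection over a candidate catalog.

    ``probe_values`` feeds duplicate/complement detection; ``screen_tables``
    (dataset id -> [raw table, centered table]) feeds the NA/infinite rule;
    ``degenerate_tables`` (dataset id -> centered table) feeds the
    degeneracy rule, which excludes a measure flagged in at least
    ``min_datasets`` datasets.  ``holdout_tables`` triggers a warn-only
    out-of-sample re-check of the surviving measures.
    """
    measure_ids = list(measure_ids)
    removed: dict[str, list[tuple[str, str]]] = {}
    warnings: list[str] = []

    def remove(m, phase, reason):
        removed.setdefault(m, []).append((phase, reason))

    # phase 1a: duplicates
    dup_classes = detect_duplicates(probe_values[measure_ids], tol=tol)
    for cls in dup_classes:
        if len(cls) < 2:
            continue
        confirmed = [m for m in cls if get_definition(m).duplicate_of in cls]
        unconfirmed = [m for m in cls
                       if m not in confirmed and len(cls) > 1]
        for m in confirmed:
            remove(m, "duplicate",
                   f"duplicate of {get_definition(m).duplicate_of}")
        if len(unconfirmed) > 1 and not confirmed:
            warnings.append(
                f"numerically duplicate but not formula-confirmed: {cls}")

    alive = [m for m in measure_ids if m not in removed]

    # phase 1b: complements
    comp_pairs = detect_complements(probe_values[alive], tol=tol)
    for m1, m2, retained_member in comp_pairs:
        dropped = m2 if retained_member == m1 else m1
        d = get_definition(dropped)
        if d.complement_of == retained_member:
            remove(dropped, "complement",
                   f"complement of {retained_member}")
        else:
            warnings.append(
                f"numerically complementary but not formula-confirmed: "
                f"({m1}, {m2})")
    alive = [m for m in alive if m not in removed]

    # phase 2: NA / infinite screen
    na_excluded, na_detail = na_screen(
        {ds: [t[alive] for t in tabs] for ds, tabs in screen_tables.items()},
        threshold=na_threshold, min_datasets=min_datasets)
    for m in na_excluded:
        hits = na_detail[(na_detail["measure"] == m) & na_detail["hit"]]
        remove(m, "na_screen",
               f">= {na_threshold:.0%} NAs or infinite mean in "
               f"{len(hits)} datasets ({', '.join(hits['dataset'])})")
    alive = [m for m in alive if m not in removed]

    # phase 3: degenerate outputs
    degen_flags: dict[str, list[str]] = {}
    for ds, table in degenerate_tables.items():
        degen_flags[ds] = degenerate_screen(table[alive],
                                            constant_fraction=constant_fraction)
    counts: dict[str, int] = {}
    for flags in degen_flags.values():
        for m in flags:
            counts[m] = counts.get(m, 0) + 1
    for m, c in counts.items():
        if c >= min_datasets:
            remove(m, "degenerate",
                   f"modal value covers > {constant_fraction:.0%} of "
                   f"observations in {c} datasets")
    alive = [m for m in alive if m not in removed]

    # out-of-sample re-check (warn-only, mirrors the held-out application)
    if holdout_tables:
        for ds, tabs in holdout_tables.items():
            for m in alive:
                na = max(_na_fraction(t[m]) for t in tabs)
                inf = any(_inf_mean(t[m]) for t in tabs)
                if na >= na_threshold or inf:
                    warnings.append(
                        f"out-of-sample: {m} trips NA/inf rule on {ds} "
                        f"(na={na:.3f}, inf={inf})")
            flagged = degenerate_screen(tabs[-1][alive],
                                        constant_fraction=constant_fraction)
            for m in flagged:
                warnings.append(f"out-of-sample: {m} degenerate on {ds}")

    return ScreeningReport(
        retained=alive, removed=removed, duplicate_classes=dup_classes,
        complement_pairs=comp_pairs, na_detail=na_detail,
        degenerate_flags=degen_flags, warnings=warnings)
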