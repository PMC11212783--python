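"""Catalog of profile (dis)similarity measures.

Each entry describes one measure: its identity, direction (similarity vs
distance), the behavioural group it belongs to, recorded bounds, which
profile-similarity components (shape / scatter / elevation) it responds to,
and which evaluation context it needs (per-variable ranges, standardization
statistics, scale midpoints, Cattell's K).

The catalog covers the 43 retained measures (groups G1-G6 plus the four
measures whose group membership is inconsistent across datasets) and three
excluded exemplars (Canberra distance, Bray-Curtis distance, Czekanowski
distance) that exist to exercise the screening procedure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "MeasureDefinition",
    "CATALOG",
    "get_definition",
    "catalog_ids",
    "retained_ids",
    "exemplar_ids",
    "export_catalog_csv",
]

SIMILARITY = "similarity"
DISTANCE = "distance"

G1 = "G1_difference"
G2 = "G2_miscellaneous"
G3 = "G3_independence"
G4 = "G4_rank_sign"
G5 = "G5_scaled_product"
G6 = "G6_mccrae"
INCONSISTENT = "inconsistent"
EXCLUDED = "excluded_exemplar"

SHAPE = "shape"
SCATTER = "scatter"
ELEVATION = "elevation"
ALL_COMPONENTS = frozenset({SHAPE, SCATTER, ELEVATION})
SHAPE_ONLY = frozenset({SHAPE})


@dataclass(frozen=True)
class MeasureDefinition:
    """One catalog entry.

    ``bounds`` records the closed interval the measure is guaranteed to stay
    in; ``bounds_positive_only`` marks bounds that hold only for nonnegative
    inputs.  ``negative_input_caveat`` flags measures whose values are hard to
    interpret on mixed-sign data (groups G2 and G5).  ``duplicate_of`` /
    ``complement_of`` record formula-level equivalences confirmed by
    inspection; the screening stage removes a measure only when a data-driven
    flag coincides with such a confirmed link.
    """

    id: str
    display_name: str
    direction: str
    group: str
    bounds: Optional[tuple[float, float]] = None
    bounds_positive_only: bool = False
    sensitivity: frozenset[str] = field(default_factory=frozenset)
    requires_context: frozenset[str] = field(default_factory=frozenset)
    negative_input_caveat: bool = False
    duplicate_of: Optional[str] = None
    complement_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in (SIMILARITY, DISTANCE):
            raise ValueError(f"bad direction {self.direction!r} for {self.id}")


def _m(id, name, direction, group, **kw):
    caveat = group in (G2, G5)
    kw.setdefault("negative_input_caveat", caveat)
    if "sensitivity" in kw:
        kw["sensitivity"] = frozenset(kw["sensitivity"])
    if "requires_context" in kw:
        kw["requires_context"] = frozenset(kw["requires_context"])
    return MeasureDefinition(id, name, direction, group, **kw)


# Group 1: difference-score measures.  All unipolar distances except
# Cattell's r_p, which is algebraically forced into a bipolar
# correlation-like format.
_GROUP1 = [
    _m("manhattan", "Manhattan distance", DISTANCE, G1, sensitivity=ALL_COMPONENTS),
    _m("euclidean", "Euclidean distance", DISTANCE, G1, sensitivity=ALL_COMPONENTS),
    _m("squared_euclidean", "Squared Euclidean distance", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS),
    _m("chebyshev", "Chebyshev's distance", DISTANCE, G1, sensitivity=ALL_COMPONENTS),
    _m("avg_l1_linf", "Avg(L1, Linf) distance", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS),
    _m("mean_character", "Mean character distance", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS),
    _m("lorentzian", "Lorentzian distance", DISTANCE, G1, sensitivity=ALL_COMPONENTS),
    _m("gower", "Gower distance", DISTANCE, G1, bounds=(0.0, 1.0),
       sensitivity=ALL_COMPONENTS, requires_context={"ranges"}),
    _m("scaled_euclidean", "Scaled Euclidean distance", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS, requires_context={"ranges"}),
    _m("half_range_standardized", "Half-range standardized distance", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS, requires_context={"ranges"}),
    _m("max_scaled_difference", "Maximum scaled difference", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS, requires_context={"ranges"}),
    _m("mean_censored_euclidean", "Mean censored Euclidean distance", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS),
    _m("penrose_size", "Penrose size distance", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS),
    _m("penrose_shape", "Penrose shape distance", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS),
    _m("burrows_delta", "Burrows's Delta", DISTANCE, G1,
       sensitivity=ALL_COMPONENTS, requires_context={"standardization"}),
    _m("cattell_rp", "Cattell's r_p", SIMILARITY, G1, bounds=(-1.0, 1.0),
       sensitivity=ALL_COMPONENTS, requires_context={"cattell_k"}),
]

# Group 2: miscellaneous; five of the seven carry minima/maxima in their
# formulas.  Bounds hold on nonnegative scores only.
_GROUP2 = [
    _m("bray_curtis_sim", "Bray-Curtis similarity", SIMILARITY, G2,
       bounds=(0.0, 1.0), bounds_positive_only=True, sensitivity=ALL_COMPONENTS),
    _m("intersection_sim", "Intersection similarity", SIMILARITY, G2,
       sensitivity=ALL_COMPONENTS),
    _m("morisita", "Morisita's index of similarity", SIMILARITY, G2,
       sensitivity=ALL_COMPONENTS),
    _m("morisita_horn", "Morisita-Horn index of similarity", SIMILARITY, G2,
       bounds=(0.0, 1.0), bounds_positive_only=True, sensitivity=ALL_COMPONENTS),
    _m("motyka", "Motyka similarity", SIMILARITY, G2,
       bounds=(0.0, 0.5), bounds_positive_only=True, sensitivity=ALL_COMPONENTS),
    _m("ruzicka", "Ruzicka similarity", SIMILARITY, G2,
       bounds=(0.0, 1.0), bounds_positive_only=True, sensitivity=ALL_COMPONENTS),
    _m("soergel", "Soergel distance", DISTANCE, G2,
       bounds=(0.0, 1.0), bounds_positive_only=True, sensitivity=ALL_COMPONENTS),
]

# Group 3: dependence measures (zero only under no association).
_GROUP3 = [
    _m("dcor", "Distance correlation", SIMILARITY, G3, bounds=(0.0, 1.0),
       sensitivity=SHAPE_ONLY),
    _m("dcov", "Distance covariance", SIMILARITY, G3, sensitivity=SHAPE_ONLY),
    _m("tau_star", "Tau Star", SIMILARITY, G3, sensitivity=SHAPE_ONLY),
]

# Group 4: rank- and sign-based correlations and covariances.
_GROUP4 = [
    _m("gamma", "Goodman-Kruskal Gamma correlation", SIMILARITY, G4,
       bounds=(-1.0, 1.0), sensitivity=SHAPE_ONLY),
    _m("kendall_tau_b", "Kendall tau-b rank correlation", SIMILARITY, G4,
       bounds=(-1.0, 1.0), sensitivity=SHAPE_ONLY),
    _m("kendall_cov", "Kendall tau-b rank covariance", SIMILARITY, G4,
       sensitivity=SHAPE_ONLY),
    _m("spearman_corr", "Spearman rank correlation", SIMILARITY, G4,
       bounds=(-1.0, 1.0), sensitivity=SHAPE_ONLY),
    _m("spearman_cov", "Spearman rank covariance", SIMILARITY, G4,
       sensitivity=SHAPE_ONLY),
]

# Group 5: scaled products — pairwise product in the numerator, some
# scaling in the denominator.  Angular and Orloci distances sit here because
# they contain the literal cosine similarity inside their formulas.
_GROUP5 = [
    _m("cosine", "Cosine similarity", SIMILARITY, G5, bounds=(-1.0, 1.0),
       sensitivity=ALL_COMPONENTS),
    _m("angular_distance", "Angular distance", DISTANCE, G5,
       sensitivity=ALL_COMPONENTS),
    _m("orloci", "Orloci distance", DISTANCE, G5, sensitivity=ALL_COMPONENTS),
    _m("cohen_rc", "Cohen's r_c", SIMILARITY, G5, bounds=(-1.0, 1.0),
       sensitivity=ALL_COMPONENTS, requires_context={"midpoints"}),
    _m("extended_dice", "Extended Dice similarity", SIMILARITY, G5,
       bounds=(0.0, 1.0), bounds_positive_only=True, sensitivity=ALL_COMPONENTS),
    _m("kohonen", "Kohonen similarity", SIMILARITY, G5,
       bounds=(0.0, 1.0), bounds_positive_only=True, sensitivity=ALL_COMPONENTS),
]

# Group 6: McCrae's agreement measures, designed for extreme profiles.
_GROUP6 = [
    _m("mccrae_coefficient", "McCrae's coefficient of profile agreement",
       SIMILARITY, G6, bounds=(-1.0, 1.0), sensitivity=ALL_COMPONENTS,
       requires_context={"standardization"}),
    _m("mccrae_index", "McCrae's index of profile agreement", SIMILARITY, G6,
       sensitivity=ALL_COMPONENTS, requires_context={"standardization"}),
]

# Measures whose subgroup membership varies across datasets.
_INCONSISTENT = [
    _m("pearson_corr", "Pearson correlation", SIMILARITY, INCONSISTENT,
       bounds=(-1.0, 1.0), sensitivity=SHAPE_ONLY),
    _m("pearson_cov", "Pearson covariance", SIMILARITY, INCONSISTENT,
       sensitivity=SHAPE_ONLY),
    _m("icc_double_entry", "Double-Entry intraclass correlation", SIMILARITY,
       INCONSISTENT, bounds=(-1.0, 1.0), sensitivity=ALL_COMPONENTS),
    _m("inner_product", "Inner product", SIMILARITY, INCONSISTENT,
       sensitivity=ALL_COMPONENTS),
]

# Exemplars of excluded measures, kept to exercise screening: the
# Czekanowski distance duplicates the Bray-Curtis distance, the Bray-Curtis
# distance complements the Bray-Curtis similarity, and the Canberra distance
# degenerates (0/0 terms) on zero-inflated rating data.
_EXEMPLARS = [
    _m("bray_curtis_dist", "Bray-Curtis distance", DISTANCE, EXCLUDED,
       sensitivity=ALL_COMPONENTS, complement_of="bray_curtis_sim"),
    _m("czekanowski_dist", "Czekanowski distance", DISTANCE, EXCLUDED,
       sensitivity=ALL_COMPONENTS, duplicate_of="bray_curtis_dist"),
    _m("canberra", "Canberra distance", DISTANCE, EXCLUDED,
       sensitivity=ALL_COMPONENTS),
]

CATALOG: tuple[MeasureDefinition, ...] = tuple(
    _GROUP1 + _GROUP2 + _GROUP3 + _GROUP4 + _GROUP5 + _GROUP6
    + _INCONSISTENT + _EXEMPLARS
)

_BY_ID = {d.id: d for d in CATALOG}
if len(_BY_ID) != len(CATALOG):  # pragma: no cover - construction sanity
    raise RuntimeError("duplicate measure ids in catalog")


def get_definition(measure_id: str) -> MeasureDefinition:
    try:
        return _BY_ID[measure_id]
    except KeyError:
        raise KeyError(f"unknown measure id: {measure_id!r}") from None


def catalog_ids(include_exemplars: bool = True) -> list[str]:
    """Measure ids in catalog order (retained first, exemplars last)."""
    return [d.id for d in CATALOG
            if include_exemplars or d.group != EXCLUDED]


def retained_ids() -> list[str]:
    """The 43 measures of the published retained list."""
    return catalog_ids(include_exemplars=False)


def exemplar_ids() -> list[str]:
    return [d.id for d in CATALOG if d.group == EXCLUDED]


def export_catalog_csv(path: str | Path) -> None:
    """Write the catalog as one CSV row per measure."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "display_name", "direction", "group",
                    "bounds_low", "bounds_high", "bounds_positive_only",
                    "sensitivity", "requires_context",
                    "negative_input_caveat", "duplicate_of", "complement_of"])
        for d in CATALOG:
            lo, hi = d.bounds if d.bounds is not None else ("", "")
            w.writerow([
                d.id, d.display_name, d.direction, d.group, lo, hi,
                d.bounds_positive_only,
                "+".join(sorted(d.sensitivity)),
                "+".join(sorted(d.requires_context)),
                d.negative_input_caveat,
                d.duplicate_of or "", d.complement_of or "",
            ])
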