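"""Centering schemes and dyad pairing.

Three centering schemes remove normative (stereotype) similarity before any
measure is evaluated:

* person-mean centering (longitudinal designs): subtract each person's
  per-variable mean across occasions, removing universal and person-specific
  stereotype responding while retaining within-person fluctuations;
* variable-mean centering by role (single-occasion dyadic designs): subtract
  each variable's mean separately per dyad role, the distinguishable-dyads
  analogue;
* grand-mean centering (cultural designs): subtract each variable's overall
  mean, eliminating stereotype responding common to all cultures while
  preserving between-culture mean differences — and thus the norms.

Pairing turns the long table into :class:`ProfilePair`-shaped data: one pair
per jointly answered (couple, occasion), or one pair per individual against
their own cultural norm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .measures import ProfilePair

__all__ = [
    "LongDataset",
    "CenteringSpec",
    "PairSet",
    "center",
    "cultural_norms",
    "make_pairs",
]

DYADIC_DESIGNS = ("esm_like", "vmr_like", "lab_like")
DESIGNS = DYADIC_DESIGNS + ("culture_like",)

ID_COLUMNS = ["group_id", "person_id", "role", "occasion_id"]


@dataclass
class LongDataset:
    """Tidy observation table plus design metadata.

    ``frame`` holds one row per (person, occasion) with columns
    ``group_id, person_id, role, occasion_id`` followed by the rating
    variables.  ``scale`` is the declared rating scale ``(lo, hi)``; centered
    data keep the original scale for reference but are no longer bounded by
    it (``centered`` flags this).
    """

    dataset_id: str
    design: str
    frame: pd.DataFrame
    variables: list[str]
    scale: tuple[float, float]
    centered: Optional[str] = None
    default_centering: Optional["CenteringSpec"] = None

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        missing = [c for c in ID_COLUMNS + self.variables
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame lacks columns {missing}")
        lo, hi = self.scale
        if not lo < hi:
            raise ValueError("scale must satisfy lo < hi")

    @property
    def is_dyadic(self) -> bool:
        return self.design in DYADIC_DESIGNS

    @property
    def is_longitudinal(self) -> bool:
        occ = self.frame.groupby("person_id", sort=False)["occasion_id"].nunique()
        return bool((occ > 1).any())

    def values(self) -> np.ndarray:
        return self.frame[self.variables].to_numpy(dtype=float)

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.centered is None:
            lo, hi = self.scale
            v = self.values()
            ok = np.isnan(v) | ((v >= lo) & (v <= hi))
            if not ok.all():
                raise ValueError("values outside the declared scale")
        if self.is_dyadic:
            counts = self.frame.groupby(
                ["group_id", "occasion_id", "role"], sort=False).size()
            if (counts > 1).any():
                raise ValueError(
                    "more than one row per (group, occasion, role)")


@dataclass(frozen=True)
class CenteringSpec:
    """Which centering scheme to apply.

    ``by_role`` matters for ``variable_mean_by_role`` only; person-mean
    centering is per person and therefore per role automatically.
    """

    mode: str = "none"
    by_role: bool = True

    _MODES = ("person_mean", "variable_mean_by_role", "grand_mean", "none")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"unknown centering mode {self.mode!r}")


def center(dataset: LongDataset, spec: CenteringSpec) -> LongDataset:
    """Return a centered copy of ``dataset``.

    Missing values are excluded from every mean and stay missing afterwards;
    a person-variable cell with a single observation centers to zero.
    Raises if person-mean centering is requested on single-occasion data.
    """
    df = dataset.frame.copy()
    vals = df[dataset.variables]
    if spec.mode == "none":
        centered = vals
    elif spec.mode == "person_mean":
        if not dataset.is_longitudinal:
            raise ValueError(
                "person-mean centering needs multiple occasions per person")
        centered = vals - vals.groupby(df["person_id"]).transform("mean")
    elif spec.mode == "variable_mean_by_role":
        key = df["role"] if spec.by_role else pd.Series(0, index=df.index)
        centered = vals - vals.groupby(key).transform("mean")
    elif spec.mode == "grand_mean":
        centered = vals - vals.mean(axis=0)
    else:  # pragma: no cover
        raise AssertionError(spec.mode)
    df[dataset.variables] = centered
    return replace(dataset, frame=df, centered=spec.mode)


def cultural_norms(dataset: LongDataset) -> pd.DataFrame:
    """Per-culture norm profiles: the per-variable mean over members.

    Returns a frame indexed by ``group_id`` with one column per variable.
    Raises if any culture has no observation for some variable.
    """
    if dataset.design != "culture_like":
        raise ValueError("cultural norms are defined for culture_like designs")
    norms = dataset.frame.groupby("group_id")[dataset.variables].mean()
    if norms.isna().any().any():
        bad = norms.index[norms.isna().any(axis=1)].tolist()
        raise ValueError(f"cultures with no observations on some variable: {bad}")
    return norms


@dataclass
class PairSet:
    """Stacked profile pairs ready for batch measure evaluation."""

    dataset_id: str
    design: str
    variables: list[str]
    X: np.ndarray
    Y: np.ndarray
    pair_ids: np.ndarray
    group_ids: np.ndarray

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_tuples(self) -> Iterator[tuple[str, str, ProfilePair]]:
        for i in range(len(self)):
            yield (self.pair_ids[i], self.group_ids[i],
                   ProfilePair(self.X[i], self.Y[i]))


def make_pairs(dataset: LongDataset,
               norms: Optional[pd.DataFrame] = None) -> PairSet:
    """Build profile pairs from a long dataset.

    Dyadic designs yield one pair per (couple, occasion) answered by both
    roles; cultural designs yield one pair per individual versus their own
    culture's norm (``norms`` required, typically from
    :func:`cultural_norms` after grand-mean centering).  Pairs containing any
    missing variable are dropped.
    """
    vars_ = dataset.variables
    df = dataset.frame
    if dataset.is_dyadic:
        roles = sorted(df["role"].unique())
        if len(roles) != 2:
            raise ValueError(f"dyadic design needs exactly 2 roles, got {roles}")
        wide = df.set_index(["group_id", "occasion_id", "role"])[vars_].unstack(
            "role")
        xa = wide.loc[:, pd.IndexSlice[:, roles[0]]].to_numpy(dtype=float)
        xb = wide.loc[:, pd.IndexSlice[:, roles[1]]].to_numpy(dtype=float)
        keep = ~(np.isnan(xa).any(axis=1) | np.isnan(xb).any(axis=1))
        idx = wide.index[keep]
        pair_ids = np.array([f"{g}:{t}" for g, t in idx])
        group_ids = np.array([str(g) for g, _ in idx])
        return PairSet(dataset.dataset_id, dataset.design, vars_,
                       xa[keep], xb[keep], pair_ids, group_ids)
    if norms is None:
        raise ValueError("culture_like pairing requires norm profiles")
    X = df[vars_].to_numpy(dtype=float)
    Y = norms.loc[df["group_id"], vars_].to_numpy(dtype=float)
    keep = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    pair_ids = (df["person_id"].astype(str) + ":"
                + df["occasion_id"].astype(str)).to_numpy()[keep]
    group_ids = df["group_id"].astype(str).to_numpy()[keep]
    return PairSet(dataset.dataset_id, dataset.design, vars_,
                   X[keep], Y[keep], pair_ids, group_ids)
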