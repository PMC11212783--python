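"""Evaluation of profile (dis)similarity measures.

Every measure consumes a :class:`ProfilePair` — two aligned rating vectors
``x`` and ``y`` over the same ``p`` variables — possibly together with a
:class:`MeasureContext` carrying per-variable ranges, standardization
statistics, scale midpoints and Cattell's K.

All formulas are implemented batch-first: the worker functions operate on
``(n, p)`` arrays of ``n`` pairs at once, and :func:`evaluate_measure` is the
scalar wrapper.  Data-driven degeneracies (division by zero, log of zero,
square root of a negative, zero variance) yield the missing marker (NaN),
never a silent zero and never an exception; genuine misuse (length mismatch,
unknown measure id, missing required context) raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MeasureDefinition, get_definition

__all__ = [
    "ProfilePair",
    "MeasureContext",
    "evaluate_measure",
    "evaluate_batch",
    "compute_values_table",
    "is_missing",
    "MISSING",
]

MISSING = float("nan")


def is_missing(value) -> np.ndarray | bool:
    """Predicate for the missing marker."""
    return np.isnan(value)


@dataclass(frozen=True)
class ProfilePair:
    """Two aligned numeric rating vectors over the same ``p >= 2`` variables.

    Missingness is resolved upstream: an occasion answered by only one dyad
    member produces no pair, so a ProfilePair never contains missing entries.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("profile vectors must be one-dimensional")
        if x.shape != y.shape:
            raise ValueError(
                f"profile length mismatch: {x.shape[0]} vs {y.shape[0]}")
        if x.shape[0] < 2:
            raise ValueError("profiles need at least 2 variables")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("ProfilePair must not contain missing entries")

    @property
    def p(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class MeasureContext:
    """Per-dataset evaluation context.

    ranges
        Per-variable range R_i in the units of the data, used by the Gower,
        scaled-Euclidean, half-range and maximum-scaled variants.
    means, sds
        Per-variable standardization statistics over a reference dataset
        (Burrows's Delta, McCrae's measures).
    midpoints
        Per-variable scale midpoint, expressed in the same coordinates as the
        data being evaluated (Cohen's r_c).
    cattell_k
        Cattell's K constant; defaults to the median of the chi-square
        distribution with p degrees of freedom, Cattell's convention for
        standardized profiles.
    """

    variable_count: int
    ranges: Optional[np.ndarray] = None
    means: Optional[np.ndarray] = None
    sds: Optional[np.ndarray] = None
    midpoints: Optional[np.ndarray] = None
    cattell_k: Optional[float] = None

    def __post_init__(self):
        for name in ("ranges", "means", "sds", "midpoints"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (self.variable_count,):
                    raise ValueError(
                        f"{name} must have length {self.variable_count}")
                object.__setattr__(self, name, v)
        if self.cattell_k is not None and not self.cattell_k > 0:
            raise ValueError("cattell_k must be positive")

    @classmethod
    def from_values(cls, values, scale: Optional[tuple[float, float]] = None,
                    midpoints: Optional[Sequence[float]] = None,
                    cattell_k: Optional[float] = None) -> "MeasureContext":
        """Build a context from a reference data matrix (rows = observations).

        Observed per-variable ranges and standardization statistics are
        computed from ``values`` (missing entries excluded).  Nonpositive
        observed ranges or SDs are stored as NaN so that measures consuming
        them degrade to the missing marker instead of dividing by zero.
        ``midpoints`` defaults to the scale midpoint when ``scale`` is given.
        """
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("values must be 2-D (observations x variables)")
        p = arr.shape[1]
        with np.errstate(all="ignore"):
            vmax = np.nanmax(arr, axis=0)
            vmin = np.nanmin(arr, axis=0)
            ranges = vmax - vmin
            means = np.nanmean(arr, axis=0)
            sds = np.nanstd(arr, axis=0, ddof=1)
        ranges = np.where(ranges > 0, ranges, np.nan)
        sds = np.where(sds > 0, sds, np.nan)
        if midpoints is None:
            if scale is not None:
                lo, hi = scale
                midpoints = np.full(p, (lo + hi) / 2.0)
            else:
                midpoints = np.zeros(p)
        if cattell_k is None:
            cattell_k = float(stats.chi2.median(df=p))
        return cls(variable_count=p, ranges=ranges, means=means, sds=sds,
                   midpoints=np.asarray(midpoints, dtype=float),
                   cattell_k=cattell_k)


# ---------------------------------------------------------------------------
# numeric helpers

def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(np.broadcast_shapes(num.shape, den.shape), np.nan)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _row_pearson(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    Uc = U - U.mean(axis=1, keepdims=True)
    Vc = V - V.mean(axis=1, keepdims=True)
    num = (Uc * Vc).sum(axis=1)
    den = np.sqrt((Uc * Uc).sum(axis=1) * (Vc * Vc).sum(axis=1))
    r = _safe_div(num, den)
    return np.clip(r, -1.0, 1.0)


def _need(ctx: Optional[MeasureContext], field: str, measure: str):
    if ctx is None or getattr(ctx, field, None) is None:
        raise ValueError(f"measure {measure!r} requires context field {field!r}")
    return getattr(ctx, field)


# ---------------------------------------------------------------------------
# Group 1: difference-score distances (d_i = x_i - y_i)

def _manhattan(X, Y, ctx):
    return np.abs(X - Y).sum(axis=1)


def _euclidean(X, Y, ctx):
    return np.sqrt(((X - Y) ** 2).sum(axis=1))


def _squared_euclidean(X, Y, ctx):
    return ((X - Y) ** 2).sum(axis=1)


def _chebyshev(X, Y, ctx):
    return np.abs(X - Y).max(axis=1)


def _avg_l1_linf(X, Y, ctx):
    return 0.5 * (_manhattan(X, Y, ctx) + _chebyshev(X, Y, ctx))


def _mean_character(X, Y, ctx):
    return np.abs(X - Y).mean(axis=1)


def _lorentzian(X, Y, ctx):
    return np.log1p(np.abs(X - Y)).sum(axis=1)


def _gower(X, Y, ctx):
    R = _need(ctx, "ranges", "gower")
    return (np.abs(X - Y) / R).mean(axis=1)


def _scaled_euclidean(X, Y, ctx):
    R = _need(ctx, "ranges", "scaled_euclidean")
    return np.sqrt((((X - Y) / R) ** 2).sum(axis=1))


def _half_range_standardized(X, Y, ctx):
    R = _need(ctx, "ranges", "half_range_standardized")
    return np.sqrt((((X - Y) / (R / 2.0)) ** 2).sum(axis=1))


def _max_scaled_difference(X, Y, ctx):
    R = _need(ctx, "ranges", "max_scaled_difference")
    return (np.abs(X - Y) / R).max(axis=1)


def _mean_censored_euclidean(X, Y, ctx):
    d2 = (X - Y) ** 2
    m = (~((X == 0) & (Y == 0))).sum(axis=1).astype(float)
    return np.sqrt(_safe_div(d2.sum(axis=1), m))


def _penrose_size(X, Y, ctx):
    return ((X - Y).mean(axis=1)) ** 2


def _penrose_shape(X, Y, ctx):
    d = X - Y
    return (d ** 2).mean(axis=1) - d.mean(axis=1) ** 2


def _burrows_delta(X, Y, ctx):
    sds = _need(ctx, "sds", "burrows_delta")
    return (np.abs(X - Y) / sds).mean(axis=1)


def _cattell_rp(X, Y, ctx):
    if ctx is None or ctx.cattell_k is None:
        raise ValueError("measure 'cattell_rp' requires context field 'cattell_k'")
    D2 = ((X - Y) ** 2).sum(axis=1)
    K = ctx.cattell_k
    return (2 * K - D2) / (2 * K + D2)


# ---------------------------------------------------------------------------
# Group 2: minimum/maximum-based similarities

def _bray_curtis_sim(X, Y, ctx):
    num = 2.0 * np.minimum(X, Y).sum(axis=1)
    return _safe_div(num, X.sum(axis=1) + Y.sum(axis=1))


def _motyka(X, Y, ctx):
    num = np.minimum(X, Y).sum(axis=1)
    return _safe_div(num, X.sum(axis=1) + Y.sum(axis=1))


def _ruzicka(X, Y, ctx):
    return _safe_div(np.minimum(X, Y).sum(axis=1), np.maximum(X, Y).sum(axis=1))


def _soergel(X, Y, ctx):
    return _safe_div(np.abs(X - Y).sum(axis=1), np.maximum(X, Y).sum(axis=1))


def _intersection_sim(X, Y, ctx):
    return np.minimum(X, Y).sum(axis=1)


def _morisita(X, Y, ctx):
    Nx = X.sum(axis=1)
    Ny = Y.sum(axis=1)
    lam_x = _safe_div((X * (X - 1.0)).sum(axis=1), Nx * (Nx - 1.0))
    lam_y = _safe_div((Y * (Y - 1.0)).sum(axis=1), Ny * (Ny - 1.0))
    num = 2.0 * (X * Y).sum(axis=1)
    return _safe_div(num, (lam_x + lam_y) * Nx * Ny)


def _morisita_horn(X, Y, ctx):
    Nx = X.sum(axis=1)
    Ny = Y.sum(axis=1)
    sx = _safe_div((X * X).sum(axis=1), Nx * Nx)
    sy = _safe_div((Y * Y).sum(axis=1), Ny * Ny)
    num = 2.0 * (X * Y).sum(axis=1)
    return _safe_div(num, (sx + sy) * Nx * Ny)


# ---------------------------------------------------------------------------
# Group 3: dependence measures

def _double_center(A: np.ndarray) -> np.ndarray:
    rm = A.mean(axis=2, keepdims=True)
    cm = A.mean(axis=1, keepdims=True)
    gm = A.mean(axis=(1, 2), keepdims=True)
    return A - rm - cm + gm


def _dcov_terms(X, Y):
    A = _double_center(np.abs(X[:, :, None] - X[:, None, :]))
    B = _double_center(np.abs(Y[:, :, None] - Y[:, None, :]))
    dcov2 = np.maximum((A * B).mean(axis=(1, 2)), 0.0)
    dvar2x = (A * A).mean(axis=(1, 2))
    dvar2y = (B * B).mean(axis=(1, 2))
    return dcov2, dvar2x, dvar2y


def _dcov(X, Y, ctx):
    dcov2, _, _ = _dcov_terms(X, Y)
    return np.sqrt(dcov2)


def _dcor(X, Y, ctx):
    dcov2, dvar2x, dvar2y = _dcov_terms(X, Y)
    denom = np.sqrt(dvar2x * dvar2y)
    out = np.zeros(X.shape[0])
    ok = denom > 0
    out[ok] = np.sqrt(dcov2[ok] / denom[ok])
    return np.clip(out, 0.0, 1.0)


_TAU_STAR_CACHE: dict[int, np.ndarray] = {}


def _tau_star_pairings(p: int) -> np.ndarray:
    """Index array (6, n_quadruples, 4) of ordered quadruple representatives.

    The sign kernel is invariant under within-pair swaps combined with a
    pair swap, so the 24 orderings of a quadruple collapse to 6 distinct
    kernel values: 3 pairings x 2 cross-pair matchings.  Averaging over
    these 6 reproduces the full ordered-quadruple U-statistic.
    """
    if p not in _TAU_STAR_CACHE:
        quads = np.array(list(combinations(range(p), 4)))
        _TAU_STAR_CACHE[p] = np.stack([
            quads[:, [0, 1, 2, 3]], quads[:, [0, 1, 3, 2]],
            quads[:, [0, 2, 1, 3]], quads[:, [0, 2, 3, 1]],
            quads[:, [0, 3, 1, 2]], quads[:, [0, 3, 2, 1]],
        ])
    return _TAU_STAR_CACHE[p]


def _sign_kernel(Z: np.ndarray) -> np.ndarray:
    # a(z1,z2,z3,z4) = sign(|z1-z2| + |z3-z4| - |z1-z3| - |z2-z4|)
    return np.sign(np.abs(Z[..., 0] - Z[..., 1]) + np.abs(Z[..., 2] - Z[..., 3])
                   - np.abs(Z[..., 0] - Z[..., 2]) - np.abs(Z[..., 1] - Z[..., 3]))


def _tau_star(X, Y, ctx):
    n, p = X.shape
    if p < 4:
        raise ValueError("tau_star requires profiles of length p >= 4")
    # the sign kernel depends only on the order pattern of each quadruple;
    # mid-rank transforming first makes the sign arithmetic exact (half
    # integers) where raw-value cancellation would be float-fragile
    X = stats.rankdata(X, axis=1)
    Y = stats.rankdata(Y, axis=1)
    pairings = _tau_star_pairings(p)
    m = pairings.shape[1]
    out = np.empty(n)
    chunk = max(1, 2_000_000 // (6 * m))
    for s in range(0, n, chunk):
        ax = _sign_kernel(X[s:s + chunk][:, pairings])
        ay = _sign_kernel(Y[s:s + chunk][:, pairings])
        out[s:s + chunk] = (ax * ay).mean(axis=(1, 2))
    return out


# ---------------------------------------------------------------------------
# Group 4: rank- and sign-based measures

def _ranks(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=1)


def _spearman_corr(X, Y, ctx):
    return _row_pearson(_ranks(X), _ranks(Y))


def _spearman_cov(X, Y, ctx):
    rx = _ranks(X)
    ry = _ranks(Y)
    p = X.shape[1]
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean(axis=1, keepdims=True)
    return (rxc * ryc).sum(axis=1) / (p - 1)


def _concordance_counts(X, Y):
    p = X.shape[1]
    iu, ju = np.triu_indices(p, 1)
    sx = np.sign(X[:, iu] - X[:, ju])
    sy = np.sign(Y[:, iu] - Y[:, ju])
    s = sx * sy
    C = (s > 0).sum(axis=1).astype(float)
    D = (s < 0).sum(axis=1).astype(float)
    Tx = (sx == 0).sum(axis=1).astype(float)
    Ty = (sy == 0).sum(axis=1).astype(float)
    n0 = p * (p - 1) / 2.0
    return C, D, Tx, Ty, n0


def _kendall_tau_b(X, Y, ctx):
    C, D, Tx, Ty, n0 = _concordance_counts(X, Y)
    den = np.sqrt((n0 - Tx) * (n0 - Ty))
    return _safe_div(C - D, den)


def _kendall_cov(X, Y, ctx):
    # tau-a form: the unnormalized concordance average (C - D) / n0
    C, D, _, _, n0 = _concordance_counts(X, Y)
    return (C - D) / n0


def _gamma(X, Y, ctx):
    C, D, _, _, _ = _concordance_counts(X, Y)
    return _safe_div(C - D, C + D)


# ---------------------------------------------------------------------------
# Group 5 and the inconsistent measures: product-based

def _inner_product(X, Y, ctx):
    return (X * Y).sum(axis=1)


def _pearson_cov(X, Y, ctx):
    p = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    return (Xc * Yc).sum(axis=1) / (p - 1)


def _pearson_corr(X, Y, ctx):
    return _row_pearson(X, Y)


def _icc_double_entry(X, Y, ctx):
    U = np.concatenate([X, Y], axis=1)
    V = np.concatenate([Y, X], axis=1)
    return _row_pearson(U, V)


def _cosine(X, Y, ctx):
    num = (X * Y).sum(axis=1)
    den = np.sqrt((X * X).sum(axis=1) * (Y * Y).sum(axis=1))
    return np.clip(_safe_div(num, den), -1.0, 1.0)


def _angular_distance(X, Y, ctx):
    return np.arccos(_cosine(X, Y, ctx)) / math.pi


def _orloci(X, Y, ctx):
    return np.sqrt(np.maximum(2.0 * (1.0 - _cosine(X, Y, ctx)), 0.0))


def _extended_dice(X, Y, ctx):
    num = 2.0 * (X * Y).sum(axis=1)
    return _safe_div(num, (X * X).sum(axis=1) + (Y * Y).sum(axis=1))


def _kohonen(X, Y, ctx):
    # Tanimoto-type scaling of the pairwise-product numerator
    sxy = (X * Y).sum(axis=1)
    return _safe_div(sxy, (X * X).sum(axis=1) + (Y * Y).sum(axis=1) - sxy)


def _cohen_rc(X, Y, ctx):
    mid = _need(ctx, "midpoints", "cohen_rc")
    return _cosine(X - mid, Y - mid, ctx)


# ---------------------------------------------------------------------------
# Group 6: McCrae's profile-agreement measures (on z-scored profiles)

def _mccrae_z(X, Y, ctx, which):
    means = _need(ctx, "means", which)
    sds = _need(ctx, "sds", which)
    return (X - means) / sds, (Y - means) / sds


def _mccrae_index(X, Y, ctx):
    zx, zy = _mccrae_z(X, Y, ctx, "mccrae_index")
    k = X.shape[1]
    M2 = (((zx + zy) / 2.0) ** 2).sum(axis=1)
    D2 = ((zx - zy) ** 2).sum(axis=1)
    return (k + 2.0 * M2 - D2 / 2.0) / k


def _mccrae_coefficient(X, Y, ctx):
    ipa = _mccrae_index(X, Y, ctx)
    return ipa / np.sqrt(1.0 + ipa * ipa)


# ---------------------------------------------------------------------------
# Excluded exemplars

def _canberra(X, Y, ctx, policy: str = "strict"):
    num = np.abs(X - Y)
    den = np.abs(X) + np.abs(Y)
    if policy == "strict":
        # any 0/0 term poisons the whole value (reproduces the high NA
        # counts observed on zero-inflated rating data)
        terms = _safe_div(num, den)
        return terms.sum(axis=1)
    elif policy == "skip":
        terms = np.zeros_like(num)
        np.divide(num, den, out=terms, where=den != 0)
        return terms.sum(axis=1)
    raise ValueError(f"unknown canberra policy {policy!r}")


def _bray_curtis_dist(X, Y, ctx):
    return _safe_div(np.abs(X - Y).sum(axis=1), X.sum(axis=1) + Y.sum(axis=1))


def _czekanowski_dist(X, Y, ctx):
    # numerically identical to the Bray-Curtis distance on every input
    return _bray_curtis_dist(X, Y, ctx)


# ---------------------------------------------------------------------------
# registry and public API

_Batch = Callable[[np.ndarray, np.ndarray, Optional[MeasureContext]], np.ndarray]

REGISTRY: dict[str, _Batch] = {
    "manhattan": _manhattan,
    "euclidean": _euclidean,
    "squared_euclidean": _squared_euclidean,
    "chebyshev": _chebyshev,
    "avg_l1_linf": _avg_l1_linf,
    "mean_character": _mean_character,
    "lorentzian": _lorentzian,
    "gower": _gower,
    "scaled_euclidean": _scaled_euclidean,
    "half_range_standardized": _half_range_standardized,
    "max_scaled_difference": _max_scaled_difference,
    "mean_censored_euclidean": _mean_censored_euclidean,
    "penrose_size": _penrose_size,
    "penrose_shape": _penrose_shape,
    "burrows_delta": _burrows_delta,
    "cattell_rp": _cattell_rp,
    "bray_curtis_sim": _bray_curtis_sim,
    "intersection_sim": _intersection_sim,
    "morisita": _morisita,
    "morisita_horn": _morisita_horn,
    "motyka": _motyka,
    "ruzicka": _ruzicka,
    "soergel": _soergel,
    "dcor": _dcor,
    "dcov": _dcov,
    "tau_star": _tau_star,
    "gamma": _gamma,
    "kendall_tau_b": _kendall_tau_b,
    "kendall_cov": _kendall_cov,
    "spearman_corr": _spearman_corr,
    "spearman_cov": _spearman_cov,
    "cosine": _cosine,
    "angular_distance": _angular_distance,
    "orloci": _orloci,
    "cohen_rc": _cohen_rc,
    "extended_dice": _extended_dice,
    "kohonen": _kohonen,
    "mccrae_coefficient": _mccrae_coefficient,
    "mccrae_index": _mccrae_index,
    "pearson_corr": _pearson_corr,
    "pearson_cov": _pearson_cov,
    "icc_double_entry": _icc_double_entry,
    "inner_product": _inner_product,
    "bray_curtis_dist": _bray_curtis_dist,
    "czekanowski_dist": _czekanowski_dist,
    "canberra": _canberra,
}

_CTX_FIELD = {"ranges": "ranges", "standardization": "sds",
              "midpoints": "midpoints", "cattell_k": "cattell_k"}


def _check_context(definition: MeasureDefinition, ctx: Optional[MeasureContext]):
    for req in definition.requires_context:
        field = _CTX_FIELD[req]
        if ctx is None or getattr(ctx, field) is None:
            raise ValueError(
                f"measure {definition.id!r} requires context field {req!r}")
        if req == "standardization" and ctx.means is None:
            raise ValueError(
                f"measure {definition.id!r} requires standardization means")


def evaluate_batch(measure: str | MeasureDefinition, X: np.ndarray,
                   Y: np.ndarray, ctx: Optional[MeasureContext] = None
                   ) -> np.ndarray:
    """Evaluate one measure on ``n`` pairs stacked as ``(n, p)`` arrays."""
    definition = measure if isinstance(measure, MeasureDefinition) \
        else get_definition(measure)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or X.shape != Y.shape:
        raise ValueError("X and Y must be matching (n, p) arrays")
    if X.shape[1] < 2:
        raise ValueError("profiles need at least 2 variables")
    _check_context(definition, ctx)
    with np.errstate(all="ignore"):
        return np.asarray(REGISTRY[definition.id](X, Y, ctx), dtype=float)


def evaluate_measure(measure: str | MeasureDefinition, pair: ProfilePair,
                     ctx: Optional[MeasureContext] = None) -> float:
    """Evaluate one measure on one pair; NaN marks a data degeneracy."""
    return float(evaluate_batch(measure, pair.x[None, :], pair.y[None, :],
                                ctx)[0])


def compute_values_table(pairs, measure_ids: Iterable[str],
                         ctx: Optional[MeasureContext] = None,
                         dataset_id: Optional[str] = None) -> pd.DataFrame:
    """Observations x measures table for a set of pairs.

    ``pairs`` is any object exposing ``X``/``Y`` ``(n, p)`` arrays plus
    ``pair_ids`` and ``group_ids`` sequences (see
    :class:`profilesim.preprocessing.PairSet`).  The result is a DataFrame
    indexed by (dataset_id, group_id, pair_id) with one column per measure;
    NaN entries are missing markers.
    """
    measure_ids = list(measure_ids)
    did = dataset_id if dataset_id is not None \
        else getattr(pairs, "dataset_id", "data")
    idx = pd.MultiIndex.from_arrays(
        [np.repeat(did, len(pairs.pair_ids)),
         np.asarray(pairs.group_ids), np.asarray(pairs.pair_ids)],
        names=["dataset_id", "group_id", "pair_id"])
    cols = {}
    for mid in measure_ids:
        cols[mid] = evaluate_batch(mid, pairs.X, pairs.Y, ctx)
    return pd.DataFrame(cols, index=idx)
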