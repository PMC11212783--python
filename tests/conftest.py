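"""Shared fixtures: random profile pairs, small datasets, and one full
pipeline run on the default synthetic suite (session-scoped, reused by the
screening and clustering acceptance checks)."""

import warnings

import numpy as np
import pandas as pd
import pytest

import profilesim as ps

SUITE_SEED = 1


@pytest.fixture(scope="session")
def full_result() -> ps.pipeline.PipelineResult:
    """One pipeline run over the five default synthetic datasets."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ps.run_pipeline(ps.PipelineConfig(seed=SUITE_SEED))


def make_random_pairs(n: int, p: int, seed: int, nonnegative: bool = False):
    """(X, Y) arrays of random profile pairs; mixed-sign by default."""
    rng = np.random.default_rng(seed)
    if nonnegative:
        X = rng.uniform(0.0, 6.0, size=(n, p))
        Y = rng.uniform(0.0, 6.0, size=(n, p))
    else:
        X = rng.normal(0.0, 2.0, size=(n, p))
        Y = rng.normal(0.0, 2.0, size=(n, p))
    return X, Y


def make_context(X, Y, cattell_k=None) -> ps.MeasureContext:
    """Context whose ranges/standardization cover the probe pairs and whose
    midpoints are deliberately nonzero."""
    stacked = np.vstack([X, Y])
    mid = stacked.mean(axis=0) + 0.5
    return ps.MeasureContext.from_values(stacked, midpoints=mid,
                                         cattell_k=cattell_k)


@pytest.fixture()
def dyadic_frame() -> pd.DataFrame:
    """Tiny two-couple longitudinal dataset with a partly missing occasion."""
    rows = []
    for g, base in (("g1", 10.0), ("g2", 20.0)):
        for role in ("A", "B"):
            for t in (1, 2, 3):
                rows.append((g, f"{g}{role}", role, t,
                             base + t, base + 2 * t))
    df = pd.DataFrame(rows, columns=["group_id", "person_id", "role",
                                     "occasion_id", "v1", "v2"])
    # couple g2 misses role B at occasion 3
    return df[~((df.group_id == "g2") & (df.role == "B")
                & (df.occasion_id == 3))].reset_index(drop=True)


@pytest.fixture()
def dyadic_dataset(dyadic_frame) -> ps.LongDataset:
    return ps.LongDataset("toy", "esm_like", dyadic_frame, ["v1", "v2"],
                          scale=(0.0, 100.0),
                          default_centering=ps.CenteringSpec("person_mean"))


@pytest.fixture()
def culture_frame() -> pd.DataFrame:
    rows = []
    for g, shift in (("c1", 0.0), ("c2", 2.0)):
        for m in range(3):
            rows.append((g, f"{g}m{m}", "member", 1,
                         1.0 + m + shift, 4.0 - m + shift))
    return pd.DataFrame(rows, columns=["group_id", "person_id", "role",
                                       "occasion_id", "v1", "v2"])


@pytest.fixture()
def culture_dataset(culture_frame) -> ps.LongDataset:
    return ps.LongDataset("cult", "culture_like", culture_frame,
                          ["v1", "v2"], scale=(1.0, 9.0),
                          default_centering=ps.CenteringSpec("grand_mean"))
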