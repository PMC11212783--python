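"""Centering post-conditions, idempotence, and pairing logic."""

import numpy as np
import pandas as pd
import pytest

import profilesim as ps


def test_person_mean_centering_two_occasions():
    df = pd.DataFrame({
        "group_id": ["g1"] * 4, "person_id": ["p1", "p1", "p2", "p2"],
        "role": ["A", "A", "B", "B"], "occasion_id": [1, 2, 1, 2],
        "v1": [10.0, 20.0, 5.0, 7.0], "v2": [0.0, 4.0, 1.0, 1.0]})
    ds = ps.LongDataset("t", "esm_like", df, ["v1", "v2"], (0.0, 100.0))
    out = ps.center(ds, ps.CenteringSpec("person_mean"))
    p1 = out.frame[out.frame.person_id == "p1"]
    assert list(p1.v1) == [-5.0, 5.0]
    # every (person, variable) mean is zero afterwards
    means = out.frame.groupby("person_id")[["v1", "v2"]].mean()
    assert np.allclose(means.to_numpy(), 0.0, atol=1e-10)


def test_person_mean_requires_longitudinal_design():
    df = pd.DataFrame({
        "group_id": ["g1", "g1"], "person_id": ["p1", "p2"],
        "role": ["A", "B"], "occasion_id": [1, 1],
        "v1": [1.0, 2.0], "v2": [3.0, 4.0]})
    ds = ps.LongDataset("t", "lab_like", df, ["v1", "v2"], (1.0, 7.0))
    with pytest.raises(ValueError):
        ps.center(ds, ps.CenteringSpec("person_mean"))


def test_variable_mean_by_role_centering(dyadic_dataset):
    out = ps.center(dyadic_dataset, ps.CenteringSpec("variable_mean_by_role"))
    means = out.frame.groupby("role")[["v1", "v2"]].mean()
    assert np.allclose(means.to_numpy(), 0.0, atol=1e-10)


def test_grand_mean_centering_preserves_culture_differences(culture_dataset):
    raw_means = culture_dataset.frame.groupby("group_id")[["v1", "v2"]].mean()
    out = ps.center(culture_dataset, ps.CenteringSpec("grand_mean"))
    cen_means = out.frame.groupby("group_id")[["v1", "v2"]].mean()
    assert np.allclose(out.frame[["v1", "v2"]].mean().to_numpy(), 0.0,
                       atol=1e-10)
    raw_diff = raw_means.loc["c2"] - raw_means.loc["c1"]
    cen_diff = cen_means.loc["c2"] - cen_means.loc["c1"]
    assert np.allclose(raw_diff.to_numpy(), cen_diff.to_numpy(), atol=1e-12)
    assert raw_diff["v1"] == pytest.approx(2.0)


def test_grand_mean_simple_example():
    df = pd.DataFrame({
        "group_id": ["c1"] * 3, "person_id": ["p1", "p2", "p3"],
        "role": ["member"] * 3, "occasion_id": [1, 1, 1],
        "v1": [1.0, 2.0, 3.0]})
    ds = ps.LongDataset("t", "culture_like", df, ["v1"], (1.0, 9.0))
    out = ps.center(ds, ps.CenteringSpec("grand_mean"))
    assert list(out.frame.v1) == [-1.0, 0.0, 1.0]


def test_centering_is_idempotent(dyadic_dataset, culture_dataset):
    for ds, mode in ((dyadic_dataset, "person_mean"),
                     (dyadic_dataset, "variable_mean_by_role"),
                     (culture_dataset, "grand_mean")):
        spec = ps.CenteringSpec(mode)
        once = ps.center(ds, spec)
        twice = ps.center(once, spec)
        np.testing.assert_allclose(
            once.frame[ds.variables].to_numpy(),
            twice.frame[ds.variables].to_numpy(), atol=1e-10)


def test_single_observation_cell_centers_to_zero():
    df = pd.DataFrame({
        "group_id": ["g1"] * 3, "person_id": ["p1", "p1", "p2"],
        "role": ["A", "A", "B"], "occasion_id": [1, 2, 1],
        "v1": [3.0, 5.0, 9.0]})
    ds = ps.LongDataset("t", "esm_like", df, ["v1"], (0.0, 10.0))
    out = ps.center(ds, ps.CenteringSpec("person_mean"))
    assert out.frame.loc[out.frame.person_id == "p2", "v1"].iloc[0] == 0.0


def test_missing_values_stay_missing_and_are_excluded_from_means():
    df = pd.DataFrame({
        "group_id": ["g1"] * 3, "person_id": ["p1"] * 3,
        "role": ["A"] * 3, "occasion_id": [1, 2, 3],
        "v1": [2.0, np.nan, 4.0]})
    ds = ps.LongDataset("t", "esm_like", df, ["v1"], (0.0, 10.0))
    out = ps.center(ds, ps.CenteringSpec("person_mean"))
    assert list(out.frame.v1)[0] == -1.0
    assert np.isnan(list(out.frame.v1)[1])


def test_cultural_norms_aggregation(culture_dataset):
    norms = ps.cultural_norms(culture_dataset)
    # culture c1 members score 1,2,3 on v1 -> norm 2
    assert norms.loc["c1", "v1"] == pytest.approx(2.0)
    # single-member culture: norm equals the member's profile
    one = culture_dataset.frame[culture_dataset.frame.person_id == "c1m0"]
    solo = ps.LongDataset("t", "culture_like", one, ["v1", "v2"], (1.0, 9.0))
    solo_norms = ps.cultural_norms(solo)
    assert solo_norms.loc["c1", "v1"] == one.v1.iloc[0]


def test_norms_commute_with_grand_mean_centering(culture_dataset):
    """Norm of centered data equals centered norm of raw data (linearity)."""
    raw_norms = ps.cultural_norms(culture_dataset)
    centered = ps.center(culture_dataset, ps.CenteringSpec("grand_mean"))
    cen_norms = ps.cultural_norms(centered)
    shift = culture_dataset.frame[["v1", "v2"]].mean()
    np.testing.assert_allclose((raw_norms - shift).to_numpy(),
                               cen_norms.to_numpy(), atol=1e-12)


def test_make_pairs_joint_occasions_only(dyadic_dataset):
    pairs = ps.make_pairs(dyadic_dataset)
    # g1 has 3 joint occasions, g2 only 2 (B missing at occasion 3)
    assert len(pairs) == 5
    assert sorted(pairs.pair_ids) == ["g1:1", "g1:2", "g1:3", "g2:1", "g2:2"]
    # x carries role A, y role B
    first = next(pairs.to_tuples())
    assert first[1] == "g1"


def test_pair_conservation_under_centering(dyadic_dataset):
    raw_pairs = ps.make_pairs(dyadic_dataset)
    centered = ps.center(dyadic_dataset, ps.CenteringSpec("person_mean"))
    cen_pairs = ps.make_pairs(centered)
    assert len(raw_pairs) == len(cen_pairs)
    assert list(raw_pairs.pair_ids) == list(cen_pairs.pair_ids)


def test_make_pairs_culture(culture_dataset):
    norms = ps.cultural_norms(culture_dataset)
    pairs = ps.make_pairs(culture_dataset, norms)
    assert len(pairs) == len(culture_dataset.frame)
    # y vectors are the norm of the member's own culture
    for pid, gid, pair in pairs.to_tuples():
        np.testing.assert_allclose(pair.y,
                                   norms.loc[gid].to_numpy(dtype=float))


def test_make_pairs_drops_incomplete_profiles(dyadic_dataset):
    df = dyadic_dataset.frame.copy()
    df.loc[(df.group_id == "g1") & (df.occasion_id == 1)
           & (df.role == "A"), "v1"] = np.nan
    ds = ps.LongDataset("t", "esm_like", df, ["v1", "v2"], (0.0, 100.0))
    assert len(ps.make_pairs(ds)) == 4


def test_long_dataset_roundtrip(tmp_path, dyadic_dataset):
    from profilesim.io import read_long_dataset, write_long_dataset
    path = tmp_path / "toy.csv"
    write_long_dataset(dyadic_dataset, path)
    back = read_long_dataset(path)
    assert back.dataset_id == dyadic_dataset.dataset_id
    assert back.design == dyadic_dataset.design
    assert back.variables == dyadic_dataset.variables
    np.testing.assert_allclose(back.values(), dyadic_dataset.values())


def test_values_table_roundtrip(tmp_path, dyadic_dataset):
    from profilesim.io import read_values_table, write_values_table
    pairs = ps.make_pairs(dyadic_dataset)
    tab = ps.compute_values_table(pairs, ["manhattan", "euclidean"])
    path = tmp_path / "values.csv"
    write_values_table(tab, path)
    back = read_values_table(path)
    np.testing.assert_allclose(back[tab.columns].to_numpy(), tab.to_numpy())
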