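"""Counting, median-of-ratios normalization, rankings and fold changes."""

import numpy as np
import pandas as pd
import pytest

from mirmod.quantify import (
    normalize,
    pairwise_table,
    plain_counts,
    size_factors,
    top_expressed,
    total_counts,
)


def test_plain_counts_sums_depths():
    counts = plain_counts(
        [("m1", "s1", 3.0), ("m1", "s1", 5.0)], ["s1", "s2"], ["m1", "m2"]
    )
    assert counts.loc["m1", "s1"] == 8.0
    assert counts.loc["m2", "s2"] == 0.0


def test_plain_counts_fractional_split():
    counts = plain_counts(
        [("m1", "s1", 3.0), ("m2", "s1", 3.0)], ["s1"], ["m1", "m2"]
    )
    assert counts["s1"].tolist() == [3.0, 3.0]
    assert counts["s1"].sum() == 6.0


def test_size_factors_identical_columns_are_unity():
    counts = pd.DataFrame({"s1": [10.0, 5.0, 2.0], "s2": [10.0, 5.0, 2.0]})
    assert np.allclose(size_factors(counts), [1.0, 1.0])


def test_size_factors_doubled_column_ratio_is_two():
    counts = pd.DataFrame({"s1": [10.0, 5.0, 2.0], "s2": [20.0, 10.0, 4.0]})
    f = size_factors(counts)
    # closed form: geometric row means give factors (1/sqrt(2), sqrt(2))
    assert np.allclose(f, [2 ** -0.5, 2 ** 0.5])
    assert f["s2"] / f["s1"] == pytest.approx(2.0)


def test_size_factors_single_positive_row_closed_form():
    counts = pd.DataFrame({"s1": [4.0, 0.0], "s2": [9.0, 7.0]})
    f = size_factors(counts)
    assert np.allclose(f, [4 / 6, 9 / 6])  # gm(4, 9) = 6


def test_size_factors_require_an_all_positive_row():
    counts = pd.DataFrame({"s1": [4.0, 0.0], "s2": [0.0, 7.0]})
    with pytest.raises(ValueError, match="pseudocount"):
        size_factors(counts)
    f = size_factors(counts, pseudocount=1.0)
    assert (f > 0).all()


def test_size_factors_need_two_samples():
    with pytest.raises(ValueError):
        size_factors(pd.DataFrame({"s1": [4.0]}))


def test_normalization_is_idempotent():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(1, 500, size=(40, 3)).astype(float),
        columns=["s1", "s2", "s3"],
    )
    norm = normalize(counts)
    assert np.allclose(size_factors(norm), 1.0, atol=1e-9)


def test_size_factors_match_deseq2_reference_implementation():
    """Cross-check against pydeseq2's median-of-ratios estimator."""
    pydeseq2 = pytest.importorskip("pydeseq2.dds")
    rng = np.random.default_rng(1)
    base = rng.lognormal(3, 1.5, size=60)
    depth = np.array([1.0, 2.5, 0.6, 1.4])
    counts = pd.DataFrame(
        rng.poisson(np.outer(depth, base)).astype(np.int64),
        index=[f"s{i}" for i in range(4)],
        columns=[f"g{j}" for j in range(60)],
    )
    meta = pd.DataFrame(index=counts.index, data={"condition": ["a", "a", "b", "b"]})
    dds = pydeseq2.DeseqDataSet(counts=counts, metadata=meta, design="~condition", quiet=True)
    dds.fit_size_factors()
    expected = dds.obs["size_factors"].to_numpy(dtype=float)
    expected = expected / np.exp(np.mean(np.log(expected)))  # common scale
    mine = size_factors(counts.T.astype(float)).to_numpy()
    assert np.allclose(mine, expected, rtol=1e-8)


def test_top_expressed_ranking_and_tie_break():
    norm = pd.DataFrame(
        {"s1": [5.0, 5.0, 1.0], "s2": [5.0, 5.0, 9.0]},
        index=["miR-b", "miR-a", "miR-c"],
    )
    table = top_expressed(norm, ["s1"], ["s2"], n=10)
    assert len(table) == 3  # n exceeds the universe
    assert table.index.tolist() == ["miR-a", "miR-b", "miR-c"]  # tie -> lexicographic
    assert table.loc["miR-c", "mean_a"] == 1.0
    assert table.loc["miR-c", "mean_b"] == 9.0
    assert table.loc["miR-c", "mean_overall"] == 5.0


def test_top_expressed_validates_inputs():
    norm = pd.DataFrame({"s1": [1.0]}, index=["m1"])
    with pytest.raises(KeyError):
        top_expressed(norm, ["s1"], ["nope"], n=10)
    with pytest.raises(ValueError):
        top_expressed(norm, ["s1"], ["s1"], n=7)


def test_pairwise_fold_changes():
    norm = pd.DataFrame({"s1": [3.0, 4.0], "s2": [3.0, 4.0]}, index=["m1", "m2"])
    table = pairwise_table(norm, ["s1"], ["s2"])
    assert (table["log2fc"] == 0.0).all()
    big = pd.DataFrame({"s1": [3000.0], "s2": [1000.0]}, index=["m1"])
    lfc = pairwise_table(big, ["s1"], ["s2"], pseudo=1e-9)["log2fc"].iloc[0]
    assert lfc == pytest.approx(np.log2(3.0), abs=1e-5)


def test_pairwise_swap_negates_and_overlap_errors():
    rng = np.random.default_rng(2)
    norm = pd.DataFrame(
        rng.integers(0, 50, size=(10, 4)).astype(float),
        index=[f"m{i}" for i in range(10)],
        columns=["a1", "a2", "b1", "b2"],
    )
    fwd = pairwise_table(norm, ["a1", "a2"], ["b1", "b2"]).sort_index()
    rev = pairwise_table(norm, ["b1", "b2"], ["a1", "a2"]).sort_index()
    assert np.allclose(fwd["log2fc"], -rev["log2fc"])
    with pytest.raises(ValueError, match="overlap"):
        pairwise_table(norm, ["a1"], ["a1", "b1"])


def test_total_counts_matches_column_sums():
    counts = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]})
    assert total_counts(counts).tolist() == [3.0, 7.0]
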