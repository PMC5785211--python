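import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clocklight import expression as ex


def _em(values, conditions, times, lengths=None, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    cols = pd.MultiIndex.from_tuples(
        list(zip(conditions, times)), names=["condition", "time_h"]
    )
    frame = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=cols)
    lengths_s = pd.Series(lengths, index=genes) if lengths is not None else None
    return ex.ExpressionMatrix(frame, lengths_s)


# ---------------------------------------------------------------------------
# normalize_counts


def test_normalize_counts_equalizes_proportional_samples():
    em = _em([[10, 20], [20, 40], [30, 60]], ["c", "c"], [0.0, 2.0], lengths=[100, 200, 300])
    out = ex.normalize_counts(em).values
    # sample medians 20 and 40; grand median 30 -> both samples scale to
    # counts [15, 30, 45], then /length gives 0.15 per nucleotide.
    np.testing.assert_allclose(out.to_numpy(), 0.15)


def test_normalize_counts_identity_up_to_length_division():
    em = _em([[4, 4], [10, 10]], ["c", "c"], [0.0, 2.0], lengths=[2, 5])
    out = ex.normalize_counts(em).values
    np.testing.assert_allclose(out.to_numpy(), [[2.0, 2.0], [2.0, 2.0]])


def test_normalize_counts_invariant_to_per_sample_scaling():
    """Per-sample scale factors cancel: outputs agree up to one global
    constant (the grand-median target itself), so relative expression is
    exactly invariant."""
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 500, size=(30, 4)).astype(float)
    lengths = rng.integers(100, 2000, size=30)
    times = [0.0, 2.0, 4.0, 6.0]
    base = _em(counts, ["c"] * 4, times, lengths=lengths)
    scaled_counts = counts * np.array([1.0, 3.0, 0.5, 2.0])
    scaled = _em(scaled_counts, ["c"] * 4, times, lengths=lengths)
    out1 = ex.normalize_counts(base).values.to_numpy()
    out2 = ex.normalize_counts(scaled).values.to_numpy()
    ratio = out2 / out1
    np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-12)
    np.testing.assert_allclose(
        ex.log2_relative_expression(ex.normalize_counts(base), "c", pseudocount=0.0).to_numpy(),
        ex.log2_relative_expression(ex.normalize_counts(scaled), "c", pseudocount=0.0).to_numpy(),
        atol=1e-12,
    )


def test_normalize_counts_rejects_all_zero_sample():
    em = _em([[1, 0], [2, 0]], ["c", "c"], [0.0, 2.0], lengths=[10, 10])
    with pytest.raises(ValueError, match="all-zero"):
        ex.normalize_counts(em)


# ---------------------------------------------------------------------------
# log2 relative expression


def test_log2_relative_constant_gene_is_zero():
    em = _em([[3, 3, 3]], ["ref", "ref", "test"], [0.0, 2.0, 0.0])
    out = ex.log2_relative_expression(em, "ref", pseudocount=0.0)
    np.testing.assert_allclose(out.to_numpy(), 0.0)


def test_log2_relative_power_of_two():
    em = _em([[2, 2, 8]], ["ref", "ref", "test"], [0.0, 2.0, 0.0])
    out = ex.log2_relative_expression(em, "ref", pseudocount=0.0)
    assert out[("test", 0.0)].iloc[0] == pytest.approx(2.0)


def test_log2_relative_reference_mean():
    em = _em([[1, 3, 8]], ["ref", "ref", "test"], [0.0, 2.0, 0.0])
    out = ex.log2_relative_expression(em, "ref", pseudocount=0.0)
    assert out[("test", 0.0)].iloc[0] == pytest.approx(2.0)  # log2(8/2)


def test_log2_relative_missing_reference_raises():
    em = _em([[1, 2]], ["a", "a"], [0.0, 2.0])
    with pytest.raises(ValueError, match="ref"):
        ex.log2_relative_expression(em, "ref")


# ---------------------------------------------------------------------------
# cosinor


def test_cosinor_recovers_exact_cosine():
    t = np.arange(12.0)
    y = 2.0 + 0.5 * np.cos(2 * np.pi * (t - 6.0) / 24.0)
    fit = ex.cosinor_fit(t, y)
    assert fit.mesor == pytest.approx(2.0)
    assert fit.amplitude == pytest.approx(0.5)
    assert fit.acrophase_deg == pytest.approx(90.0)


def test_cosinor_flat_series_has_zero_amplitude():
    fit = ex.cosinor_fit(np.arange(8.0), np.full(8, 3.0))
    assert fit.amplitude == pytest.approx(0.0, abs=1e-12)


def test_cosinor_requires_three_distinct_times():
    with pytest.raises(ValueError):
        ex.cosinor_fit([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        ex.cosinor_fit([0.0, 1.0], [1.0, 2.0])


def test_cosinor_noisy_fit_matches_dense_grid_search_oracle():
    """LS fit within 2% of a brute-force (amplitude, phase) SSE grid search."""
    rng = np.random.default_rng(42)
    t = np.arange(0.0, 24.0, 2.0)
    true = 1.0 + 0.4 * np.cos(2 * np.pi * t / 24.0 - np.deg2rad(250.0))
    y = true + rng.normal(0.0, 0.05, t.size)
    fit = ex.cosinor_fit(t, y)

    amps = np.linspace(0.0, 1.0, 2001)
    phases = np.deg2rad(np.arange(0.0, 360.0, 0.25))
    best = (np.inf, None, None)
    for phi in phases:
        basis = np.cos(2 * np.pi * t / 24.0 - phi)
        for a in amps:
            resid = y - (y.mean() + a * basis)
            sse = float(resid @ resid)
            if sse < best[0]:
                best = (sse, a, phi)
    _, amp_star, phi_star = best
    assert fit.amplitude == pytest.approx(amp_star, rel=0.02)
    assert fit.acrophase_deg == pytest.approx(np.degrees(phi_star), abs=0.02 * 360)


def test_cosinor_invariant_to_24h_time_shift():
    rng = np.random.default_rng(3)
    t = np.arange(0.0, 24.0, 3.0)
    y = rng.normal(1.0, 0.3, t.size)
    a = ex.cosinor_fit(t, y)
    b = ex.cosinor_fit(t + 48.0, y)
    assert a.amplitude == pytest.approx(b.amplitude)
    assert a.acrophase_deg == pytest.approx(b.acrophase_deg)


def test_cosinor_frame_matches_per_series_fit():
    rng = np.random.default_rng(9)
    t = np.arange(0.0, 24.0, 2.0)
    data = rng.normal(1.0, 0.5, (5, t.size))
    frame = pd.DataFrame(data, columns=pd.Index(t, name="time_h"))
    fits = ex.cosinor_fit_frame(frame)
    for i in range(5):
        single = ex.cosinor_fit(t, data[i])
        assert fits["amplitude"].iloc[i] == pytest.approx(single.amplitude)
        assert fits["acrophase_deg"].iloc[i] == pytest.approx(single.acrophase_deg)


# ---------------------------------------------------------------------------
# classification


def _classify_one(amplitude, acrophase, max_expr=2.0):
    fits = pd.DataFrame(
        {"amplitude": [amplitude], "acrophase_deg": [acrophase]}, index=["g0"]
    )
    em = _em([[max_expr, 0.1]], ["c", "c"], [0.0, 2.0], genes=["g0"])
    return ex.classify_circadian(fits, em).iloc[0]


@pytest.mark.parametrize(
    "amplitude,acrophase,expected",
    [
        (0.2, 100.0, "dawn"),
        (0.2, 250.0, "dusk"),
        (0.2, 39.0, "dusk"),  # inclusive dusk boundary
        (0.2, 40.0, "dawn"),  # inclusive dawn boundary
        (0.2, 189.0, "dawn"),
        (0.2, 190.0, "dusk"),
        (0.10, 100.0, "non_circadian"),  # below amplitude threshold
        (0.15, 100.0, "non_circadian"),  # threshold is strict
    ],
)
def test_classification_windows_and_threshold(amplitude, acrophase, expected):
    assert _classify_one(amplitude, acrophase)["label"] == expected


def test_classification_expression_filter_gates_labels():
    row = _classify_one(0.5, 100.0, max_expr=0.5)
    assert not row["passed_expression_filter"]
    assert row["label"] == "non_circadian"


def test_classification_missing_gene_raises():
    fits = pd.DataFrame({"amplitude": [0.2], "acrophase_deg": [100.0]}, index=["absent"])
    em = _em([[2.0, 2.0]], ["c", "c"], [0.0, 2.0], genes=["g0"])
    with pytest.raises(ValueError, match="absent"):
        ex.classify_circadian(fits, em)


def test_classification_is_a_partition(gene_counts_dataset):
    counts = gene_counts_dataset["counts"].astype(float)
    em = ex.normalize_counts(ex.ExpressionMatrix(counts, gene_counts_dataset["lengths"]))
    cond = em.conditions[0]
    fits = ex.cosinor_fit_frame(ex.log2_relative_expression(em, cond)[cond])
    labels = ex.classify_circadian(fits, em)["label"]
    assert set(labels.unique()) <= {"dawn", "dusk", "non_circadian"}
    assert labels.notna().all()


# ---------------------------------------------------------------------------
# z-score blocks, k-means, naming, scaling


def test_zscore_block_centers_and_scales_each_block():
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0, 10.0, 20.0, 30.0]],
        index=["g0"],
        columns=["a1", "a2", "a3", "b1", "b2", "b3"],
    )
    out, dropped = ex.zscore_block_normalize(
        frame, {"a": ["a1", "a2", "a3"], "b": ["b1", "b2", "b3"]}
    )
    np.testing.assert_allclose(out.loc["g0", ["a1", "a2", "a3"]], [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(out.loc["g0", ["b1", "b2", "b3"]], [-1.0, 0.0, 1.0])
    assert dropped == []


def test_zscore_block_invariant_to_block_scaling():
    rng = np.random.default_rng(1)
    base = pd.DataFrame(rng.normal(size=(6, 6)), columns=list("abcdef"))
    blocks = {"x": list("abc"), "y": list("def")}
    scaled = base.copy()
    scaled[list("abc")] *= 7.0
    scaled[list("def")] *= 0.2
    out1, _ = ex.zscore_block_normalize(base, blocks)
    out2, _ = ex.zscore_block_normalize(scaled, blocks)
    np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-12)


def test_zscore_block_drops_zero_variance_gene():
    frame = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"], columns=list("abc"))
    out, dropped = ex.zscore_block_normalize(frame, {"a": list("abc")})
    assert dropped == ["flat"]
    assert list(out.index) == ["ok"]


def test_kmeans_k1_puts_everything_together():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(rng.normal(size=(10, 6)))
    km = ex.kmeans_correlation(frame, k=1, n_restarts=3, seed=0)
    assert set(km.assignments) == {1}


def test_kmeans_identical_rows_share_a_cluster():
    rng = np.random.default_rng(0)
    base = rng.normal(size=6)
    frame = pd.DataFrame(
        np.vstack([base, base, rng.normal(size=6), -base]),
        index=["a", "b", "c", "d"],
    )
    km = ex.kmeans_correlation(frame, k=2, n_restarts=10, seed=1)
    assert km.assignments["a"] == km.assignments["b"]


def test_kmeans_recovers_planted_groups_and_is_affine_invariant():
    from sklearn.metrics import adjusted_rand_score

    from clocklight.synth import make_cluster_profiles

    profiles, planted = make_cluster_profiles(60, 3, noise_sd=0.1, seed=5)
    km = ex.kmeans_correlation(profiles, k=3, n_restarts=20, seed=5)
    assert adjusted_rand_score(planted, km.assignments) >= 0.95

    # row-wise positive affine transform leaves correlation distances alone
    rng = np.random.default_rng(2)
    gains = rng.uniform(0.5, 3.0, len(profiles))
    offsets = rng.uniform(-5.0, 5.0, len(profiles))
    transformed = profiles.mul(gains, axis=0).add(offsets, axis=0)
    km2 = ex.kmeans_correlation(transformed, k=3, n_restarts=20, seed=5)
    assert adjusted_rand_score(km.assignments, km2.assignments) == pytest.approx(1.0)


def test_kmeans_rejects_k_larger_than_genes():
    frame = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)))
    with pytest.raises(ValueError):
        ex.kmeans_correlation(frame, k=5)


def test_kmeans_deterministic_under_seed():
    rng = np.random.default_rng(4)
    frame = pd.DataFrame(rng.normal(size=(30, 8)))
    a = ex.kmeans_correlation(frame, k=4, n_restarts=5, seed=11)
    b = ex.kmeans_correlation(frame, k=4, n_restarts=5, seed=11)
    pd.testing.assert_series_equal(a.assignments, b.assignments)


def test_cluster_naming_by_activation_order():
    assignments = pd.Series([1] * 5 + [2] * 4 + [3] * 3 + [4] * 1, name="cluster_index")
    t = np.array([0.0, 4.0, 8.0, 12.0])
    means = {
        1: (t, np.array([0.0, 0.3, 0.6, 1.0])),  # crosses ~5.3 h
        2: (t, np.array([0.0, 0.6, 0.9, 1.0])),  # crosses ~2.7 h
        3: (t, np.array([0.0, 0.1, 0.3, 1.0])),  # crosses ~10 h
        4: (t, np.array([0.0, 1.0, 1.0, 1.0])),
    }
    names = ex.name_clusters_by_activation(assignments, means)
    assert names[2] == "Early" and names[1] == "Middle" and names[3] == "Late"
    assert names[4] == "other"


def test_cluster_naming_with_only_two_clusters():
    assignments = pd.Series([1] * 3 + [2] * 2)
    t = np.array([0.0, 6.0, 12.0])
    means = {1: (t, np.array([0.0, 1.0, 1.0])), 2: (t, np.array([0.0, 0.0, 1.0]))}
    names = ex.name_clusters_by_activation(assignments, means)
    assert set(names) == {"Early", "Middle"}


def test_scale_unit_interval_examples_and_idempotence():
    np.testing.assert_allclose(ex.scale_unit_interval(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0])
    scaled = ex.scale_unit_interval({"a": np.array([1.0, 2.0]), "b": np.array([3.0, 5.0])})
    assert scaled["a"][0] == 0.0 and scaled["b"][1] == 1.0
    once = ex.scale_unit_interval(np.array([0.1, 0.7, 0.3, 1.0, 0.0]))
    np.testing.assert_allclose(ex.scale_unit_interval(once), once)
    with pytest.raises(ValueError):
        ex.scale_unit_interval(np.array([2.0, 2.0]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=3, max_size=20))
def test_scale_unit_interval_hits_both_endpoints(values):
    arr = np.asarray(values)
    if arr.max() == arr.min():
        return
    scaled = ex.scale_unit_interval(arr)
    assert scaled.min() == 0.0 and scaled.max() == 1.0
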