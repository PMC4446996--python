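import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epifst import (
    PeakMatrix,
    SampleMetadata,
    SimulationParams,
    ValidationError,
    genome_pca,
    pairwise_centroid_distances,
    simulate_peak_matrix,
    sliding_windows,
    species_centroids,
    windowed_divergence,
)


def _meta(labels, ids=None):
    ids = ids if ids is not None else [f"s{i}" for i in range(len(labels))]
    return SampleMetadata(pd.DataFrame({"sample_id": ids, "species": labels}))


def test_identical_samples_zero_inertia():
    dens = np.tile([[3.0], [5.0]], (1, 4))
    res = genome_pca(densities=dens, sample_ids=[f"s{i}" for i in range(4)])
    assert res.total_variance == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)
    np.testing.assert_array_equal(res.variance_explained, 0.0)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30)
def test_pca_matches_covariance_eigendecomposition(seed):
    """Scores/eigenvalues agree with a direct covariance eigenanalysis."""
    rng = np.random.default_rng(seed)
    n, p = rng.integers(3, 15), rng.integers(2, 25)
    dens = rng.normal(size=(p, n)) * rng.uniform(0.5, 3)
    res = genome_pca(densities=dens, sample_ids=[f"s{i}" for i in range(n)])
    X = dens.T - dens.T.mean(axis=0)
    cov = X.T @ X / n  # divisor-n covariance of variables
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    r = min(n, p)
    np.testing.assert_allclose(res.eigenvalues, eig[:r], rtol=1e-9, atol=1e-9)
    # eigenvalue sum equals total centered variance; fractions sum to 1
    assert res.eigenvalues.sum() == pytest.approx(res.total_variance, rel=1e-9)
    assert res.variance_explained.sum() == pytest.approx(1.0, rel=1e-9)
    # scores reproduce the centered data's geometry (pairwise distances)
    d_scores = np.linalg.norm(
        res.scores.to_numpy()[:, None, :] - res.scores.to_numpy()[None, :, :], axis=-1
    )
    d_data = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    np.testing.assert_allclose(d_scores, d_data, rtol=1e-8, atol=1e-8)


def test_scores_invariant_to_per_peak_offset():
    rng = np.random.default_rng(5)
    dens = rng.uniform(1, 5, size=(30, 6))
    ids = [f"s{i}" for i in range(6)]
    a = genome_pca(densities=dens, sample_ids=ids)
    b = genome_pca(densities=dens + rng.normal(size=(30, 1)), sample_ids=ids)
    pd.testing.assert_frame_equal(a.scores, b.scores, atol=1e-8)


def test_species_centroids_arithmetic():
    from epifst import PcaResult

    scores = pd.DataFrame({"PC1": [-1.0, 1.0, 3.0, 5.0]},
                          index=["a1", "a2", "b1", "b2"])
    res_stub = PcaResult(scores=scores, eigenvalues=np.array([5.0]),
                         variance_explained=np.array([1.0]), total_variance=5.0)
    meta = _meta(["A", "A", "B", "B"], ids=["a1", "a2", "b1", "b2"])
    cent = species_centroids(res_stub, meta, n_components=1)
    assert cent["A"][0] == pytest.approx(0.0)
    assert cent["B"][0] == pytest.approx(4.0)
    d = pairwise_centroid_distances(cent)
    assert d[("A", "B")] == pytest.approx(4.0)


def test_single_sample_species_centroid_is_its_score():
    rng = np.random.default_rng(2)
    dens = rng.normal(size=(10, 3))
    res = genome_pca(densities=dens, sample_ids=["a1", "a2", "b1"])
    cent = species_centroids(res, _meta(["A", "A", "B"], ids=["a1", "a2", "b1"]), n_components=2)
    np.testing.assert_allclose(cent["B"], res.scores.loc["b1"].to_numpy()[:2])


def test_fewer_than_two_samples_rejected():
    with pytest.raises(ValidationError):
        genome_pca(densities=np.ones((5, 1)), sample_ids=["s0"])


# ---------------------------------------------------------------------------
# windows


def test_sliding_window_enumeration():
    w = sliding_windows({"chr1": 2_000_000}, 1_000_000, 100_000)
    assert len(w) == 11
    assert (w.loc[0, "start"], w.loc[0, "end"]) == (0, 1_000_000)
    assert (w.loc[10, "start"], w.loc[10, "end"]) == (1_000_000, 2_000_000)
    assert (w["end"] - w["start"]).eq(1_000_000).all()


def test_short_chromosome_single_truncated_window():
    w = sliding_windows({"chr1": 500_000}, 1_000_000, 100_000)
    assert w.values.tolist() == [["chr1", 0, 500_000]]


def test_window_equals_step_equals_length():
    w = sliding_windows({"chr1": 1_000_000}, 1_000_000, 1_000_000)
    assert len(w) == 1


def test_invalid_window_sizes_rejected():
    with pytest.raises(ValueError):
        sliding_windows({"chr1": 100}, 10, 20)
    with pytest.raises(ValueError):
        sliding_windows({"chr1": 100}, 10, 0)


# ---------------------------------------------------------------------------
# windowed divergence


def test_windowed_divergence_identical_profiles_zero():
    meta = _meta(["A", "A", "B", "B"])
    peaks = pd.DataFrame(
        {"peak_id": ["p0", "p1", "p2"], "chrom": "chr1",
         "start": [100, 300, 700], "end": [200, 400, 800]}
    )
    dens = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 4))
    pm = PeakMatrix(peaks, dens, meta)
    out = windowed_divergence(pm, chrom_lengths={"chr1": 1000}, window_bp=1000,
                              step_bp=1000)
    assert out.loc[0, "n_peaks"] == 3
    assert out.loc[0, "dist_A__B"] == pytest.approx(0.0, abs=1e-9)


def test_windowed_divergence_orders_species_by_construction():
    """Species built with close human/chimp means and a distant macaque mean
    separate accordingly in per-window centroid distances."""
    params = SimulationParams(n_peaks=80, sigma2_alpha=0.0, sigma2_eps=0.25,
                              chrom_lengths={"chr1": 1_000_000}, seed=21,
                              fraction_divergent=0.0)
    pm, _ = simulate_peak_matrix(params)
    shift = {"human": 0.0, "chimp": 0.5, "macaque": 6.0}
    labels = pm.species_labels()
    dens = pm.densities.copy()
    for sp, s in shift.items():
        dens[:, labels == sp] += s
    pm2 = PeakMatrix(pm.peaks, dens, pm.metadata)
    out = windowed_divergence(pm2, chrom_lengths={"chr1": 1_000_000},
                              window_bp=1_000_000, step_bp=1_000_000)
    row = out.iloc[0]
    assert row["dist_human__chimp"] < row["dist_human__macaque"]
    assert row["dist_human__chimp"] < row["dist_chimp__macaque"]


def test_window_below_min_peaks_undefined():
    meta = _meta(["A", "A", "B", "B"])
    peaks = pd.DataFrame(
        {"peak_id": ["p0"], "chrom": ["chr1"], "start": [100], "end": [200]}
    )
    pm = PeakMatrix(peaks, np.ones((1, 4)), meta)
    out = windowed_divergence(pm, chrom_lengths={"chr1": 1000}, window_bp=1000,
                              step_bp=1000, min_peaks=2)
    assert out.loc[0, "n_peaks"] == 1
    assert np.isnan(out.loc[0, "dist_A__B"])


def test_distances_invariant_to_sample_order(primate_pm):
    pm, _ = primate_pm
    out1 = windowed_divergence(pm, chrom_lengths={"chr1": 100_000_000},
                               window_bp=100_000_000, step_bp=100_000_000)
    perm = np.random.default_rng(3).permutation(len(pm.sample_ids))
    meta2 = SampleMetadata(pm.metadata.table.iloc[perm].reset_index(drop=True))
    pm2 = PeakMatrix(pm.peaks.copy(), pm.densities[:, perm], meta2)
    out2 = windowed_divergence(pm2, chrom_lengths={"chr1": 100_000_000},
                               window_bp=100_000_000, step_bp=100_000_000)

    def dists(row):
        return {
            frozenset(c[len("dist_"):].split("__")): row[c]
            for c in row.index if c.startswith("dist_")
        }

    d1, d2 = dists(out1.iloc[0]), dists(out2.iloc[0])
    assert d1.keys() == d2.keys()
    for key in d1:
        assert d1[key] == pytest.approx(d2[key], rel=1e-8)
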