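"""Dissimilarities, NMDS, environmental surfaces and distance decay."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import sedna
from sedna.ordination import (
    bray_curtis,
    classical_mds,
    distance_decay,
    fit_surface,
    kruskal_stress,
    nmds,
)


def _df(arr, prefix="S"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"O{j}" for j in range(arr.shape[1])])


# ---------------------------------------------------------------------------
# Bray-Curtis

def test_identical_rows_have_zero_dissimilarity():
    m = _df([[1, 2, 3], [1, 2, 3]])
    D = bray_curtis(m, mode="log")
    assert D.iloc[0, 1] == pytest.approx(0.0)


def test_disjoint_rows_have_unit_dissimilarity():
    m = _df([[5, 0, 2, 0], [0, 3, 0, 7]])
    assert bray_curtis(m, mode="presence").iloc[0, 1] == pytest.approx(1.0)
    assert bray_curtis(m, mode="log").iloc[0, 1] == pytest.approx(1.0)


def test_formula_oracle_on_random_pairs():
    rng = np.random.default_rng(0)
    m = _df(rng.integers(0, 20, size=(6, 15)) * (rng.random((6, 15)) < 0.7))
    m = m.loc[m.sum(axis=1) > 0]
    D = bray_curtis(m, mode="presence")
    X = (m.to_numpy() > 0).astype(float)
    for i in range(len(m)):
        for j in range(i + 1, len(m)):
            a, b = X[i], X[j]
            expected = np.abs(a - b).sum() / (a + b).sum()
            assert D.iloc[i, j] == pytest.approx(expected)


def test_presence_mode_equals_sorensen():
    """On binary data, Bray-Curtis coincides with Sorensen dissimilarity
    1 - 2|A∩B| / (|A| + |B|), computed here from set cardinalities."""
    rng = np.random.default_rng(1)
    m = _df((rng.random((8, 25)) < 0.4).astype(float) * rng.integers(1, 9, (8, 25)))
    m = m.loc[m.sum(axis=1) > 0]
    D = bray_curtis(m, mode="presence")
    B = m.to_numpy() > 0
    for i in range(len(m)):
        for j in range(i + 1, len(m)):
            shared = int((B[i] & B[j]).sum())
            sor = 1 - 2 * shared / (B[i].sum() + B[j].sum())
            assert D.iloc[i, j] == pytest.approx(sor)


def test_empty_sample_is_an_error():
    m = _df([[1, 2], [0, 0]])
    with pytest.raises(ValueError, match="no taxa"):
        bray_curtis(m)


# ---------------------------------------------------------------------------
# NMDS

def _planar_D(n=20, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    D = squareform(pdist(pts))
    idx = [f"S{i}" for i in range(n)]
    return pd.DataFrame(D, index=idx, columns=idx), pts


def test_planar_distances_embed_with_near_zero_stress():
    D, _ = _planar_D()
    res = nmds(D, seed=1, n_restarts=5)
    assert res.stress < 0.01
    assert np.allclose(res.coords.mean(axis=0), 0, atol=1e-8)


def test_stress_invariant_to_isometries_of_the_configuration():
    D, pts = _planar_D(15, seed=2)
    s0 = kruskal_stress(pts, D.to_numpy())
    theta = 0.83
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    assert kruskal_stress(pts @ R, D.to_numpy()) == pytest.approx(s0, abs=1e-10)
    assert kruskal_stress(pts * [-1, 1], D.to_numpy()) == pytest.approx(s0, abs=1e-10)


def test_nmds_no_worse_than_metric_start():
    rng = np.random.default_rng(3)
    comm = _df((rng.random((18, 30)) < 0.4).astype(int))
    comm = comm.loc[comm.sum(axis=1) > 0]
    D = bray_curtis(comm, mode="presence")
    res = nmds(D, seed=4, n_restarts=5)
    start_stress = kruskal_stress(classical_mds(D.to_numpy()), D.to_numpy())
    assert res.stress <= start_stress + 1e-9


def test_nmds_reproducible_given_seed():
    D, _ = _planar_D(12, seed=5)
    r1 = nmds(D, seed=6, n_restarts=4)
    r2 = nmds(D, seed=6, n_restarts=4)
    assert r1.stress == r2.stress
    pd.testing.assert_frame_equal(r1.coords, r2.coords)


def test_asymmetric_input_rejected():
    bad = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError, match="symmetric"):
        nmds(bad)


# ---------------------------------------------------------------------------
# surfaces

def _coords(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, 2)), columns=["NMDS1", "NMDS2"],
                        index=[f"S{i}" for i in range(n)])


def test_linear_response_fully_explained():
    coords = _coords(60, seed=1)
    z = pd.Series(1.5 * coords["NMDS1"] - 0.7 * coords["NMDS2"] + 2.0,
                  index=coords.index)
    fit = fit_surface(coords, z, "linear")
    assert fit.deviance_explained >= 0.999


def test_noise_response_not_overfit():
    coords = _coords(100, seed=2)
    z = pd.Series(np.random.default_rng(3).normal(size=100), index=coords.index)
    fit = fit_surface(coords, z, "noise")
    assert fit.deviance_explained < 0.15


def test_curved_surface_matches_independent_smoother():
    """Deviance explained on a planted curved surface must agree within
    0.1 with an independent kernel-ridge smoother tuned by CV."""
    from sklearn.kernel_ridge import KernelRidge
    from sklearn.model_selection import GridSearchCV

    coords = _coords(100, seed=4)
    rng = np.random.default_rng(5)
    z = pd.Series(np.sin(coords["NMDS1"]) + coords["NMDS2"] ** 2
                  + rng.normal(0, 0.3, 100), index=coords.index)
    fit = fit_surface(coords, z, "curved")

    gcv = GridSearchCV(KernelRidge(kernel="rbf"),
                       {"alpha": np.logspace(-4, 1, 8), "gamma": np.logspace(-2, 1, 8)},
                       cv=5)
    gcv.fit(coords.to_numpy(), z.to_numpy())
    pred = gcv.predict(coords.to_numpy())
    r2 = 1 - np.sum((z - pred) ** 2) / np.sum((z - z.mean()) ** 2)
    assert abs(fit.deviance_explained - r2) <= 0.1


def test_constant_response_warns_with_zero_deviance():
    coords = _coords(30, seed=6)
    z = pd.Series(3.14, index=coords.index)
    with pytest.warns(UserWarning, match="constant"):
        fit = fit_surface(coords, z, "flat")
    assert fit.deviance_explained == 0.0


def test_deviance_monotone_as_penalty_shrinks():
    coords = _coords(80, seed=7)
    rng = np.random.default_rng(8)
    z = pd.Series(np.cos(coords["NMDS1"] * 2) + rng.normal(0, 0.2, 80),
                  index=coords.index)
    devs = [fit_surface(coords, z, lambdas=np.array([lam])).deviance_explained
            for lam in [1e3, 1.0, 1e-3, 1e-6]]
    assert all(b >= a - 1e-10 for a, b in zip(devs, devs[1:]))


def test_too_few_samples_is_an_error():
    coords = _coords(6, seed=9)
    with pytest.raises(ValueError, match="10 samples"):
        fit_surface(coords, pd.Series(np.arange(6.0), index=coords.index))


# ---------------------------------------------------------------------------
# distance decay

def _geo_community(n, rng, decay=False):
    lat = pd.Series(rng.uniform(60, 75, n), index=[f"S{i}" for i in range(n)])
    lon = pd.Series(rng.uniform(-50, -20, n), index=lat.index)
    if decay:
        # community composition drifts smoothly with latitude
        grad = (lat - lat.min()) / (lat.max() - lat.min())
        probs = np.clip(np.linspace(0.05, 0.95, 30)[None, :]
                        - grad.to_numpy()[:, None] * 0.8 + 0.4, 0.02, 0.98)
        m = (rng.random((n, 30)) < probs).astype(float)
    else:
        m = (rng.random((n, 30)) < 0.4).astype(float)
    m[m.sum(axis=1) == 0, 0] = 1
    return pd.DataFrame(m, index=lat.index,
                        columns=[f"O{j}" for j in range(30)]), lat, lon


def test_planted_decay_detected():
    rng = np.random.default_rng(10)
    m, lat, lon = _geo_community(30, rng, decay=True)
    res = distance_decay(m, lat, lon, n_permutations=999, seed=11)
    assert res["correlation"] < 0
    assert res["p_value"] <= 0.01


def test_decay_correlation_invariant_to_sample_order():
    rng = np.random.default_rng(12)
    m, lat, lon = _geo_community(15, rng)
    r1 = distance_decay(m, lat, lon, n_permutations=49, seed=13)
    perm = rng.permutation(len(m))
    r2 = distance_decay(m.iloc[perm], lat, lon, n_permutations=49, seed=13)
    assert r1["correlation"] == pytest.approx(r2["correlation"], abs=1e-12)


def test_decay_agrees_with_skbio_mantel():
    """The observed correlation matches scikit-bio's Mantel statistic
    (sign-flipped: we correlate similarity, skbio the dissimilarity)."""
    from skbio import DistanceMatrix
    from skbio.stats.distance import mantel

    rng = np.random.default_rng(14)
    m, lat, lon = _geo_community(16, rng, decay=True)
    res = distance_decay(m, lat, lon, n_permutations=99, seed=15)
    D = bray_curtis(m, mode="presence").to_numpy()
    from sedna.envdesign import haversine_km
    la, lo = lat.to_numpy(), lon.to_numpy()
    G = haversine_km(la[:, None], lo[:, None], la[None, :], lo[None, :])
    np.fill_diagonal(G, 0.0)
    G = (G + G.T) / 2
    r_ref, p_ref, _ = mantel(DistanceMatrix(D), DistanceMatrix(G),
                             method="pearson", permutations=0)
    assert res["correlation"] == pytest.approx(-r_ref, abs=1e-10)


def test_null_decay_type_one_error_controlled():
    rng = np.random.default_rng(16)
    rejections = 0
    reps = 100
    for rep in range(reps):
        m, lat, lon = _geo_community(14, rng)
        res = distance_decay(m, lat, lon, n_permutations=99, seed=17 + rep)
        rejections += res["p_value"] <= 0.05
    rate = rejections / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert rate <= 0.05 + 3 * se


def test_too_few_samples_for_decay():
    rng = np.random.default_rng(18)
    m, lat, lon = _geo_community(3, rng)
    with pytest.raises(ValueError, match="4 samples"):
        distance_decay(m, lat, lon)
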