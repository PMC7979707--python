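import numpy as np
import pandas as pd
import pytest

from dieltrait.surface import (
    DensityField,
    extract_hotspots,
    hdr_thresholds,
    kde_field,
    normal_scale_bandwidth,
    pca_surface,
    plugin_bandwidth,
    select_bandwidth,
)


def _df(X, prefix="t"):
    return pd.DataFrame(
        X, columns=[f"{prefix}{i}" for i in range(X.shape[1])],
        index=[f"s{i}" for i in range(X.shape[0])],
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_isotropic_fractions(rng):
    X = rng.standard_normal((10_000, 5))
    surf = pca_surface(_df(X))
    assert np.abs(surf.variance_fractions - 0.2).max() < 0.03


def test_pca_dominant_direction(rng):
    X = rng.standard_normal((20_000, 5))
    X[:, 2] *= np.sqrt(10.0)
    surf = pca_surface(_df(X))
    # eigenvalues 10,1,1,1,1 -> PC1 fraction 10/14
    assert surf.variance_fractions[0] == pytest.approx(10 / 14, abs=0.02)
    assert abs(surf.loadings.iloc[2, 0]) > 0.99
    assert surf.loadings.iloc[2, 0] > 0  # sign convention: top trait loads positive


def test_pca_duplicated_rows_invariant(rng):
    X = rng.standard_normal((100, 5))
    a = pca_surface(_df(X))
    b = pca_surface(_df(np.vstack([X, X])))
    assert np.allclose(a.loadings.to_numpy(), b.loadings.to_numpy(), atol=1e-9)
    assert np.allclose(a.variance_fractions, b.variance_fractions, atol=1e-9)


def test_pca_reconstruction_with_all_axes(rng):
    X = rng.standard_normal((60, 5)) @ rng.standard_normal((5, 5))
    surf = pca_surface(_df(X), n_axes=5)
    recon = surf.scores.to_numpy() @ surf.loadings.to_numpy().T
    assert np.abs(recon - (X - X.mean(axis=0))).max() < 1e-8


def test_pca_input_errors(rng):
    with pytest.raises(ValueError, match="at least"):
        pca_surface(_df(rng.standard_normal((4, 5))))
    X = rng.standard_normal((30, 5))
    X[3, 2] = np.nan
    with pytest.raises(ValueError, match="complete"):
        pca_surface(_df(X))
    with pytest.raises(ValueError):
        pca_surface(_df(rng.standard_normal((30, 5))), n_axes=6)


# ---------------------------------------------------------------------------
# bandwidth selection
# ---------------------------------------------------------------------------

def test_normal_scale_formula(rng):
    X = rng.standard_normal((500, 2))
    H = normal_scale_bandwidth(X)
    want = (4 / 4) ** (2 / 6) * 500 ** (-2 / 6) * np.cov(X.T)
    assert np.allclose(H, want)


def test_plugin_bandwidth_near_normal_scale_on_gaussian(rng):
    # on truly Gaussian data the plug-in choice is the same order of
    # magnitude as the normal-scale optimum and positive definite
    X = rng.multivariate_normal([0, 0], [[1.0, 0.6], [0.6, 2.0]], size=800)
    H = plugin_bandwidth(X)
    evals = np.linalg.eigvalsh(H)
    assert evals.min() > 0
    ns = normal_scale_bandwidth(X)
    ratio = np.linalg.det(H) / np.linalg.det(ns)
    assert 0.2 < ratio < 2.0


def test_select_bandwidth_modes(rng):
    X = rng.standard_normal((200, 2))
    H, used = select_bandwidth(X, "normal-scale")
    assert used == "normal-scale"
    H2, used2 = select_bandwidth(X, "plugin")
    assert used2 in ("plugin", "normal-scale-fallback")
    with pytest.raises(ValueError):
        select_bandwidth(X, "silverman")


# ---------------------------------------------------------------------------
# KDE field
# ---------------------------------------------------------------------------

def test_kde_mass_and_mode(gaussian_scores):
    field = kde_field(gaussian_scores, grid_size=121, bandwidth_mode="normal-scale")
    assert 0.99 <= field.integrated_mass() <= 1.01
    i, j = np.unravel_index(field.density.argmax(), field.density.shape)
    assert np.hypot(field.x[i], field.y[j]) < 0.15
    assert len(field.point_density) == len(gaussian_scores)


def test_kde_two_clusters_two_maxima(rng):
    X = np.vstack([
        rng.standard_normal((300, 2)) * 0.5 + [-4, 0],
        rng.standard_normal((300, 2)) * 0.5 + [4, 0],
    ])
    field = kde_field(X, grid_size=101, bandwidth_mode="normal-scale")
    from scipy.ndimage import maximum_filter

    local_max = (field.density == maximum_filter(field.density, size=5)) & (
        field.density > 0.1 * field.density.max()
    )
    assert local_max.sum() == 2


def test_kde_input_errors(rng):
    with pytest.raises(ValueError):
        kde_field(rng.standard_normal((5, 2)))
    with pytest.raises(ValueError):
        kde_field(rng.standard_normal((50, 3)))


# ---------------------------------------------------------------------------
# HDR thresholds
# ---------------------------------------------------------------------------

def test_hdr_thresholds_monotone(gaussian_scores):
    field = kde_field(gaussian_scores, grid_size=81, bandwidth_mode="normal-scale")
    th = hdr_thresholds(field.point_density)
    assert th[0.5] >= th[0.95] >= th[0.99]
    frac = (field.point_density >= th[0.5]).mean()
    assert 0.47 <= frac <= 0.53


def test_hdr_alpha_one_limit(rng):
    dens = rng.random(100)
    th = hdr_thresholds(dens, quantiles=(1.0,))
    assert th[1.0] == pytest.approx(dens.min())


def test_hdr_uniform_tie_case():
    th = hdr_thresholds(np.full(50, 0.7))
    assert th[0.5] == th[0.95] == th[0.99] == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

def _field_and_scores(X, grid=101):
    scores = _df(X, prefix="PC")
    field = kde_field(scores, grid_size=grid, bandwidth_mode="normal-scale")
    th = hdr_thresholds(field.point_density)
    return field, th, scores


def test_single_cluster_single_hotspot(rng):
    X = rng.standard_normal((600, 2))
    field, th, scores = _field_and_scores(X)
    fams = pd.Series("famA", index=scores.index)
    hs = extract_hotspots(field, th[0.5], scores, fams)
    assert hs.n_hotspots == 1
    frac = hs.hotspots[0].n_species / len(scores)
    assert 0.45 <= frac <= 0.55
    assert hs.family_coverage_niche == 1.0


def test_two_clusters_two_hotspots(rng):
    X = np.vstack([
        rng.standard_normal((400, 2)) * 0.5 + [-5, 0],
        rng.standard_normal((400, 2)) * 0.5 + [5, 0],
    ])
    field, th, scores = _field_and_scores(X)
    fams = pd.Series(["famL"] * 400 + ["famR"] * 400, index=scores.index)
    hs = extract_hotspots(field, th[0.5], scores, fams)
    assert hs.n_hotspots == 2
    sizes = sorted(h.n_species / len(scores) for h in hs.hotspots)
    for s in sizes:
        assert 0.18 <= s <= 0.32  # each about a quarter of the species
    total = sum(h.n_species for h in hs.hotspots) / len(scores)
    assert 0.45 <= total <= 0.55


def test_hotspot_partition_is_exact(rng):
    X = rng.standard_normal((500, 2))
    field, th, scores = _field_and_scores(X)
    fams = pd.Series("f", index=scores.index)
    hs = extract_hotspots(field, th[0.5], scores, fams)
    members = [s for h in hs.hotspots for s in h.species]
    assert len(members) == len(set(members))  # pairwise disjoint
    assert sorted(members + hs.unassigned) == sorted(scores.index)


def test_hotspot_min_species_and_all_family_denominator(rng):
    X = np.vstack([
        rng.standard_normal((500, 2)) * 0.5,
        rng.standard_normal((4, 2)) * 0.1 + [9, 9],
    ])
    field, th, scores = _field_and_scores(X)
    fams = pd.Series(["famA"] * 500 + ["famB"] * 4, index=scores.index)
    keep_all = extract_hotspots(field, th[0.5], scores, fams,
                                all_families={"famA", "famB", "famC"})
    assert keep_all.family_coverage_all is not None
    assert keep_all.family_coverage_all <= keep_all.family_coverage_niche
    filtered = extract_hotspots(field, th[0.5], scores, fams, min_species=10)
    assert filtered.n_hotspots <= keep_all.n_hotspots


def test_no_cell_above_threshold_warns(rng, caplog):
    X = rng.standard_normal((50, 2))
    scores = _df(X, prefix="PC")
    field = kde_field(scores, grid_size=41, bandwidth_mode="normal-scale")
    with caplog.at_level("WARNING", logger="dieltrait.surface"):
        hs = extract_hotspots(field, field.density.max() * 10, scores,
                              pd.Series("f", index=scores.index))
    assert hs.n_hotspots == 0
    assert sorted(hs.unassigned) == sorted(scores.index)
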