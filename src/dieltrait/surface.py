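"""Per-niche ecological strategy surfaces.

For one diel niche: PCA of the five standardised traits onto two axes, a
bivariate Gaussian kernel density over the score plane with an
unconstrained plug-in bandwidth matrix, highest-density-region thresholds at
the 0.5 / 0.95 / 0.99 quantiles of the sample densities, and functional
hotspots as the connected grid regions above the 0.5 threshold (the areas
holding the densest half of the niche's species).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize

log = logging.getLogger(__name__)

HDR_QUANTILES = (0.5, 0.95, 0.99)
DEFAULT_GRID = 151


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaSurface:
    scores: pd.DataFrame          # n x k
    loadings: pd.DataFrame        # traits x k eigenvectors
    variance_fractions: np.ndarray
    center: np.ndarray


def pca_surface(traits: pd.DataFrame, n_axes: int = 2) -> PcaSurface:
    """PCA by eigendecomposition of the trait covariance matrix.

    Each axis is oriented so that its largest-|loading| trait loads positive,
    which removes the sign arbitrariness of eigenvectors.
    """
    X = traits.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("PCA requires complete data (impute first)")
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} species, got {n}")
    if n_axes > p:
        raise ValueError("n_axes exceeds the number of traits")
    center = X.mean(axis=0)
    C = np.cov(X - center, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    for j in range(p):
        i_max = np.abs(evecs[:, j]).argmax()
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = (X - center) @ evecs[:, :n_axes]
    return PcaSurface(
        scores=pd.DataFrame(
            scores, index=traits.index,
            columns=[f"PC{i + 1}" for i in range(n_axes)],
        ),
        loadings=pd.DataFrame(
            evecs[:, :n_axes], index=traits.columns,
            columns=[f"PC{i + 1}" for i in range(n_axes)],
        ),
        variance_fractions=evals[:n_axes] / evals.sum(),
        center=center,
    )


# ---------------------------------------------------------------------------
# bandwidth selection
# ---------------------------------------------------------------------------

def normal_scale_bandwidth(X: np.ndarray) -> np.ndarray:
    """Unconstrained normal-scale bandwidth matrix for a d-variate KDE."""
    n, d = X.shape
    return (4.0 / (d + 2)) ** (2.0 / (d + 4)) * n ** (-2.0 / (d + 4)) * np.cov(X.T)


def _hermite(m: int, u: np.ndarray) -> np.ndarray:
    if m == 0:
        return np.ones_like(u)
    if m == 1:
        return u
    if m == 2:
        return u * u - 1.0
    if m == 3:
        return u**3 - 3.0 * u
    if m == 4:
        return u**4 - 6.0 * u * u + 3.0
    raise ValueError(m)


def _psi_functional(Z: np.ndarray, r: tuple, g: float, chunk: int = 256) -> float:
    """Double-sum estimate of the integrated density-derivative functional.

    psi_r = integral of f^(r) * f, estimated with an isotropic Gaussian
    pilot of bandwidth g on (pre-sphered) data Z.
    """
    n = len(Z)
    r1, r2 = r
    tot = 0.0
    for i0 in range(0, n, chunk):
        D = (Z[i0 : i0 + chunk, None, :] - Z[None, :, :]) / g
        phi = np.exp(-0.5 * (D[..., 0] ** 2 + D[..., 1] ** 2)) / (2 * np.pi)
        tot += float((_hermite(r1, D[..., 0]) * _hermite(r2, D[..., 1]) * phi).sum())
    return (-1.0) ** (r1 + r2) * tot / (n * n * g ** (2 + r1 + r2))


def plugin_bandwidth(X: np.ndarray) -> np.ndarray:
    """Unconstrained plug-in bandwidth matrix for a bivariate Gaussian KDE.

    The data are pre-sphered; the fourth-order integrated density-derivative
    functionals are estimated by double sums under an isotropic
    normal-reference pilot of bandwidth g = (2d/((d+2)n))^(1/(d+6)) (the
    summed-asymptotic-MSE style pilot), and the plug-in estimate of the
    asymptotic mean integrated squared error is minimised over the Cholesky
    factor of H. Raises if the optimisation fails or H is not SPD.
    """
    n, d = X.shape
    if d != 2:
        raise ValueError("plug-in selector implemented for 2-D data")
    S = np.cov(X.T)
    L = np.linalg.cholesky(S)
    Z = X @ np.linalg.inv(L).T
    g = (2.0 * d / ((d + 2) * n)) ** (1.0 / (d + 6))
    psi = {r: _psi_functional(Z, r, g) for r in [(4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]}
    RK = (4 * np.pi) ** (-d / 2)

    def crit(p: np.ndarray) -> float:
        l11, l21, l22 = np.exp(p[0]), p[1], np.exp(p[2])
        H11, H12, H22 = l11 * l11, l11 * l21, l21 * l21 + l22 * l22
        det = H11 * H22 - H12 * H12
        if det <= 0 or not np.isfinite(det):
            return 1e12
        t2 = (
            H11 * H11 * psi[(4, 0)]
            + H22 * H22 * psi[(0, 4)]
            + (2 * H11 * H22 + 4 * H12 * H12) * psi[(2, 2)]
            + 4 * H11 * H12 * psi[(3, 1)]
            + 4 * H12 * H22 * psi[(1, 3)]
        )
        return RK / (n * np.sqrt(det)) + 0.25 * t2

    h0 = (4.0 / (d + 2)) ** (2.0 / (d + 4)) * n ** (-2.0 / (d + 4))
    x0 = np.array([0.5 * np.log(h0), 0.0, 0.5 * np.log(h0)])
    res = minimize(crit, x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 3000})
    if not res.success:
        raise RuntimeError("plug-in bandwidth optimisation did not converge")
    l11, l21, l22 = np.exp(res.x[0]), res.x[1], np.exp(res.x[2])
    Lh = np.array([[l11, 0.0], [l21, l22]])
    H = L @ (Lh @ Lh.T) @ L.T
    if np.linalg.eigvalsh(H).min() <= 0:
        raise RuntimeError("plug-in bandwidth matrix is not positive definite")
    return H


def select_bandwidth(X: np.ndarray, mode: str = "plugin") -> tuple[np.ndarray, str]:
    """Bandwidth matrix plus the mode actually used (fallback is logged)."""
    if mode == "normal-scale":
        return normal_scale_bandwidth(X), "normal-scale"
    if mode != "plugin":
        raise ValueError("bandwidth_mode must be 'plugin' or 'normal-scale'")
    try:
        return plugin_bandwidth(X), "plugin"
    except Exception as err:
        log.warning("plug-in bandwidth failed (%s); normal-scale fallback", err)
        return normal_scale_bandwidth(X), "normal-scale-fallback"


# ---------------------------------------------------------------------------
# kernel density field
# ---------------------------------------------------------------------------

@dataclass
class DensityField:
    x: np.ndarray                 # grid axis 1 (length g)
    y: np.ndarray                 # grid axis 2 (length g)
    density: np.ndarray           # g x g, density[i, j] at (x[i], y[j])
    bandwidth: np.ndarray         # 2 x 2 SPD
    bandwidth_mode: str
    point_density: np.ndarray = field(repr=False, default=None)  # at the samples

    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def integrated_mass(self) -> float:
        return float(self.density.sum() * self.cell_area())


def _kde_eval(points: np.ndarray, X: np.ndarray, H: np.ndarray,
              chunk: int = 2048) -> np.ndarray:
    """Gaussian KDE with full bandwidth matrix H, evaluated at ``points``."""
    L = np.linalg.cholesky(H)
    Linv = np.linalg.inv(L)
    const = 1.0 / (len(X) * 2 * np.pi * np.sqrt(np.linalg.det(H)))
    Zx = X @ Linv.T
    out = np.empty(len(points))
    Zp = points @ Linv.T
    for i0 in range(0, len(points), chunk):
        D2 = (
            ((Zp[i0 : i0 + chunk, None, :] - Zx[None, :, :]) ** 2).sum(axis=2)
        )
        out[i0 : i0 + chunk] = np.exp(-0.5 * D2).sum(axis=1)
    return const * out


def kde_field(
    scores: np.ndarray | pd.DataFrame,
    grid_size: int = DEFAULT_GRID,
    bandwidth_mode: str = "plugin",
) -> DensityField:
    """Bivariate KDE over a padded grid covering the score cloud.

    The grid spans the data range padded by three bandwidth SDs on each side,
    which keeps the integrated mass loss below 1%.
    """
    X = np.asarray(scores, float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    if len(X) < 10:
        raise ValueError("need at least 10 points for a density surface")
    H, used = select_bandwidth(X, bandwidth_mode)
    pad = 3.0 * np.sqrt(np.linalg.eigvalsh(H).max())
    x = np.linspace(X[:, 0].min() - pad, X[:, 0].max() + pad, grid_size)
    y = np.linspace(X[:, 1].min() - pad, X[:, 1].max() + pad, grid_size)
    XX, YY = np.meshgrid(x, y, indexing="ij")
    grid_pts = np.column_stack([XX.ravel(), YY.ravel()])
    dens = _kde_eval(grid_pts, X, H).reshape(grid_size, grid_size)
    at_points = _kde_eval(X, X, H)
    return DensityField(
        x=x, y=y, density=dens, bandwidth=H, bandwidth_mode=used,
        point_density=at_points,
    )


def hdr_thresholds(
    point_density: np.ndarray, quantiles=HDR_QUANTILES
) -> dict:
    """Highest-density-region thresholds.

    c_alpha is the empirical (1 - alpha) quantile of the density values at
    the sample points, so about a fraction alpha of the species sit in the
    region {x : f(x) >= c_alpha}. Thresholds decrease as alpha grows.
    """
    dens = np.asarray(point_density, float)
    return {
        float(a): float(np.quantile(dens, 1.0 - a, method="lower"))
        for a in quantiles
    }


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

@dataclass
class Hotspot:
    label: int
    cells: np.ndarray             # boolean g x g membership
    species: list
    families: set

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass
class HotspotSet:
    hotspots: list
    unassigned: list              # species outside every hotspot
    family_coverage_niche: float  # families hit / families present in niche
    family_coverage_all: float | None  # optional: over all families supplied

    @property
    def n_hotspots(self) -> int:
        return len(self.hotspots)


def extract_hotspots(
    field: DensityField,
    c50: float,
    scores: pd.DataFrame,
    families: pd.Series,
    all_families: set | None = None,
    min_species: int = 0,
) -> HotspotSet:
    """Connected 0.5-HDR components and their species/family membership.

    Components are 8-connected regions of grid cells with density >= c50.
    Each species is assigned to the component containing its PC coordinates
    (none, if its cell falls below the threshold). ``min_species`` drops
    smaller components when set (default keeps all).
    """
    above = field.density >= c50
    if not above.any():
        log.warning("no grid cell reaches the 0.5 HDR threshold")
        return HotspotSet([], list(scores.index), 0.0,
                          0.0 if all_families is not None else None)
    labels, n_comp = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    pts = scores.to_numpy(float)
    ix = np.clip(np.searchsorted(field.x, pts[:, 0]) - 1, 0, len(field.x) - 1)
    iy = np.clip(np.searchsorted(field.y, pts[:, 1]) - 1, 0, len(field.y) - 1)
    # snap to the nearer grid node
    ix = ix + (np.abs(field.x[np.minimum(ix + 1, len(field.x) - 1)] - pts[:, 0])
               < np.abs(field.x[ix] - pts[:, 0]))
    iy = iy + (np.abs(field.y[np.minimum(iy + 1, len(field.y) - 1)] - pts[:, 1])
               < np.abs(field.y[iy] - pts[:, 1]))
    comp = labels[np.clip(ix, 0, len(field.x) - 1), np.clip(iy, 0, len(field.y) - 1)]
    fam = families.reindex(scores.index)
    hotspots = []
    for lab in range(1, n_comp + 1):
        members = scores.index[comp == lab]
        if min_species and len(members) < min_species:
            continue
        hotspots.append(
            Hotspot(
                label=lab,
                cells=labels == lab,
                species=list(members),
                families=set(fam.loc[members].dropna()),
            )
        )
    assigned = {s for h in hotspots for s in h.species}
    unassigned = [s for s in scores.index if s not in assigned]
    fam_in_niche = set(fam.dropna())
    hit = set().union(*[h.families for h in hotspots]) if hotspots else set()
    cov_niche = len(hit) / len(fam_in_niche) if fam_in_niche else 0.0
    cov_all = (len(hit) / len(all_families)) if all_families else None
    return HotspotSet(hotspots, unassigned, cov_niche, cov_all)
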