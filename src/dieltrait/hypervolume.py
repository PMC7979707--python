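"""Trait hypervolumes via one-class SVM boundaries and Monte-Carlo volume.

A group's occupied region of (z-scored) trait space is described by a
one-class SVM with a radial kernel fitted to the group's points; the volume
is estimated by uniform rejection sampling in a bounding box around the
data, in units of trait SDs raised to the number of dimensions. Pairwise
set statistics (intersection, union, unique fractions, Jaccard, Sorensen)
come from density-matched mutual inclusion of the two point clouds.

All hypervolumes within one analysis must share a single standardisation
frame (z-scores over the full species set) so that volumes are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .diet import diet_trait, gower_distance, pcoa
from .traits import TraitTable, transform_standardise

log = logging.getLogger(__name__)


@dataclass
class HypervolumeParams:
    nu: float = 0.01
    gamma: float | None = None        # None: 1/(d * mean variance), scale-adaptive
    margin_bandwidths: float = 1.0    # box expansion, in kernel SD equivalents
    proposal_density: float | None = None  # points per unit volume (d<=2 default 1000)
    min_proposals: int = 20_000
    max_proposals: int = 200_000


@dataclass
class PointCloudHypervolume:
    dimension: int
    svm: OneClassSVM = field(repr=False)
    points: np.ndarray = field(repr=False)   # accepted uniform samples
    volume: float
    point_density: float
    box_low: np.ndarray
    box_high: np.ndarray
    n_proposed: int
    seed: int | None
    params: HypervolumeParams

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(pts) >= 0


def _resolve_gamma(X: np.ndarray, gamma: float | None) -> float:
    if gamma is not None:
        return gamma
    v = X.var(axis=0).mean()
    return 1.0 / (X.shape[1] * v)


def build_hypervolume(
    points: np.ndarray | pd.DataFrame,
    params: HypervolumeParams | None = None,
    seed: int | None = None,
) -> PointCloudHypervolume:
    """Fit a one-class SVM boundary and estimate its enclosed volume.

    Uniform points are proposed in the data bounding box expanded by one
    kernel-bandwidth equivalent per side; the volume is the accepted fraction
    times the box volume, and the accepted points are kept as the cloud.
    """
    params = params or HypervolumeParams()
    X = np.asarray(points, float)
    if X.ndim != 2:
        raise ValueError("points must be 2-dimensional (n x d)")
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more points than dimensions ({n} <= {d})")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate support: all points identical")
    gamma = _resolve_gamma(X, params.gamma)
    svm = OneClassSVM(nu=params.nu, gamma=gamma).fit(X)
    bw = 1.0 / np.sqrt(2.0 * gamma)
    lo = X.min(axis=0) - params.margin_bandwidths * bw
    hi = X.max(axis=0) + params.margin_bandwidths * bw
    box_vol = float(np.prod(hi - lo))
    density = params.proposal_density
    if density is None and d <= 2:
        density = 1000.0
    if density is not None:
        n_prop = int(np.ceil(density * box_vol))
        n_prop = int(np.clip(n_prop, params.min_proposals, params.max_proposals))
    else:
        n_prop = params.max_proposals
    rng = np.random.default_rng(seed)
    proposals = rng.uniform(lo, hi, size=(n_prop, d))
    accepted = proposals[svm.decision_function(proposals) >= 0]
    if len(accepted) == 0:
        raise ValueError(
            "no proposal accepted by the boundary; review nu/gamma or input scaling"
        )
    volume = len(accepted) / n_prop * box_vol
    return PointCloudHypervolume(
        dimension=d,
        svm=svm,
        points=accepted,
        volume=volume,
        point_density=len(accepted) / volume,
        box_low=lo,
        box_high=hi,
        n_proposed=n_prop,
        seed=seed,
        params=params,
    )


# ---------------------------------------------------------------------------
# set statistics
# ---------------------------------------------------------------------------

@dataclass
class OverlapStats:
    volume_1: float
    volume_2: float
    intersection: float
    union: float
    unique_fraction_1: float
    unique_fraction_2: float
    jaccard: float
    sorensen: float


def overlap(
    h1: PointCloudHypervolume,
    h2: PointCloudHypervolume,
    seed: int | None = None,
) -> OverlapStats:
    """Pairwise set statistics by density-matched mutual inclusion.

    Both clouds are thinned to the smaller of the two point densities, the
    fraction of each cloud inside the other boundary is measured, and the
    intersection volume is the average of the two resulting estimates.
    """
    if h1.dimension != h2.dimension:
        raise ValueError("hypervolume dimensions differ")
    rng = np.random.default_rng(
        seed if seed is not None else abs(hash((h1.seed, h2.seed))) % 2**31
    )
    dens = min(h1.point_density, h2.point_density)
    clouds = []
    for h in (h1, h2):
        pts = h.points
        keep = int(round(dens * h.volume))
        if keep < len(pts):
            pts = pts[rng.choice(len(pts), size=max(keep, 1), replace=False)]
        clouds.append(pts)
    frac_1_in_2 = float(h2.contains(clouds[0]).mean())
    frac_2_in_1 = float(h1.contains(clouds[1]).mean())
    inter = 0.5 * (frac_1_in_2 * h1.volume + frac_2_in_1 * h2.volume)
    inter = min(inter, h1.volume, h2.volume)
    union = h1.volume + h2.volume - inter
    return OverlapStats(
        volume_1=h1.volume,
        volume_2=h2.volume,
        intersection=inter,
        union=union,
        unique_fraction_1=max(0.0, (h1.volume - inter) / h1.volume),
        unique_fraction_2=max(0.0, (h2.volume - inter) / h2.volume),
        jaccard=inter / union,
        sorensen=2.0 * inter / (h1.volume + h2.volume),
    )


# ---------------------------------------------------------------------------
# shared standardisation frame for trait tables
# ---------------------------------------------------------------------------

def trait_frame(
    table: TraitTable,
    diet_axes: int = 1,
    include_activity: bool = False,
) -> pd.DataFrame:
    """Standardised trait matrix over ALL species (one shared frame).

    Computes the synthetic diet trait from the table's diet categories
    (Gower + PCoA, axis 1, or axes 1-2 for the sensitivity variant), applies
    the transforms and z-scores every column over the full species set, so
    hypervolumes of any species subset share the same SD units. Optionally
    appends the activity pattern as a z-scored ordinal sixth trait.
    """
    if table.mask.to_numpy().any():
        raise ValueError("trait frame has missing values; impute or drop first")
    res = pcoa(gower_distance(table.diet_matrix()), k=max(diet_axes, 1),
               raw=table.diet_matrix())
    dt = diet_trait(res, use_axes=diet_axes)
    frame = transform_standardise(table, dt.iloc[:, 0])
    if diet_axes == 2:
        ax2 = dt.iloc[:, 1]
        frame["diet_axis2"] = ((ax2 - ax2.mean()) / ax2.std(ddof=1)).to_numpy()
    if include_activity:
        codes = pd.Categorical(
            table.data["diel_niche"],
            categories=["nocturnal", "crepuscular", "cathemeral", "diurnal"],
        ).codes.astype(float)
        frame["activity"] = (codes - codes.mean()) / codes.std(ddof=1)
    frame.index = table.species
    if frame.isna().any().any():
        raise ValueError("trait frame has missing values; impute or drop first")
    return frame


# ---------------------------------------------------------------------------
# the comparative analyses
# ---------------------------------------------------------------------------

def niche_vs_rest(
    frame: pd.DataFrame,
    groups: pd.Series,
    niche: str,
    params: HypervolumeParams | None = None,
    seed: int | None = None,
) -> OverlapStats:
    """Hypervolume of one group vs all remaining species (unmatched sizes)."""
    groups = groups.reindex(frame.index)
    sel = (groups == niche).to_numpy()
    if sel.sum() == 0 or (~sel).sum() == 0:
        raise ValueError(f"empty group for niche {niche!r}")
    ss = np.random.SeedSequence(seed).spawn(3)
    h1 = build_hypervolume(frame[sel], params, _seed_of(ss[0]))
    h2 = build_hypervolume(frame[~sel], params, _seed_of(ss[1]))
    return overlap(h1, h2, _seed_of(ss[2]))


@dataclass
class MatchedComparison:
    niche_a: str
    niche_b: str
    subset_size: int
    replicates: list
    seed: int | None

    def mean(self, stat: str) -> float:
        return float(np.mean([getattr(r, stat) for r in self.replicates]))

    def sd(self, stat: str) -> float:
        vals = [getattr(r, stat) for r in self.replicates]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def matched_pair(
    frame: pd.DataFrame,
    groups: pd.Series,
    niche_a: str,
    niche_b: str,
    n_subsets: int = 100,
    params: HypervolumeParams | None = None,
    seed: int | None = None,
) -> MatchedComparison:
    """Size-matched pairwise comparison.

    Per replicate the larger group is subsampled without replacement to the
    smaller group's size, both hypervolumes are rebuilt and the overlap
    statistics recorded; means and SDs across replicates summarise the pair.
    """
    groups = groups.reindex(frame.index)
    A = frame[(groups == niche_a).to_numpy()]
    B = frame[(groups == niche_b).to_numpy()]
    d = frame.shape[1]
    size = min(len(A), len(B))
    if size < d + 2:
        raise ValueError(f"matched subset size {size} below d + 2 = {d + 2}")
    ss = np.random.SeedSequence(seed).spawn(n_subsets)
    reps = []
    for r in range(n_subsets):
        rng = np.random.default_rng(ss[r])
        sub = []
        for G in (A, B):
            if len(G) > size:
                idx = rng.choice(len(G), size=size, replace=False)
                sub.append(G.iloc[idx])
            else:
                sub.append(G)
        s1, s2, s3 = (int(x) for x in rng.integers(2**31, size=3))
        h1 = build_hypervolume(sub[0], params, s1)
        h2 = build_hypervolume(sub[1], params, s2)
        reps.append(overlap(h1, h2, s3))
    return MatchedComparison(
        niche_a=niche_a, niche_b=niche_b, subset_size=size,
        replicates=reps, seed=seed,
    )


def flexibility_analysis(
    frame: pd.DataFrame,
    groups: pd.Series,
    flexible: pd.Series,
    params: HypervolumeParams | None = None,
    seed: int | None = None,
) -> dict:
    """Flexible vs obligate hypervolume overlap, pooled and per diel niche.

    Returns a mapping scope -> OverlapStats (volume_1/unique_fraction_1 refer
    to the flexible group); a scope missing either group is skipped with a
    warning and mapped to None.
    """
    groups = groups.reindex(frame.index)
    flexible = flexible.reindex(frame.index).astype(bool)
    scopes = {"all": pd.Series(True, index=frame.index)}
    for niche in pd.unique(groups.dropna()):
        scopes[str(niche)] = groups == niche
    out = {}
    ss = np.random.SeedSequence(seed).spawn(len(scopes))
    for (scope, sel), s in zip(scopes.items(), ss):
        flex = frame[(sel & flexible).to_numpy()]
        obli = frame[(sel & ~flexible).to_numpy()]
        d = frame.shape[1]
        if len(flex) <= d or len(obli) <= d:
            log.warning("scope %s lacks flexible or obligate species; skipped", scope)
            out[scope] = None
            continue
        s1, s2, s3 = s.spawn(3)
        h_flex = build_hypervolume(flex, params, _seed_of(s1))
        h_obli = build_hypervolume(obli, params, _seed_of(s2))
        out[scope] = overlap(h_flex, h_obli, _seed_of(s3))
    return out


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)
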