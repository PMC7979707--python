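"""Multiple imputation by chained equations with phylogenetic predictors.

Missing trait values are imputed on the transformed scales (log10 body mass
and litter size, square-root habitat breadth), conditioning each incomplete
column on every other trait column plus the first k phylogenetic
eigenvectors (PCoA axes of the tip-tip patristic distance matrix), which
inject the tendency of close relatives to resemble one another. Continuous
columns are redrawn from a Bayesian normal linear regression, the diel
niche from a multinomial logistic model and the foraging stratum from a
proportional-odds model; m independent chains are run and pooled by the
mean (numeric) or the mode (categorical).
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diet import DistanceMatrix, pcoa
from .traits import DIEL_NICHES, TraitTable
from .trees import TreeArrays, patristic_distances

log = logging.getLogger(__name__)

_MIN_OBSERVED = 20
_RIDGE = 1e-8


def phylo_eigenvectors(tree: TreeArrays, k: int = 10) -> pd.DataFrame:
    """First k phylogenetic eigenvectors (PCoA of patristic distances).

    Columns are centred and ordered by descending eigenvalue; rows are
    indexed by tip label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = patristic_distances(tree)
    res = pcoa(DistanceMatrix(values=D, ids=tree.labels), k=k)
    out = res.scores
    out.columns = [f"pev_{i + 1}" for i in range(k)]
    return out


@dataclass
class ImputationRun:
    tables: list            # m completed TraitTables
    frames: list            # m completed working frames (transformed scales)
    seed: int | None
    m: int
    iters: int
    warnings: list


# ---------------------------------------------------------------------------
# conditional-model draws
# ---------------------------------------------------------------------------

def _scaler(X: np.ndarray):
    """Column-standardiser for the non-intercept part of a design matrix."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return lambda A: (A - mu) / sd


def _draw_bayes_normal(X_obs, y_obs, X_mis, rng):
    """Posterior draw from the normal linear model, then predictive draw."""
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs + _RIDGE * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * XtX_inv
    cov = (cov + cov.T) / 2 + _RIDGE * np.eye(p)
    beta = beta_hat + np.linalg.cholesky(cov) @ rng.standard_normal(p)
    return X_mis @ beta + np.sqrt(sigma2) * rng.standard_normal(len(X_mis))


def _categorical_draw(proba: np.ndarray, classes: np.ndarray, rng) -> np.ndarray:
    cum = proba.cumsum(axis=1)
    u = rng.random((len(proba), 1))
    idx = (u > cum).sum(axis=1)
    return classes[np.minimum(idx, len(classes) - 1)]


def _draw_multinomial(X_obs, y_obs, X_mis, rng, warn_out, what):
    """Bootstrap multinomial-logistic fit, then categorical draws."""
    from sklearn.linear_model import LogisticRegression

    cats = np.unique(y_obs)
    if len(cats) < 2:
        return np.full(len(X_mis), cats[0])
    try:
        scale = _scaler(X_obs[:, 1:])
        boot = rng.integers(len(y_obs), size=len(y_obs))
        yb, Xb = y_obs[boot], X_obs[boot]
        if len(np.unique(yb)) < 2:
            yb, Xb = y_obs, X_obs
        clf = LogisticRegression(max_iter=500)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            clf.fit(scale(Xb[:, 1:]), yb)
        proba = clf.predict_proba(scale(X_mis[:, 1:]))
        return _categorical_draw(proba, clf.classes_, rng)
    except Exception as err:  # non-convergence and friends
        msg = f"{what}: multinomial fit failed ({err}); drawing from observed marginal"
        log.warning(msg)
        warn_out.append(msg)
        return rng.choice(y_obs, size=len(X_mis))


def _draw_ordinal(X_obs, y_obs, X_mis, rng, warn_out, what):
    """Proportional-odds (ordered logit) draw with multinomial fallback."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    cats = np.unique(y_obs)
    if len(cats) < 2:
        return np.full(len(X_mis), cats[0])
    try:
        scale = _scaler(X_obs[:, 1:])
        boot = rng.integers(len(y_obs), size=len(y_obs))
        yb, Xb = y_obs[boot], X_obs[boot]
        if len(np.unique(yb)) < len(cats):
            yb, Xb = y_obs, X_obs
        endog = pd.Series(pd.Categorical(yb, categories=cats, ordered=True))
        model = OrderedModel(endog, scale(Xb[:, 1:]), distr="logit")
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = model.fit(method="bfgs", maxiter=300, disp=False)
        proba = np.asarray(fit.model.predict(fit.params, exog=scale(X_mis[:, 1:])))
        return _categorical_draw(proba, cats, rng)
    except Exception as err:
        msg = f"{what}: proportional-odds fit failed ({err}); multinomial fallback"
        log.warning(msg)
        warn_out.append(msg)
        return _draw_multinomial(X_obs, y_obs, X_mis, rng, warn_out, what)


# ---------------------------------------------------------------------------
# the chain core: frame-level chained-equations sampler
# ---------------------------------------------------------------------------

#: per-column conditional-model families
MODEL_NORMAL, MODEL_MULTINOMIAL, MODEL_ORDINAL = "normal", "multinomial", "ordinal"


def mice_frames(
    frame: pd.DataFrame,
    miss: dict,
    models: dict,
    predictors: np.ndarray | None = None,
    m: int = 5,
    iters: int = 10,
    seed: int | None = None,
) -> tuple[list, list]:
    """m chained-equation completions of ``frame``.

    ``miss`` maps column name -> boolean missing vector; ``models`` maps
    column name -> model family. ``predictors`` (always-complete columns,
    e.g. phylogenetic eigenvectors) are appended to every design matrix.
    Returns (list of completed frames, warnings).
    """
    if m < 1 or iters < 1:
        raise ValueError("m and iters must be >= 1")
    for col, mv in miss.items():
        mv = np.asarray(mv, bool)
        if mv.all():
            raise ValueError(f"column {col} is entirely missing")
        if (~mv).sum() < _MIN_OBSERVED:
            raise ValueError(f"column {col} has fewer than {_MIN_OBSERVED} observed cells")
    if predictors is None:
        predictors = np.zeros((len(frame), 0))

    def design(f: pd.DataFrame, target: str) -> np.ndarray:
        parts = [np.ones((len(f), 1))]
        for col in f.columns:
            if col == target:
                continue
            if isinstance(f[col].dtype, pd.CategoricalDtype):
                codes = f[col].cat.codes.to_numpy()
                n_cat = len(f[col].cat.categories)
                onehot = np.zeros((len(f), n_cat - 1))
                for j in range(1, n_cat):
                    onehot[:, j - 1] = codes == j
                parts.append(onehot)
            else:
                parts.append(f[col].to_numpy(float)[:, None])
        parts.append(predictors)
        return np.concatenate(parts, axis=1)

    rng_master = np.random.default_rng(seed)
    chain_seeds = rng_master.integers(2**31, size=m)
    completed, warn = [], []
    for chain in range(m):
        rng = np.random.default_rng(chain_seeds[chain])
        f = frame.copy()
        for col, mv in miss.items():
            mv = np.asarray(mv, bool)
            obs = f[col][~mv].to_numpy()
            f.loc[mv, col] = rng.choice(obs, size=int(mv.sum()))
        for _ in range(iters):
            for col, mv in miss.items():
                mv = np.asarray(mv, bool)
                X = design(f, col)
                if models[col] == MODEL_NORMAL:
                    y = f[col].to_numpy(float)
                    f.loc[mv, col] = _draw_bayes_normal(X[~mv], y[~mv], X[mv], rng)
                elif models[col] == MODEL_MULTINOMIAL:
                    y = f[col].astype(str).to_numpy()
                    f.loc[mv, col] = _draw_multinomial(
                        X[~mv], y[~mv], X[mv], rng, warn, col
                    )
                elif models[col] == MODEL_ORDINAL:
                    y = f[col].to_numpy(float)
                    f.loc[mv, col] = _draw_ordinal(
                        X[~mv], y[~mv], X[mv], rng, warn, col
                    )
                else:
                    raise ValueError(f"unknown model family {models[col]!r}")
        completed.append(f)
    return completed, warn


# ---------------------------------------------------------------------------
# trait-table wrapper
# ---------------------------------------------------------------------------

_CONT_COLS = ("body_mass_g", "litter_size", "habitat_breadth")
_FORWARD = {
    "body_mass_g": np.log10,
    "litter_size": np.log10,
    "habitat_breadth": np.sqrt,
}
_BACKWARD = {
    "body_mass_g": lambda x: 10.0 ** x,
    "litter_size": lambda x: 10.0 ** x,
    "habitat_breadth": lambda x: np.maximum(1.0, np.round(x**2)),
}


def _working_frame(table: TraitTable) -> pd.DataFrame:
    df = table.data
    out = pd.DataFrame(index=df.index)
    for col in _CONT_COLS:
        out[col] = _FORWARD[col](df[col].to_numpy(float))
    for cat in table.diet_columns:
        out[cat] = df[cat].to_numpy(float)
    out["foraging_stratum"] = df["foraging_stratum"].to_numpy(float)
    out["diel_niche"] = pd.Categorical(df["diel_niche"], categories=DIEL_NICHES)
    return out


def chained_impute(
    table: TraitTable,
    eigenvectors: pd.DataFrame | None,
    m: int = 5,
    iters: int = 10,
    seed: int | None = None,
) -> ImputationRun:
    """Run m chains of column-by-column conditional imputation.

    Missing cells are initialised from the observed marginal of their column
    and then, for ``iters`` sweeps, redrawn from a conditional model of the
    column on all other trait columns plus the phylogenetic eigenvectors.
    Observed cells are never touched. Pass ``eigenvectors=None`` to impute
    without phylogenetic information.
    """
    frame0 = _working_frame(table)
    mask = table.mask
    miss, models = {}, {}
    for col in frame0.columns:
        if col in mask.columns and mask[col].any():
            miss[col] = mask[col].to_numpy(bool)
            if col == "diel_niche":
                models[col] = MODEL_MULTINOMIAL
            elif col == "foraging_stratum":
                models[col] = MODEL_ORDINAL
            else:
                models[col] = MODEL_NORMAL
    if eigenvectors is not None:
        ev = eigenvectors.reindex(table.species)
        unplaced = ev.index[ev.isna().any(axis=1)]
        if len(unplaced):
            log.warning(
                "%d species lack phylogenetic placement; zero eigenvectors used",
                len(unplaced),
            )
        ev = ev.fillna(0.0).to_numpy(float)
    else:
        ev = None
    frames, warn = mice_frames(frame0, miss, models, ev, m=m, iters=iters, seed=seed)
    tables = [_complete_table(table, f, miss) for f in frames]
    return ImputationRun(
        tables=tables, frames=frames, seed=seed, m=m, iters=iters, warnings=warn
    )


def _complete_table(table: TraitTable, frame: pd.DataFrame, miss: dict) -> TraitTable:
    """Back-transform a completed working frame into a full TraitTable."""
    df = table.data.copy()
    for col in _CONT_COLS:
        if col in miss:
            mv = miss[col]
            df.loc[mv, col] = _BACKWARD[col](frame[col].to_numpy(float)[mv])
    for cat in table.diet_columns:
        if cat in miss:
            mv = miss[cat]
            df.loc[mv, cat] = np.maximum(0.0, frame[cat].to_numpy(float)[mv])
    if "foraging_stratum" in miss:
        mv = miss["foraging_stratum"]
        df.loc[mv, "foraging_stratum"] = np.clip(
            np.round(frame["foraging_stratum"].to_numpy(float)[mv]), 1, 4
        )
    if "diel_niche" in miss:
        mv = miss["diel_niche"]
        df.loc[mv, "diel_niche"] = frame["diel_niche"].astype(str).to_numpy()[mv]
    mask = table.mask.copy()
    mask.loc[:, :] = False
    return TraitTable(data=df, mask=mask)


def pool(run: ImputationRun) -> TraitTable:
    """Pool the m completed tables: mean for numeric, mode for categorical.

    Categorical ties break deterministically toward the lowest category code
    (diel niches in their canonical order; strata by their ordinal code).
    """
    if run.m < 1:
        raise ValueError("empty imputation run")
    base = run.tables[0]
    df = base.data.copy()
    numeric = ["body_mass_g", "litter_size", "habitat_breadth"] + base.diet_columns
    for col in numeric:
        stack = np.column_stack([t.data[col].to_numpy(float) for t in run.tables])
        df[col] = stack.mean(axis=1)
    # habitat breadth stays an integer count
    df["habitat_breadth"] = np.maximum(1, np.round(df["habitat_breadth"])).astype(int)
    strat = np.column_stack(
        [t.data["foraging_stratum"].to_numpy(int) for t in run.tables]
    )
    df["foraging_stratum"] = _mode_rows(strat, np.arange(1, 5))
    niche_codes = np.column_stack(
        [
            pd.Categorical(t.data["diel_niche"], categories=DIEL_NICHES).codes
            for t in run.tables
        ]
    )
    df["diel_niche"] = np.array(DIEL_NICHES)[_mode_rows(niche_codes, np.arange(4))]
    mask = base.mask.copy()
    mask.loc[:, :] = False
    return TraitTable(data=df, mask=mask)


def _mode_rows(values: np.ndarray, domain: np.ndarray) -> np.ndarray:
    """Row-wise mode over a small integer domain, ties to the lowest value."""
    counts = np.stack([(values == v).sum(axis=1) for v in domain], axis=1)
    return domain[counts.argmax(axis=1)]
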