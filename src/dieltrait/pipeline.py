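"""Full-analysis orchestration: validate -> diet trait -> impute -> lambda ->
strategy surfaces -> hypervolumes -> report.

One master seed drives every stochastic stage through stage-named streams,
so changing the subset count of the hypervolume stage cannot perturb the
lambda stage. Sensitivity switches mirror the analysis variants: running on
complete cases instead of imputed data, carrying one or two diet ordination
axes, and including the activity pattern itself as a sixth trait.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diet import diet_trait, gower_distance, pcoa
from .hypervolume import (
    HypervolumeParams,
    flexibility_analysis,
    matched_pair,
    niche_vs_rest,
    trait_frame,
)
from .impute import chained_impute, phylo_eigenvectors, pool
from .phylosig import binary_recode, lambda_over_trees
from .surface import extract_hotspots, hdr_thresholds, kde_field, pca_surface
from .traits import DIEL_NICHES, TraitTable, read_trait_table
from .trees import read_newick

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunConfig:
    trait_csv: str
    trees_newick: str
    out_dir: str = "dieltrait_run"
    use_imputed: bool = True          # False: complete-case (data-deletion) variant
    diet_axes: int = 1
    include_activity_as_trait: bool = False
    chains: int = 25
    iters: int = 100
    n_eigenvectors: int = 10
    n_trees: int = 30
    n_subsets: int = 100
    grid_size: int = 151
    bandwidth_mode: str = "plugin"
    min_niche_size: int = 10          # niches smaller than this skip surfaces
    hypervolume: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if self.diet_axes not in (1, 2):
            raise ValueError("diet_axes must be 1 or 2")
        if self.chains < 1 or self.iters < 1:
            raise ValueError("chains and iters must be >= 1")
        if self.bandwidth_mode not in ("plugin", "normal-scale"):
            raise ValueError("bandwidth_mode must be 'plugin' or 'normal-scale'")


def stage_seed(master: int, stage: str) -> int:
    """Independent per-stage seed: master seed combined with the stage name."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(stage.encode())])
        .generate_state(1)[0] % 2**31
    )


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    version: str = __version__

    def record(self, stage: str, elapsed: float, **outputs) -> None:
        self.stages[stage] = {"status": "ok", "elapsed_s": round(elapsed, 3), **outputs}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "version": self.version,
                       "stages": self.stages}, fh, indent=2, default=_jsonable)

    @staticmethod
    def from_json(path) -> "RunReport":
        with open(path) as fh:
            raw = json.load(fh)
        rep = RunReport(config=raw["config"], version=raw["version"])
        rep.stages = raw["stages"]
        return rep


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(type(x))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order, writing outputs as each completes."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    hv_params = HypervolumeParams(**config.hypervolume)

    def run_stage(name, fn):
        t0 = time.time()
        try:
            payload = fn()
        except Exception as err:
            raise PipelineError(name, err) from err
        report.record(name, time.time() - t0, **payload)
        report.to_json(out / "report.json")
        log.info("stage %s done (%.1fs)", name, time.time() - t0)
        return payload

    state: dict = {}

    # 1 -- load and validate inputs
    def s_validate():
        state["table"] = read_trait_table(config.trait_csv)
        state["trees"] = read_newick(config.trees_newick)
        t = state["table"]
        counts = t.data["diel_niche"].value_counts().to_dict()
        return {
            "n_species": t.n_species,
            "n_trees": len(state["trees"]),
            "niche_counts": counts,
            "missing_fraction": float(t.mask.to_numpy().mean()),
        }

    run_stage("validate", s_validate)

    # 2 -- synthetic diet trait (on observed diet rows; imputation fills the rest)
    def s_diet():
        table = state["table"]
        diet = table.diet_matrix().dropna()
        res = pcoa(gower_distance(diet), k=2, raw=diet)
        state["diet_pcoa"] = res
        dt = diet_trait(res, use_axes=config.diet_axes)
        dt.to_csv(out / "diet_trait.csv")
        return {
            "variance_fractions": res.variance_fractions[:2],
            "axis1_loadings": res.loadings.iloc[:, 0].to_dict(),
        }

    run_stage("diet", s_diet)

    # 3 -- imputation (or the complete-case variant)
    def s_impute():
        table = state["table"]
        if not config.use_imputed:
            keep = table.complete_rows()
            df = table.data[keep.to_numpy()].reset_index(drop=True)
            state["completed"] = TraitTable.from_dataframe(df)
            state["imputed_activity"] = pd.Series(False, index=state["completed"].species)
            return {"mode": "data-deletion", "n_retained": int(keep.sum())}
        tree = state["trees"][0]
        ev = phylo_eigenvectors(tree, config.n_eigenvectors)
        run = chained_impute(
            table, ev, m=config.chains, iters=config.iters,
            seed=stage_seed(config.seed, "impute"),
        )
        pooled = pool(run)
        state["completed"] = pooled
        state["imputed_activity"] = pd.Series(
            table.mask["diel_niche"].to_numpy(), index=pooled.species
        )
        for i, t in enumerate(run.tables):
            t.data.to_csv(out / f"imputed_{i + 1:02d}.csv", index=False)
        pooled.data.to_csv(out / "pooled.csv", index=False)
        return {
            "mode": "imputed",
            "chains": config.chains,
            "iters": config.iters,
            "n_imputed_activity": int(state["imputed_activity"].sum()),
            "warnings": run.warnings,
        }

    run_stage("impute", s_impute)

    # 4 -- phylogenetic signal of the activity pattern
    def s_lambda():
        completed = state["completed"]
        # avoid circularity: drop species whose activity pattern was imputed
        retained = completed.species[~state["imputed_activity"].to_numpy()]
        niche = pd.Series(
            pd.Categorical(completed.data["diel_niche"], categories=DIEL_NICHES).codes,
            index=completed.species,
        ).loc[retained]
        trees = [_prune_to(t, set(retained)) for t in state["trees"]]
        n_trees = min(config.n_trees, len(trees))
        seed = stage_seed(config.seed, "lambda")
        states = {sp: int(c) for sp, c in niche.items()}
        summary = lambda_over_trees(trees, states, 4, n_trees, seed)
        per_niche = {}
        for i, name in enumerate(DIEL_NICHES):
            codes = {sp: int(binary_recode(np.array([c]), i)[0])
                     for sp, c in states.items()}
            if len(set(codes.values())) < 2:
                per_niche[name] = None
                continue
            s = lambda_over_trees(trees, codes, 2, n_trees, seed)
            per_niche[name] = {"mean": s.mean, "sd": s.sd}
        payload = {
            "lambda_mean": summary.mean,
            "lambda_sd": summary.sd,
            "n_retained": len(retained),
            "n_trees": n_trees,
            "per_niche": per_niche,
        }
        state["lambda"] = payload
        return payload

    run_stage("lambda", s_lambda)

    # 5 -- shared standardisation frame
    def s_frame():
        frame = trait_frame(
            state["completed"],
            diet_axes=config.diet_axes,
            include_activity=config.include_activity_as_trait,
        )
        state["frame"] = frame
        frame.to_csv(out / "trait_frame.csv")
        return {"n_traits": frame.shape[1], "n_species": frame.shape[0]}

    run_stage("frame", s_frame)

    # 6 -- per-niche strategy surfaces
    def s_surfaces():
        completed = state["completed"]
        frame = state["frame"]
        groups = pd.Series(completed.data["diel_niche"].to_numpy(), index=frame.index)
        fams = pd.Series(completed.data["family"].to_numpy(), index=frame.index)
        all_fams = set(fams.dropna())
        per_niche = {}
        for niche in DIEL_NICHES:
            sel = (groups == niche).to_numpy()
            if sel.sum() < max(config.min_niche_size, frame.shape[1] + 1):
                per_niche[niche] = None
                continue
            surf = pca_surface(frame[sel])
            fieldd = kde_field(surf.scores, config.grid_size, config.bandwidth_mode)
            th = hdr_thresholds(fieldd.point_density)
            hs = extract_hotspots(fieldd, th[0.5], surf.scores,
                                  fams[sel], all_families=all_fams)
            surf.scores.to_csv(out / f"surface_{niche}_scores.csv")
            surf.loadings.to_csv(out / f"surface_{niche}_loadings.csv")
            per_niche[niche] = {
                "n_species": int(sel.sum()),
                "variance_fractions": surf.variance_fractions,
                "n_hotspots": hs.n_hotspots,
                "hotspot_sizes": [h.n_species for h in hs.hotspots],
                "family_coverage_niche": hs.family_coverage_niche,
                "family_coverage_all": hs.family_coverage_all,
                "bandwidth_mode": fieldd.bandwidth_mode,
            }
        state["surfaces"] = per_niche
        return {"per_niche": per_niche}

    run_stage("surfaces", s_surfaces)

    # 7 -- hypervolumes: niche vs rest, matched pairs, flexibility
    def s_hypervolumes():
        frame = state["frame"]
        completed = state["completed"]
        groups = pd.Series(completed.data["diel_niche"].to_numpy(), index=frame.index)
        flex = pd.Series(
            completed.data["diel_flexible"].astype(bool).to_numpy(), index=frame.index
        )
        seed = stage_seed(config.seed, "hypervolume")
        ss = np.random.SeedSequence(seed).spawn(3)
        present = [n for n in DIEL_NICHES if (groups == n).sum() > frame.shape[1] + 1]
        vs_rest = {}
        for i, niche in enumerate(present):
            vs_rest[niche] = asdict(
                niche_vs_rest(frame, groups, niche, hv_params,
                              int(ss[0].generate_state(len(present))[i] % 2**31))
            )
        pairs = {}
        pair_list = [
            (a, b) for a, b in combinations(present, 2)
        ]
        child = ss[1].spawn(len(pair_list))
        for (a, b), cs in zip(pair_list, child):
            mc = matched_pair(
                frame, groups, a, b, n_subsets=config.n_subsets,
                params=hv_params, seed=int(cs.generate_state(1)[0] % 2**31),
            )
            pairs[f"{a}|{b}"] = {
                "subset_size": mc.subset_size,
                "volume_1_mean": mc.mean("volume_1"),
                "volume_1_sd": mc.sd("volume_1"),
                "volume_2_mean": mc.mean("volume_2"),
                "volume_2_sd": mc.sd("volume_2"),
                "unique_fraction_1_mean": mc.mean("unique_fraction_1"),
                "unique_fraction_1_sd": mc.sd("unique_fraction_1"),
                "unique_fraction_2_mean": mc.mean("unique_fraction_2"),
                "unique_fraction_2_sd": mc.sd("unique_fraction_2"),
            }
        flexres = flexibility_analysis(
            frame, groups, flex, hv_params, int(ss[2].generate_state(1)[0] % 2**31)
        )
        flexibility = {
            scope: (asdict(stats) if stats is not None else None)
            for scope, stats in flexres.items()
        }
        state["hypervolumes"] = {
            "niche_vs_rest": vs_rest, "matched_pairs": pairs,
            "flexibility": flexibility,
        }
        return state["hypervolumes"]

    run_stage("hypervolumes", s_hypervolumes)

    table1 = make_table1(report)
    table1.to_csv(out / "table1.csv", index=False)
    report.to_json(out / "report.json")
    return report


def _prune_to(tree, keep: set):
    """Restrict a tree to the given tip labels (drop the rest)."""
    from . import trees as _trees

    if set(tree.labels) == keep:
        return tree
    dtree = _trees.to_dendropy(tree)
    taxa = [t for t in dtree.taxon_namespace if t.label in keep]
    dtree.retain_taxa(taxa)
    return _trees.from_dendropy(dtree)


def make_table1(report: RunReport) -> pd.DataFrame:
    """Overlap table: each niche vs the rest, then all matched niche pairs."""
    if "hypervolumes" not in report.stages:
        raise ValueError("hypervolume stage has not completed")
    hv = report.stages["hypervolumes"]
    rows = []
    for niche, stats in hv["niche_vs_rest"].items():
        rows.append(
            {
                "comparison": "niche_vs_rest",
                "group_1": niche,
                "group_2": f"excluding {niche}",
                "volume_1": stats["volume_1"],
                "volume_2": stats["volume_2"],
                "unique_fraction_1": stats["unique_fraction_1"],
                "unique_fraction_2": stats["unique_fraction_2"],
                "volume_1_sd": np.nan,
                "unique_fraction_1_sd": np.nan,
                "subset_size": np.nan,
            }
        )
    for pair, stats in hv["matched_pairs"].items():
        a, b = pair.split("|")
        rows.append(
            {
                "comparison": "matched_pair",
                "group_1": a,
                "group_2": b,
                "volume_1": stats["volume_1_mean"],
                "volume_2": stats["volume_2_mean"],
                "unique_fraction_1": stats["unique_fraction_1_mean"],
                "unique_fraction_2": stats["unique_fraction_2_mean"],
                "volume_1_sd": stats["volume_1_sd"],
                "unique_fraction_1_sd": stats["unique_fraction_1_sd"],
                "subset_size": stats["subset_size"],
            }
        )
    return pd.DataFrame(rows)
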