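"""End-to-end analysis pipeline with table outputs.

Orchestrates: taxon mean shapes -> limb superimposition with semilandmark
sliding -> shape PCA with Anderson retention -> tree handling (fixed
topology or MRP supertree) -> conservative time calibration -> rank tests
with Bonferroni correction -> simulation-based phylogenetic ANOVA -> RMA
allometry (full sample and Titanosauria / Lithostrotia subsets) -> Pagel's
lambda per retained PC and log centroid size -> ancestral states and
phylomorphospace for traits with significant signal -> per-clade
ancestor-descendant change summaries.  Every stage writes a CSV table and
a JSON log records seeds and settings.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .landmarks import (read_landmarks, gpa_align, slide_semilandmarks,
                        taxon_mean_shape, SlidingScheme, centroid_size)
from .ordination import shape_pca, variance_table
from .trees import (read_newick, write_newick, read_tip_ages, read_clades,
                    time_calibrate, mrp_encode, mrp_supertree, TimeTree)
from .comparative import fit_lambda, ace_bm, phylomorphospace, phylo_anova
from .allometry import rma_fit, kruskal_wallis, bonferroni
from .trend import clade_change_summary


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclasses.dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    landmarks: str
    tip_ages: str
    clades: str
    output_dir: str
    tree: str | None = None               # calibratable newick (fixed topology)
    source_trees: list[str] = dataclasses.field(default_factory=list)
    sliding_criterion: str = "bending_energy"
    sliding_cycles: int = 3
    alpha: float = 0.05
    n_sim: int = 1000
    mbl: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if self.tree is None and not self.source_trees:
            raise ValueError("either a fixed tree or source trees required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def _scheme_from_configs(config) -> SlidingScheme | None:
    curves: dict[str, list[int]] = {}
    for cid in sorted({c for c in config.curve_ids if c}):
        anchor = [i for i in range(config.n_points)
                  if config.curve_ids[i] == cid and config.roles[i] == "fixed"]
        semi = [i for i in range(config.n_points)
                if config.curve_ids[i] == cid
                and config.roles[i] == "semilandmark"]
        if len(anchor) >= 2 and semi:
            curves[cid] = [anchor[0]] + semi + [anchor[-1]]
    return SlidingScheme(curves=curves) if curves else None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a result bundle of dataframes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "n_sim": config.n_sim,
                 "alpha": config.alpha, "mbl": config.mbl,
                 "sliding": {"criterion": config.sliding_criterion,
                             "cycles": config.sliding_cycles},
                 "version": __version__}
    bundle: dict = {"log": log}

    @_stage("landmarks")
    def load():
        if not os.path.exists(config.landmarks):
            raise FileNotFoundError(config.landmarks)
        return read_landmarks(config.landmarks)

    configs = load()

    @_stage("taxon_means")
    def means():
        return taxon_mean_shape(configs)

    taxon_configs = means()

    @_stage("gpa")
    def superimpose():
        scheme = _scheme_from_configs(taxon_configs[0])
        if scheme is not None:
            slid = slide_semilandmarks(
                taxon_configs, scheme,
                criterion=config.sliding_criterion,
                n_cycles=config.sliding_cycles).configurations
        else:
            slid = taxon_configs
        return gpa_align(slid)

    alignment = superimpose()
    coords = pd.DataFrame(
        alignment.tangent_coords,
        index=pd.Index(alignment.taxon_ids, name="taxon"))
    coords.to_csv(out / "aligned_coordinates.csv")
    pd.DataFrame(alignment.consensus.points,
                 columns=["x", "y", "z"]).to_csv(out / "consensus.csv",
                                                 index=False)

    @_stage("pca")
    def ordinate():
        return shape_pca(alignment, alpha=config.alpha)

    pca = ordinate()
    vt = variance_table(pca)
    vt.to_csv(out / "table_variance.csv", index=False)
    bundle["variance"] = vt
    scores = pd.DataFrame(
        pca.scores, index=pd.Index(pca.taxon_ids, name="taxon"),
        columns=[f"PC{i + 1}" for i in range(pca.n_components)])
    scores.to_csv(out / "pc_scores.csv")
    bundle["scores"] = scores
    log["n_pcs"] = pca.n_components
    log["n_retained"] = pca.n_retained

    @_stage("tree")
    def build_tree() -> TimeTree:
        if config.tree:
            with open(config.tree, encoding="utf-8") as fh:
                return read_newick(fh.read())
        sources = []
        for p in config.source_trees:
            with open(p, encoding="utf-8") as fh:
                sources.append(read_newick(fh.read()))
        return mrp_supertree(mrp_encode(sources), seed=config.seed)

    topology = build_tree()

    @_stage("calibration")
    def calibrate() -> TimeTree:
        ages = read_tip_ages(config.tip_ages)
        tree = time_calibrate(topology, ages, mbl=config.mbl)
        tree.clades = read_clades(config.clades)
        return tree

    tree = calibrate()
    (out / "calibrated_tree.nwk").write_text(write_newick(tree) + "\n")

    taxa = tree.tip_labels
    missing = [t for t in taxa if t not in scores.index]
    if missing:
        raise PipelineError("calibration",
                            f"tree tips without shape data: {missing}")
    clade_of = {t: next((c for c, members in sorted(tree.clades.items(),
                                                    key=lambda kv: len(kv[1]))
                         if t in members), "outgroup") for t in taxa}

    sizes = pd.Series(
        {t: s for t, s in zip(alignment.taxon_ids, alignment.centroid_sizes)})
    log_cs = np.log(sizes[taxa].to_numpy())

    @_stage("rank_tests")
    def rank_tests():
        rows = []
        glabels = [clade_of[t] for t in taxa]
        for pc in scores.columns:
            res = kruskal_wallis(scores.loc[taxa, pc].to_numpy(), glabels)
            rows.append({"PC": pc, "statistic": res.statistic, "p": res.p})
        df = pd.DataFrame(rows)
        df["p_adjusted"] = bonferroni(df["p"].to_numpy())
        return df

    kw = rank_tests()
    kw.to_csv(out / "table_kruskal_wallis.csv", index=False)
    bundle["kruskal_wallis"] = kw

    @_stage("phylo_anova")
    def anova():
        rows = []
        groups = {t: clade_of[t] for t in taxa}
        for pc in scores.columns[:pca.n_retained or len(scores.columns)]:
            res = phylo_anova(tree, dict(scores.loc[taxa, pc]), groups,
                              n_sim=config.n_sim, seed=config.seed)
            rows.append({"PC": pc, "Df": res.df_factor, "SS": res.ss_factor,
                         "MS": res.ms_factor, "R2": res.r_squared,
                         "F": res.F, "Z": res.Z, "p": res.p})
        return pd.DataFrame(rows)

    anova_df = anova()
    anova_df.to_csv(out / "table_phylo_anova.csv", index=False)
    bundle["phylo_anova"] = anova_df

    @_stage("allometry")
    def allometry():
        rows = []
        subsets = {"all": taxa}
        for name in ("Titanosauria", "Lithostrotia"):
            if name in tree.clades:
                subsets[name] = [t for t in taxa if t in tree.clades[name]]
        for subset, members in subsets.items():
            x = np.log(sizes[members].to_numpy())
            for pc in scores.columns:
                y = scores.loc[members, pc].to_numpy()
                try:
                    fit = rma_fit(x, y, alpha=config.alpha)
                except Exception:
                    continue
                rows.append({"subset": subset, "PC": pc,
                             "intercept": fit.intercept, "slope": fit.slope,
                             "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                             "r2": fit.r_squared, "p": fit.p})
        return pd.DataFrame(rows)

    rma_df = allometry()
    rma_df.to_csv(out / "table_rma.csv", index=False)
    bundle["rma"] = rma_df

    @_stage("signal")
    def signal():
        rows = []
        traits = {"log_Csize": pd.Series(log_cs, index=taxa)}
        for pc in scores.columns[:pca.n_retained or len(scores.columns)]:
            traits[pc] = scores.loc[taxa, pc]
        for name, tr in traits.items():
            fit = fit_lambda(tree, dict(tr), n_sim=config.n_sim,
                             seed=config.seed)
            rows.append({"trait": name, "lambda": fit.lambda_hat,
                         "sigma2": fit.sigma2_hat, "LR": fit.LR, "p": fit.p})
        return pd.DataFrame(rows), traits

    signal_df, traits = signal()
    signal_df.to_csv(out / "table_lambda.csv", index=False)
    bundle["lambda"] = signal_df

    @_stage("phylomorphospace")
    def project():
        pms = phylomorphospace(
            tree, {t: scores.loc[t, ["PC1", "PC2"]].to_numpy() for t in taxa})
        rows = [{"node_id": nid, "label": pms["labels"][nid] or "",
                 "PC1": xy[0], "PC2": xy[1]}
                for nid, xy in pms["coordinates"].items()]
        return pd.DataFrame(rows)

    pms_df = project()
    pms_df.to_csv(out / "phylomorphospace.csv", index=False)
    bundle["phylomorphospace"] = pms_df

    @_stage("trend")
    def trends():
        sig = signal_df[signal_df["p"].notna()
                        & (signal_df["p"] < config.alpha)]["trait"].tolist()
        frames = {}
        for name in sig:
            states = ace_bm(tree, dict(traits[name]))
            rows = []
            for clade in tree.clades:
                cs = clade_change_summary(tree, states, clade)
                rows.append({"clade": clade, "mean": cs.mean, "sum": cs.sum,
                             "skew": cs.skew, "median": cs.median, "n": cs.n,
                             "positive": cs.positive_changes,
                             "negative": cs.negative_changes,
                             "chi2": cs.chi2, "p": cs.p})
            frames[name] = pd.DataFrame(rows)
        return frames

    for name, df in trends().items():
        df.to_csv(out / f"table_trend_{name}.csv", index=False)
        bundle[f"trend_{name}"] = df

    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2)
    return bundle
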