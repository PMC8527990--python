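"""Full-analysis orchestration: load → rarefy → metrics → decay/stats/temporal.

``run_pipeline`` executes the complete analysis from a config object, writing
one TSV per analysis stage plus a JSON manifest and a run log (config echo,
seeds, input checksums).  Outputs already present in the output directory are
reused unless ``force`` is set, so each stage is independently re-runnable
from cached intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decay, metrics, mstats, subgroups, temporal
from .io import (
    load_count_table,
    load_square_matrix,
    load_study_design,
    load_tree,
    write_square_matrix,
)
from .model import CountTable, DataModelError, StudyDesign

log = logging.getLogger(__name__)

KNOWN_METRICS = ("sorensen", "braycurtis", "wunifrac")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    counts_path: str
    sample_meta_path: str
    facility_meta_path: str
    out_dir: str
    taxonomy_path: str | None = None
    tree_path: str | None = None
    counts_dialect: str = "wide_tsv"
    collapse_genus: bool = False
    otu_depth: int = subgroups.OTU_DEPTH
    phylotype_depth: int = subgroups.PHYLOTYPE_DEPTH
    metric_list: list[str] = field(default_factory=lambda: ["braycurtis", "sorensen"])
    alpha: float = 0.001
    seed: int = 0
    varpart_env: list[str] = field(
        default_factory=lambda: ["TKN_in", "TKN_out", "NH3_out"])
    volume_variable: str = "flow_rate"
    window_width_km: float = 200.0
    window_step_km: float = 10.0
    window_start_km: float = 10.0
    window_min_pairs: int = 10
    n_permutations: int = 999

    def __post_init__(self) -> None:
        if self.phylotype_depth < 1 or self.otu_depth < 1:
            raise DataModelError("rarefaction depths must be >= 1")
        if not 0 < self.alpha < 0.5:
            raise DataModelError(f"alpha must be in (0, 0.5), got {self.alpha}")
        unknown = [m for m in self.metric_list if m not in KNOWN_METRICS]
        if unknown:
            raise DataModelError(
                f"unknown metric(s) {unknown}; known: {list(KNOWN_METRICS)}")
        if "wunifrac" in self.metric_list and not self.tree_path:
            raise DataModelError("metric 'wunifrac' requires a tree_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("counts_path", "sample_meta_path", "facility_meta_path",
                     "taxonomy_path", "tree_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise DataModelError(f"{name} does not exist: {p}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fit_row(name: str, fit) -> dict:
    return {"analysis": name, "slope": fit.slope, "intercept": fit.intercept,
            "pearson_rho": fit.pearson_rho, "p_value": fit.p_value,
            "n_pairs": fit.n_pairs}


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run the full analysis; returns the manifest dict.

    Stages: alpha diversity, facility-pair table, per-metric decay fits,
    subgroup decay fits, taxon-volume fit, Mantel battery, variation
    partitioning, sliding windows, monthly decay, temporal classes, AMOVA.
    Any stage failure aborts with the stage name; the manifest marks which
    outputs were completed.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    run_log = logging.FileHandler(out / "run.log", mode="w")
    run_log.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("distdecay")
    root.addHandler(run_log)
    root.setLevel(logging.INFO)

    manifest: dict = {"config": dataclasses.asdict(config), "stages": {},
                      "inputs": {}}
    for name in ("counts_path", "sample_meta_path", "facility_meta_path",
                 "taxonomy_path", "tree_path"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    def cached(fname: str) -> Path | None:
        p = out / fname
        return p if (p.exists() and not force) else None

    def emit(fname: str, df: pd.DataFrame, stage: str) -> None:
        df.to_csv(out / fname, sep="\t", index=False,
                  float_format="%.10g")
        manifest["stages"][stage] = {"output": fname, "complete": True}
        log.info("stage %s -> %s (%d rows)", stage, fname, len(df))

    stage = "load"
    try:
        table = load_count_table(config.counts_path, config.counts_dialect,
                                 config.taxonomy_path)
        design = load_study_design(config.sample_meta_path,
                                   config.facility_meta_path)
        tree = load_tree(config.tree_path) if config.tree_path else None

        stage = "rarefy"
        n_before = table.n_samples
        table = subgroups.subsample_counts(table, config.phylotype_depth,
                                           config.seed)
        log.info("rarefied to %d: kept %d of %d samples",
                 config.phylotype_depth, table.n_samples, n_before)
        if config.collapse_genus:
            table = subgroups.collapse_to_genus(table)
        design = design.subset_samples(table.sample_ids)

        stage = "alpha_diversity"
        alpha = metrics.alpha_diversity(table)
        emit("alpha_diversity.tsv",
             alpha.reset_index(names="sample_id"), stage)

        stage = "taxon_volume"
        try:
            tv = decay.taxon_volume_fit(alpha, design, config.volume_variable)
            emit("taxon_volume.tsv", pd.DataFrame([_fit_row("taxon_volume", tv)]),
                 stage)
        except DataModelError as exc:
            log.warning("taxon-volume fit skipped: %s", exc)
            manifest["stages"][stage] = {"output": None, "complete": False}

        stage = "dissimilarity"
        geo = metrics.geographic_distance_km(design)
        ds_by_metric: dict[str, object] = {}
        for m in config.metric_list:
            cache = cached(f"ds_{m}.tsv")
            if cache:
                ds_by_metric[m] = load_square_matrix(cache)
                continue
            if m == "wunifrac":
                ds_by_metric[m] = metrics.weighted_unifrac(table, tree)
            else:
                ds_by_metric[m] = metrics.beta_dissimilarity(table, m)
            write_square_matrix(ds_by_metric[m], out / f"ds_{m}.tsv")
        manifest["stages"][stage] = {
            "output": [f"ds_{m}.tsv" for m in config.metric_list],
            "complete": True}

        stage = "facility_pairs"
        env_diffs = {}
        for v in design.env_variables:
            try:
                env_diffs[v], _ = metrics.env_difference_matrix(design, v)
            except DataModelError:
                log.warning("env variable %s skipped (insufficient data)", v)
        primary = config.metric_list[0]
        pairs = decay.facility_annual_mean(ds_by_metric[primary], design)
        pairs = decay.facility_pair_table(pairs, geo, env_diffs)
        emit("facility_pairs.tsv", pairs, stage)

        stage = "decay_fits"
        rows = []
        for m in config.metric_list:
            p = decay.facility_annual_mean(ds_by_metric[m], design)
            p = decay.facility_pair_table(p, geo)
            rows.append(_fit_row(f"whole_community_{m}",
                                 decay.decay_fit_from_pairs(p)))
        emit("decay_fits.tsv", pd.DataFrame(rows), stage)

        stage = "subgroups"
        masks = subgroups.compute_subgroups(table, design)
        sub_rows = []
        for name, mask in (("universal", masks.universal),
                           ("ubiquitous", masks.ubiquitous),
                           ("archaea", masks.archaea)):
            if len(mask) < 2:
                log.warning("subgroup %s has %d taxa; decay fit skipped",
                            name, len(mask))
                continue
            sub = table.select_taxa(mask)
            keep = sub.totals() > 0
            sub = sub.select_samples(list(sub.counts.index[keep]))
            try:
                sub_ds = metrics.beta_dissimilarity(sub, "braycurtis")
                p = decay.facility_annual_mean(
                    sub_ds, design.subset_samples(sub.sample_ids))
                p = decay.facility_pair_table(p, geo)
                row = _fit_row(f"subgroup_{name}", decay.decay_fit_from_pairs(p))
            except DataModelError as exc:
                log.warning("subgroup %s decay fit skipped: %s", name, exc)
                continue
            row["n_taxa"] = len(mask)
            mean_ra = subgroups.subgroup_relative_abundance(table, mask)
            row["mean_relative_abundance"] = float(mean_ra.mean())
            sub_rows.append(row)
        emit("subgroup_decay_fits.tsv", pd.DataFrame(sub_rows), stage)

        stage = "mantel"
        ds_fac = decay.pairs_to_matrix(pairs)
        against = {"geographic_distance": geo.filter(ds_fac.ids)}
        against.update({v: m for v, m in env_diffs.items()})
        battery = mstats.mantel_battery(ds_fac, against,
                                        n_perm=config.n_permutations,
                                        seed=config.seed)
        emit("mantel_battery.tsv", battery, stage)

        stage = "varpart"
        if config.varpart_env:
            missing = [v for v in config.varpart_env
                       if v not in design.env_variables]
            if missing:
                raise DataModelError(f"varpart env variables not found: {missing}")
            env_tab = design.facilities[config.varpart_env].dropna()
            comm = _facility_mean_abundance(table, design)
            shared_fac = [f for f in comm.index if f in env_tab.index]
            comm = comm.loc[shared_fac]
            env_tab = env_tab.loc[shared_fac]
            space_tab = design.facilities.loc[shared_fac,
                                              ["longitude", "latitude"]]
            vp = mstats.cca_varpart(comm, env_tab, space_tab,
                                    n_perm=config.n_permutations,
                                    seed=config.seed)
            emit("varpart.tsv", pd.DataFrame([{
                "pure_space": vp.pure_space, "pure_env": vp.pure_env,
                "shared": vp.shared, "unexplained": vp.unexplained,
                "p_space": vp.p_space, "p_env": vp.p_env, "p_full": vp.p_full,
                "n_facilities": len(shared_fac),
            }]), stage)

        stage = "sliding_windows"
        windows = decay.sliding_window_decay(
            pairs, width_km=config.window_width_km,
            step_km=config.window_step_km, start_km=config.window_start_km,
            covariate="TKN_in" if "diff_TKN_in" in pairs.columns else None,
            min_pairs=config.window_min_pairs)
        emit("sliding_windows.tsv", decay.windows_to_frame(windows), stage)

        stage = "monthly_decay"
        monthly = decay.monthly_decay_series(ds_by_metric[primary], design,
                                             geo, alpha=config.alpha)
        emit("monthly_decay.tsv", monthly, stage)

        stage = "temporal"
        classes = temporal.classify_all_bioreactors(
            ds_by_metric[primary], design, alpha=config.alpha)
        emit("temporal_classes.tsv", classes, stage)

        stage = "amova"
        am_rows = []
        am = mstats.amova(ds_by_metric[primary], design.samples["facility"],
                          n_perm=config.n_permutations, seed=config.seed)
        am_rows.append({"grouping": "facility", "ss_among": am.ss_among,
                        "ss_within": am.ss_within, "f_stat": am.f_stat,
                        "p_value": am.p_value, "n_groups": len(am.groups)})
        for fac, sub_meta in design.samples.groupby("facility"):
            if sub_meta["bioreactor"].nunique() < 2:
                continue
            ids = [s for s in ds_by_metric[primary].ids if s in sub_meta.index]
            am = mstats.amova(ds_by_metric[primary].filter(ids),
                              sub_meta.loc[ids, "bioreactor"],
                              n_perm=config.n_permutations, seed=config.seed)
            am_rows.append({"grouping": f"parallel_bioreactors_{fac}",
                            "ss_among": am.ss_among, "ss_within": am.ss_within,
                            "f_stat": am.f_stat, "p_value": am.p_value,
                            "n_groups": len(am.groups)})
        emit("amova.tsv", pd.DataFrame(am_rows), stage)

    except DataModelError as exc:
        manifest["complete"] = False
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        root.removeHandler(run_log)
        run_log.close()
        raise PipelineError(stage, str(exc)) from exc

    manifest["complete"] = True
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    root.removeHandler(run_log)
    run_log.close()
    return manifest


def _facility_mean_abundance(table: CountTable, design: StudyDesign
                             ) -> pd.DataFrame:
    """Facility × taxon annual-mean relative abundances (bioreactors averaged).

    Taxa never observed in any facility are dropped (they carry no inertia
    and would make the chi-square standardization degenerate).
    """
    rel = table.relative_abundance()
    fac = design.samples.loc[rel.index, "facility"]
    mean = rel.groupby(fac).mean()
    return mean.loc[:, mean.sum(axis=0) > 0]
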