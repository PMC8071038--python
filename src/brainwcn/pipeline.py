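"""End-to-end orchestration: ingestion -> normalization -> augmentation ->
network construction -> centrality -> group comparison -> report bundle."""

from __future__ import annotations

import hashlib
import json
import shutil
import traceback
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .centrality import MEASURES
from .compare import GroupComparison, centrality_cluster_map, rank_nodes
from .netbuild import build_network
from .schema import (BilateralAugmenter, FeatureNormalizer, FeatureTable,
                     read_freesurfer_tables, read_phenotype, select_cohort,
                     cohort_balance_check)

__all__ = ["RunConfig", "run_pipeline", "prepare_table"]


@dataclass
class RunConfig:
    """All stage parameters of a full pipeline run.

    Defaults follow the reference analysis design: correlation quantile
    0.85 (link density 0.15), Gaussian kernel width sigma = 1, nodes =
    the full augmented feature set, subject-level subsampling of the
    control group with replacement, K = 5x10^4 repetitions, one-tailed
    empirical p-values and Box-Cox regularized z-scores. ``n_subsample``
    = None draws as many control subjects per repetition as there are
    case subjects (M_sub = min group size).
    """

    features: list[str] = field(default_factory=list)
    pheno: str = ""
    out: str = "brainwcn_out"
    quantile: float = 0.85
    sigma: float = 1.0
    node_set: str = "augmented"      # 'augmented' | 'base'
    normalize: bool = True
    n_subsample: int | None = None
    n_repetitions: int = 50000
    replace: bool = True
    subsample_mode: str = "control"  # 'control' | 'both'
    tail: str = "one"
    use_boxcox: bool = True
    weighted_distance: str = "inverse"
    ipr_variant: str = "disparity"
    max_missing_frac: float = 0.5
    case_label: str = "case"
    control_label: str = "control"
    criteria: dict = field(default_factory=dict)
    top_k: int = 5
    n_clusters: int = 4
    seed: int = 0
    threads: int = 1
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the result-determining parameters (output location,
        thread count and log level do not affect the numbers)."""
        payload = asdict(self)
        for key in ("out", "threads", "log_level"):
            payload.pop(key, None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def prepare_table(config: RunConfig) -> tuple[FeatureTable, pd.DataFrame]:
    """Ingest, cohort-filter, normalize and augment the feature table."""
    table = read_freesurfer_tables(config.features)
    pheno = read_phenotype(config.pheno)
    groups = select_cohort(pheno, config.criteria or None)
    keep = [sid for ids in groups.values() for sid in ids
            if sid in set(table.subject_ids)]
    table = table.select_subjects(keep)
    if config.normalize:
        table = FeatureNormalizer().fit_transform(table)
    if config.node_set == "augmented":
        table = BilateralAugmenter().fit_transform(table)
    elif config.node_set != "base":
        raise ValueError(f"unknown node_set {config.node_set!r}")
    return table, pheno


def _write_csv(frame: pd.DataFrame, path: Path, config_hash: str,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# brainwcn config_hash={config_hash}\n")
        frame.to_csv(fh, na_rep="NA", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write a report bundle to config.out.

    Returns a dict of output paths and headline results. On a stage
    failure, partial outputs are preserved under ``<out>/failed/`` and
    the exception re-raised with a structured message.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    bundle: dict = {"config_hash": chash, "out": str(out)}
    try:
        return _run(config, out, chash, bundle)
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "error.txt").write_text(
            f"stage failure: {exc}\n\n{traceback.format_exc()}")
        for item in out.iterdir():
            if item.name != "failed" and item.is_file():
                shutil.move(str(item), failed / item.name)
        raise RuntimeError(f"pipeline failed ({exc}); partial outputs moved "
                           f"to {failed}") from exc


def _run(config: RunConfig, out: Path, chash: str, bundle: dict) -> dict:
    (out / "run_metadata.json").write_text(json.dumps(
        {"config": asdict(config), "config_hash": chash,
         "measures": list(MEASURES)}, indent=2, default=str))

    table, pheno = prepare_table(config)
    groups = select_cohort(pheno, config.criteria or None)
    subj = set(table.subject_ids)
    case_ids = [s for s in groups.get(config.case_label, []) if s in subj]
    control_ids = [s for s in groups.get(config.control_label, []) if s in subj]
    if not case_ids or not control_ids:
        raise ValueError(
            f"need both groups: labels {config.case_label!r}/"
            f"{config.control_label!r}, found {sorted(groups)}")
    bundle["n_case"], bundle["n_control"] = len(case_ids), len(control_ids)

    ages = pheno.set_index("subject_id")["age"]
    balance = cohort_balance_check(ages.loc[case_ids], ages.loc[control_ids])
    bundle["age_balance"] = balance

    with open(out / "features_prepared.tsv", "w") as fh:
        fh.write(f"# brainwcn config_hash={chash}\n")
        table.values.to_csv(fh, sep="\t")
    with open(out / "feature_metadata.csv", "w") as fh:
        fh.write(f"# brainwcn config_hash={chash}\n")
        table.metadata.to_csv(fh)

    case_table = table.select_subjects(case_ids)
    control_table = table.select_subjects(control_ids)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        case_net = build_network(case_table, config.quantile, config.sigma)
        control_net = build_network(control_table, config.quantile, config.sigma)
        net_warnings = [str(w.message) for w in caught]
    case_net.write(out / "network_case")
    control_net.write(out / "network_control")
    bundle["network_warnings"] = net_warnings
    bundle["case_density"] = case_net.density
    bundle["case_threshold"] = case_net.threshold
    bundle["control_threshold"] = control_net.threshold

    engine = GroupComparison(
        n_subsample=config.n_subsample, n_repetitions=config.n_repetitions,
        quantile=config.quantile, sigma=config.sigma, replace=config.replace,
        subsample_mode=config.subsample_mode, tail=config.tail,
        use_boxcox=config.use_boxcox,
        weighted_distance=config.weighted_distance,
        ipr_variant=config.ipr_variant,
        max_missing_frac=config.max_missing_frac,
        random_state=config.seed, n_jobs=config.threads)
    result = engine.fit(control_table).compare(case_table)

    _write_csv(result.whole_network, out / "whole_network.csv", chash)
    _write_csv(result.per_node, out / "per_node.csv", chash, index=False)
    if result.excluded_nodes is not None and len(result.excluded_nodes):
        _write_csv(result.excluded_nodes, out / "excluded_nodes.csv", chash,
                   index=False)

    # measure cluster map on the mean control profile and the case profile
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import numpy as np

        control_mean = pd.DataFrame(
            np.nanmean(engine._null_cache[result.conventions["n_subsample"]][0],
                       axis=0),
            index=engine.node_ids_, columns=list(MEASURES))
        cmap_control = centrality_cluster_map(control_mean, config.n_clusters)
        cmap_case = centrality_cluster_map(engine.case_profile_,
                                           config.n_clusters)
    _write_csv(cmap_control.correlation, out / "cluster_map_control.csv", chash)
    _write_csv(cmap_case.correlation, out / "cluster_map_case.csv", chash)
    _write_csv(cmap_control.labels.to_frame(), out / "cluster_labels_control.csv",
               chash)

    rank_tables = {}
    for measure in MEASURES:
        ranked = rank_nodes(result, measure, k=config.top_k,
                            metadata=table.metadata)
        rank_tables[measure] = ranked
        _write_csv(ranked, out / f"top_nodes_{measure}.csv", chash, index=False)

    summary = [f"# brainwcn run summary  config_hash={chash}",
               f"groups: {len(case_ids)} {config.case_label} vs "
               f"{len(control_ids)} {config.control_label}",
               f"age balance KS: D={balance['D']:.4f} p={balance['p']:.4f}",
               f"nodes: {len(engine.node_ids_)}  "
               f"density(case)={case_net.density:.4f}  "
               f"K={config.n_repetitions}  M_sub="
               f"{result.conventions['n_subsample']}",
               "", "whole-network comparison (z, p):"]
    for measure, row in result.whole_network.iterrows():
        flag = f" [{row['z_flag']}]" if row["z_flag"] else ""
        pflag = f" [{row['p_flag']}]" if row["p_flag"] else ""
        summary.append(f"  {measure:>14s}  z={row['z']:+7.3f}{flag}  "
                       f"p={row['p']:.2e}{pflag}")
    summary.append("")
    for measure in ("betweenness", "clustering", "ipr", "w_spectral"):
        summary.append(f"top-{config.top_k} nodes by |z|, {measure}:")
        for _, r in rank_tables[measure].iterrows():
            summary.append(f"  {int(r['rank'])}. {r['feature_id']:<40s} "
                           f"z={r['z']:+.3f}")
        summary.append("")
    if net_warnings:
        summary.append("warnings:")
        summary.extend(f"  - {w}" for w in net_warnings)
    (out / "summary.txt").write_text("\n".join(summary) + "\n")

    bundle["result"] = result
    bundle["summary"] = str(out / "summary.txt")
    return bundle
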