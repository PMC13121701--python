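"""Linear orchestration: simulate/load -> preprocess -> DE -> structure -> GSEA.

One :class:`RunConfig` drives the whole run; every random draw descends
from its single seed, and rerunning with the same config reproduces every
stage output bit for bit.  Stage outputs are written as TSV/JSON under the
output directory and summarized in a :class:`RunReport` whose counts
telescope across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import __version__
from .simulate import SimConfig, generate
from .preprocess import run_preprocess
from .diffexpr import (
    fit_all_contrasts,
    collect_de_sets,
    pairwise_summary,
    top_fc_subset,
    top_genes_table,
)
from .structure import zscore_log, cluster_samples, spearman_matrix, pca, grouping_purity
from .genesets import read_gmt
from .gsea import GseaRunConfig, run_gsea

__all__ = ["RunConfig", "StageFailure", "run_all"]

log = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``matrix_path``/``samples_path``/``genes_path`` point at real
    data, or ``simulate=True`` generates a synthetic dataset from ``sim``.
    """

    out_dir: str = "medivar_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig | None = None
    matrix_path: str | None = None
    samples_path: str | None = None
    genes_path: str | None = None
    gene_sets_path: str | None = None
    # thresholds
    fc_threshold: float = 2.0
    alpha: float = 0.05
    top_fraction: float = 0.05
    percentile: float = 0.95
    hkg_k: int = 12
    # GSEA
    nperm: int = 1000
    gsea_weight: float = 1.0
    # stage toggles
    do_preprocess: bool = True
    do_de: bool = True
    do_structure: bool = True
    do_gsea: bool = True
    keep_sex_genes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            cfg.sim = SimConfig(**sim_raw)
        return cfg

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if not self.simulate:
            for name in ("matrix_path", "samples_path", "genes_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or does not exist: {p}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageFailure(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order and write a RunReport JSON."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "config": _config_echo(config), "stages": {}}

    matrix, samples, genes, truth = _load_inputs(config)
    report["stages"]["input"] = {"n_genes": int(matrix.shape[0]), "n_samples": int(matrix.shape[1])}
    mio.write_matrix(matrix, out / "matrix_raw.tsv")
    mio.write_samples(samples, out / "samples.tsv")
    mio.write_genes(genes, out / "genes.tsv")
    if truth is not None:
        truth.to_frame().to_csv(out / "sim_truth.tsv", sep="\t")

    if config.do_preprocess:
        matrix, pre_report = _run_preprocess(config, matrix, genes, out)
        report["stages"]["preprocess"] = {
            "detection_limit": pre_report.detection_limit_normalized,
            "detection_limit_raw": pre_report.detection_limit_raw,
            "n_input": pre_report.n_input,
            "n_expressed": pre_report.n_expressed,
            "n_sex_excluded": pre_report.n_sex_excluded,
            "n_retained": pre_report.n_retained,
        }

    de_sets = None
    if config.do_de:
        de = _run_de(config, matrix, samples, out)
        report["stages"]["diffexpr"] = de["summary"]
        de_sets = de["sets"]

    if config.do_structure:
        report["stages"]["structure"] = _run_structure(config, matrix, samples, de_sets, out)

    if config.do_gsea and config.gene_sets_path:
        report["stages"]["gsea"] = _run_gsea_stage(config, matrix, samples, out)

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not serializable: {type(obj)}")


def _config_echo(config: RunConfig) -> dict:
    d = asdict(config)
    if config.sim is not None:
        d["sim"] = asdict(config.sim)
    return d


@_stage("input")
def _load_inputs(config: RunConfig):
    if config.simulate:
        sim = config.sim or SimConfig(seed=config.seed)
        if config.sim is None:
            log.info("simulating with default SimConfig, seed=%d", config.seed)
        matrix, samples, genes, truth = generate(sim)
        return matrix, samples, genes, truth
    matrix = mio.read_matrix(config.matrix_path)
    samples = mio.read_samples(config.samples_path)
    genes = mio.read_genes(config.genes_path)
    return matrix, samples, genes, None


@_stage("preprocess")
def _run_preprocess(config: RunConfig, matrix, genes, out: Path):
    retained, rep = run_preprocess(
        matrix, genes, hkg_k=config.hkg_k, q=config.percentile, keep_sex_genes=config.keep_sex_genes
    )
    mio.write_matrix(retained, out / "matrix_preprocessed.tsv")
    rep.to_json(out / "preprocess_report.json")
    return retained, rep


@_stage("diffexpr")
def _run_de(config: RunConfig, matrix, samples, out: Path) -> dict:
    log2 = np.log2(matrix)
    media = fit_all_contrasts(log2, samples, "medium", fc_threshold=config.fc_threshold, alpha=config.alpha)
    donors = fit_all_contrasts(log2, samples, "donor", fc_threshold=config.fc_threshold, alpha=config.alpha)
    for name, res in {**media, **donors}.items():
        res.table.to_csv(out / f"contrast_{name}.tsv", sep="\t", float_format="%.17g")
    media_set, line_set, combined = collect_de_sets(media, donors)
    media_mean, media_sd = pairwise_summary(media)
    donor_mean, donor_sd = pairwise_summary(donors)
    top_media = top_fc_subset(media, config.top_fraction)
    top_donor = top_fc_subset(donors, config.top_fraction)
    top_genes = top_genes_table({**media, **donors}, k=3)
    top_genes.to_csv(out / "top_genes.tsv", sep="\t", index=False)
    membership = pd.DataFrame(
        {
            "gene": sorted(combined),
            "in_media_set": [g in media_set for g in sorted(combined)],
            "in_line_set": [g in line_set for g in sorted(combined)],
        }
    )
    membership.to_csv(out / "de_sets.tsv", sep="\t", index=False)
    summary = {
        "media_set_size": len(media_set),
        "line_set_size": len(line_set),
        "combined_set_size": len(combined),
        "media_pairwise_mean": media_mean,
        "media_pairwise_sd": media_sd,
        "donor_pairwise_mean": donor_mean,
        "donor_pairwise_sd": donor_sd,
        "top_fc_media_size": len(top_media),
        "top_fc_donor_size": len(top_donor),
        "red_counts_media": {k: len(v.red_genes()) for k, v in media.items()},
        "red_counts_donor": {k: len(v.red_genes()) for k, v in donors.items()},
    }
    return {"summary": summary, "sets": {"media": media_set, "line": line_set, "combined": combined}}


@_stage("structure")
def _run_structure(config: RunConfig, matrix, samples, de_sets, out: Path) -> dict:
    z = zscore_log(matrix)
    dend = cluster_samples(z)
    (out / "dendrogram_genomewide.nwk").write_text(dend.to_newick() + "\n")
    result = {
        "purity_by_medium": grouping_purity(dend, samples["medium"], k=samples["medium"].nunique()),
        "purity_by_donor": grouping_purity(dend, samples["donor"], k=samples["donor"].nunique()),
    }
    if de_sets and de_sets["combined"]:
        genes_used = sorted(de_sets["combined"])
        corr = spearman_matrix(matrix.loc[genes_used])
        corr.to_csv(out / "spearman_de_genes.tsv", sep="\t", float_format="%.17g")
        p = pca(z.loc[genes_used], n_components=3)
        p.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.17g")
        p.loadings.abs().to_csv(out / "pca_importance.tsv", sep="\t", float_format="%.17g")
        result["pca_r2_percent"] = p.r2.round(4).to_dict()
        result["pca_cumulative_r2_percent"] = float(p.r2.sum())
        result["pca_top_genes"] = {c: p.top_genes(c, 3) for c in p.r2.index}
    return result


@_stage("gsea")
def _run_gsea_stage(config: RunConfig, matrix, samples, out: Path) -> dict:
    sets = read_gmt(config.gene_sets_path)
    sets = [s for s in sets if s.members & set(matrix.index)]
    if not sets:
        raise ValueError("no gene set overlaps the expressed matrix")
    gcfg = GseaRunConfig(weight=config.gsea_weight, nperm=config.nperm, seed=config.seed, alpha=config.alpha)
    table = run_gsea(matrix, samples, sets, gcfg)
    table.to_csv(out / "gsea_results.tsv", sep="\t", index=False, float_format="%.17g")
    return {
        "n_tests": int(len(table)),
        "bh_threshold": float(table["bh_threshold"].iloc[0]) if len(table) else 0.0,
        "n_passing_fdr": int(table["passes_fdr"].sum()),
        "n_nominal": int((table["pvalue"] < config.alpha).sum()),
    }
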