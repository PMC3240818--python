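"""End-to-end discovery pipeline: preprocess -> differential expression ->
annotation intersect -> network clustering -> cross-validated subset search.

The pipeline is driven by a :class:`PipelineConfig` (YAML-loadable, unknown
keys rejected).  A single global seed fans out to the stages through fixed
offsets, so each stage is individually reproducible and composable with the
standalone CLI subcommands.  Every numeric default is the anchored study
constant: fold-change threshold 1.3, 100 permutations, top-50 ranking, MCODE
vwp 0.2 with haircut, subsets up to size 3, 10-fold CV, ridge 1e-8, EF cutoff
40 %.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as rio
from .de import fold_change_filter, intersect_annotation, rank_top_genes, sam_two_class
from .modeling import subset_search
from .network import build_network, mcode_find_complexes
from .preprocess import patient_presence_filter
from .synthetic import SimulationConfig, simulate_study

logger = logging.getLogger("remodelnet")

# stage seed offsets (fanned out from the global seed)
_SAM_OFF, _CV_OFF = 101, 202


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, anchored analysis constants, seed and output location."""

    simulation: dict | None = None
    expression_path: str | None = None
    samples_path: str | None = None
    gene_set_path: str | None = None
    network_path: str | None = None
    min_fraction: float = 0.5
    fc_threshold: float = 1.3
    permutations: int = 100
    top_k: int = 50
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_threshold: float = 0.2
    max_size: int = 3
    folds: int = 10
    include_full_set: bool = True
    ef_cutoff: float = 40.0
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a mapping")
        return cls.from_dict(raw)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        study = simulate_study(SimulationConfig(**sim_kwargs))
        return study.expression, study.samples, study.annotation, study.network, study
    missing = [name for name, path in [
        ("expression_path", config.expression_path),
        ("samples_path", config.samples_path),
        ("gene_set_path", config.gene_set_path),
        ("network_path", config.network_path),
    ] if path is None]
    if missing:
        raise ValueError(f"config must provide a simulation block or file paths; missing {missing}")
    expr = rio.read_expression_tsv(config.expression_path)
    samples = rio.read_samples_csv(config.samples_path, ef_cutoff=config.ef_cutoff)
    gene_sets = rio.read_gmt(config.gene_set_path)
    net = rio.read_sif(config.network_path)
    return expr, samples, gene_sets[0], net, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full discovery pipeline and return the run report.

    Stages: patient presence filter -> fold-change + SAM differential calls ->
    annotation intersection -> network build -> MCODE clustering -> exhaustive
    subset evaluation over the top cluster's genes.  Any stage error aborts
    with the stage name; intermediates written so far are preserved.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        expr, samples, annotation, net, study = _load_inputs(config)
        logger.info("loaded %d genes x %d samples", *expr.shape)

        if out_dir and study is not None:
            rio.write_expression_tsv(expr, out_dir / "expression.tsv")
            rio.write_samples_csv(samples, out_dir / "samples.csv")
            rio.write_samples_csv(study.validation, out_dir / "validation.csv")
            rio.write_gmt(annotation, out_dir / "annotation.gmt")
            rio.write_sif(net, out_dir / "network.sif")
            rio.write_truth_json(study.truth, out_dir / "truth.json")

        stage = "preprocess"
        filtered = patient_presence_filter(expr, config.min_fraction)
        logger.info("presence filter kept %d/%d genes", filtered.shape[0], expr.shape[0])

        stage = "differential_expression"
        fc = fold_change_filter(filtered, samples, threshold=config.fc_threshold)
        if config.permutations > 0:
            sam = sam_two_class(filtered, samples, n_permutations=config.permutations,
                                seed=config.seed + _SAM_OFF)
            fc = fc.join(sam[["d", "p_value", "q_value"]])
        de_called = fc[fc["passes_fc"]]
        top = rank_top_genes(filtered, samples, k=min(config.top_k, filtered.shape[0]))
        if out_dir:
            fc.to_csv(out_dir / "de_results.tsv", sep="\t", na_rep="NA")
            top.to_csv(out_dir / "top_genes.tsv", sep="\t")

        stage = "annotation_intersect"
        annotated, (n_up_low, n_up_high) = intersect_annotation(fc, annotation)
        if out_dir:
            annotated.to_csv(out_dir / "annotated_de.tsv", sep="\t", na_rep="NA")

        stage = "network"
        net, net_report = build_network(list(net.edges()), nodes=net.nodes())
        clusters = mcode_find_complexes(net, vwp=config.vwp, haircut=config.haircut,
                                        fluff=config.fluff,
                                        fluff_threshold=config.fluff_threshold)
        if out_dir:
            with open(out_dir / "clusters.tsv", "w") as fh:
                fh.write("cluster\tseed\tn_nodes\tn_edges\tdensity\tscore\tmembers\n")
                for i, c in enumerate(clusters, 1):
                    fh.write(f"{i}\t{c.seed_vertex}\t{len(c.members)}\t{c.n_edges}\t"
                             f"{c.density:.4f}\t{c.score:.4f}\t{';'.join(map(str, c.members))}\n")

        stage = "subset_search"
        subsets_report = []
        best = None
        missing_candidates: list = []
        if clusters:
            candidates = [g for g in clusters[0].members]
            evaluations, missing_candidates = subset_search(
                candidates, filtered, samples, max_size=config.max_size,
                k=config.folds, seed=config.seed + _CV_OFF,
                include_full=config.include_full_set)
            for ev in evaluations[:10]:
                subsets_report.append({
                    "genes": list(ev.feature_ids),
                    "auc": round(ev.auc, 4),
                    "tpr_pct": round(ev.tpr, 2),
                    "fpr_pct": round(ev.fpr, 2),
                })
            best = subsets_report[0] if subsets_report else None
            if out_dir:
                with open(out_dir / "subsets.tsv", "w") as fh:
                    fh.write("genes\tauc\ttpr_pct\tfpr_pct\n")
                    for ev in evaluations:
                        fh.write(f"{';'.join(map(str, ev.feature_ids))}\t{ev.auc:.4f}\t"
                                 f"{ev.tpr:.2f}\t{ev.fpr:.2f}\n")

        stage = "report"
        report = {
            "constants": {
                "fc_threshold": config.fc_threshold,
                "permutations": config.permutations,
                "top_k": config.top_k,
                "mcode": {"vwp": config.vwp, "haircut": config.haircut,
                          "fluff": config.fluff, "fluff_threshold": config.fluff_threshold},
                "subset_max_size": config.max_size,
                "cv_folds": config.folds,
                "ridge": 1e-8,
                "ef_cutoff": config.ef_cutoff,
                "min_fraction": config.min_fraction,
            },
            "seeds": {"global": config.seed, "sam": config.seed + _SAM_OFF,
                      "cv": config.seed + _CV_OFF},
            "preprocess": {"genes_in": int(expr.shape[0]),
                           "genes_kept": int(filtered.shape[0]),
                           "n_samples": int(expr.shape[1])},
            "differential_expression": {
                "n_called": int(de_called.shape[0]),
                "n_up_in_low": int((de_called["direction"] == "up-in-low").sum()),
                "n_up_in_high": int((de_called["direction"] == "up-in-high").sum()),
                "top_ranked": list(top.index[: min(10, len(top))]),
            },
            "annotation": {"set_size": len(annotation),
                           "n_intersection": int(annotated.shape[0]),
                           "n_up_in_low": n_up_low, "n_up_in_high": n_up_high},
            "network": net_report,
            "clusters": [{"seed": str(c.seed_vertex), "n_nodes": len(c.members),
                          "n_edges": c.n_edges, "density": round(c.density, 4),
                          "score": round(c.score, 4)} for c in clusters],
            "subsets": subsets_report,
            "best_subset": best,
            "excluded_candidates": [str(g) for g in missing_candidates],
        }
        if out_dir:
            (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
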