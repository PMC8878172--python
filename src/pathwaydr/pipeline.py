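"""End-to-end orchestration: omics -> pathway activity -> recommender ->
similarities -> candidate repurposing pairs.

A :class:`PipelineConfig` collects the input paths and every tunable the
stages expose (ssGSEA exponent alpha = 0.25, latent dimension f = 10,
similarity threshold 0.95, Perlman transform A = 0.9 / b = 1, PPI score
cutoff 700), so one seeded run is fully described by one config file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .containers import DrugResponseMatrix, OmicsMatrix, TargetMap
from .enrichment import DEFAULT_ALPHA, DEFAULT_MIN_OVERLAP, aggregate_duplicate_genes, build_multiomics_profiles
from .recommender import (
    compute_cellline_features,
    convert_ic50,
    evaluate_ranking,
    predict,
    train,
)
from .similarity import (
    DEFAULT_THRESHOLD,
    PERLMAN_A,
    PERLMAN_B,
    drug_pathway_correlation,
    functional_similarity,
    select_repurposing_pairs,
    tanimoto_similarity,
    target_distance_similarity,
)

__all__ = ["PipelineConfig", "PipelineError", "InputError", "NumericalError", "run_pipeline"]

logger = logging.getLogger("pathwaydr")

# (layer name, config attribute, duplicate-gene aggregation mode)
LAYER_SPECS = (
    ("expression", "expression_path", "mean"),
    ("methylation", "methylation_path", "sum"),
    ("cnv", "cnv_path", "mean"),
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class InputError(PipelineError):
    """Missing or malformed input (CLI exit code 2)."""


class NumericalError(PipelineError):
    """Numerical failure inside a stage (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    expression_path: str = ""
    methylation_path: str = ""
    cnv_path: str = ""
    gene_sets_path: str = ""
    response_path: str = ""
    smiles_path: str = ""
    targets_path: str = ""
    ppi_path: str = ""
    output_dir: str = "pathwaydr_out"
    response_scale: str = "neglog10"  # neglog10 | ln | log10 | linear
    alpha: float = DEFAULT_ALPHA
    min_overlap: int = DEFAULT_MIN_OVERLAP
    f: int = 10
    learning_rate: float = 0.01
    max_epochs: int = 5000
    tol: float = 1e-8
    l2: float = 0.0
    threshold: float = DEFAULT_THRESHOLD
    fingerprint: str = "rdkit"
    n_bits: int = 2048
    radius: int = 2
    perlman_a: float = PERLMAN_A
    perlman_b: float = PERLMAN_B
    ppi_min_score: float = 700.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name, path in (
            ("expression", self.expression_path),
            ("methylation", self.methylation_path),
            ("cnv", self.cnv_path),
            ("gene_sets", self.gene_sets_path),
            ("response", self.response_path),
            ("smiles", self.smiles_path),
            ("targets", self.targets_path),
            ("ppi", self.ppi_path),
        ):
            if not path or not Path(path).exists():
                raise InputError("config", f"{name} input missing: {path!r}")
        if self.response_scale not in ("neglog10", "ln", "log10", "linear"):
            raise InputError("config", f"bad response_scale {self.response_scale!r}")
        if not -1.0 < self.threshold < 1.0:
            raise InputError("config", "threshold must lie in (-1, 1)")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except (OSError, ValueError, KeyError) as err:
                raise InputError(name, str(err)) from err
            except (ArithmeticError, np.linalg.LinAlgError) as err:  # pragma: no cover
                raise NumericalError(name, str(err)) from err

        return wrapped

    return deco


def load_response(config: PipelineConfig) -> DrugResponseMatrix:
    raw = pio.read_matrix(config.response_path)
    if config.response_scale != "neglog10":
        raw = convert_ic50(raw, config.response_scale)
    return DrugResponseMatrix(data=raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all declared outputs.

    Writes the pathway activity matrix, the fitted model, the ranking
    evaluation report, the three similarity matrices, the thresholded pair
    list and a machine-readable manifest into ``config.output_dir``.
    Returns the manifest dictionary.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("config: %s", asdict(config))

    @_stage("enrichment")
    def _enrich():
        layers = []
        for layer_name, attr, mode in LAYER_SPECS:
            raw = pio.read_matrix(getattr(config, attr))
            layer = OmicsMatrix(layer_name, raw)
            layers.append(aggregate_duplicate_genes(layer, mode))
        sets = pio.read_gmt(config.gene_sets_path)
        return build_multiomics_profiles(
            layers, sets, alpha=config.alpha, min_overlap=config.min_overlap
        )

    profiles = _enrich()
    pio.write_matrix(profiles.data, outdir / "pathway_activity.csv")

    @_stage("recommender")
    def _fit():
        response = load_response(config)
        features = compute_cellline_features(profiles)
        shared = [c for c in response.cellline_ids if c in set(features.cellline_ids)]
        if not shared:
            raise InputError("recommender", "response and omics share no cell lines")
        response = DrugResponseMatrix(data=response.data[shared])
        feats = type(features)(data=features.data.loc[shared])
        model = train(
            response,
            feats,
            f=config.f,
            seed=config.seed,
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            tol=config.tol,
            l2=config.l2,
        )
        predicted = predict(model, feats)
        evaluation = evaluate_ranking(response, predicted)
        return model, predicted, evaluation

    model, predicted, evaluation = _fit()
    pio.model_to_json(model, outdir / "model.json")
    report = evaluation.per_cellline.rename("ndcg").to_frame()
    pio.write_matrix(report, outdir / "evaluation.tsv")
    with open(outdir / "evaluation_summary.json", "w") as fh:
        json.dump(
            {
                "mean_ndcg": evaluation.mean_ndcg,
                "pooled_ndcg": evaluation.pooled_ndcg,
                "sse": evaluation.sse,
            },
            fh,
            indent=1,
        )

    @_stage("similarity")
    def _similarities():
        corr = drug_pathway_correlation(predicted, profiles)
        functional = functional_similarity(corr)
        smiles = pio.read_smiles(config.smiles_path)
        structural = tanimoto_similarity(
            smiles,
            fingerprint=config.fingerprint,
            n_bits=config.n_bits,
            radius=config.radius,
        )
        raw_targets = pio.read_targets(config.targets_path)
        all_genes = set().union(*raw_targets.values()) if raw_targets else set()
        graph = pio.read_ppi_edgelist(
            config.ppi_path, min_score=config.ppi_min_score, extra_nodes=all_genes
        )
        target_sim = target_distance_similarity(
            TargetMap(targets=raw_targets, graph=graph),
            a=config.perlman_a,
            b=config.perlman_b,
        )
        return corr, functional, structural, target_sim

    corr, functional, structural, target_sim = _similarities()
    pio.write_matrix(corr.data, outdir / "drug_pathway_correlation.csv")
    pio.write_matrix(functional.data, outdir / "functional_similarity.csv")
    pio.write_matrix(structural.data, outdir / "structural_similarity.csv")
    pio.write_matrix(target_sim.data, outdir / "target_distance_similarity.csv")

    selection = select_repurposing_pairs(functional, threshold=config.threshold)
    struct_ids = set(structural.drug_ids)
    target_ids = set(target_sim.drug_ids)
    with open(outdir / "repurposing_pairs.tsv", "w") as fh:
        fh.write("drug1\tdrug2\tfunctional\tstructural\ttarget_distance\n")
        for d1, d2, value in selection.pairs:
            s = (
                f"{structural.data.loc[d1, d2]:.6f}"
                if d1 in struct_ids and d2 in struct_ids
                else "-"
            )
            t = (
                f"{target_sim.data.loc[d1, d2]:.6g}"
                if d1 in target_ids and d2 in target_ids
                else "-"
            )
            fh.write(f"{d1}\t{d2}\t{value:.9f}\t{s}\t{t}\n")

    from . import __version__

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
        "n_pathways": len(profiles.pathway_ids),
        "n_drugs": len(model.drug_ids),
        "n_celllines": len(model.cell_bias),
        "mean_ndcg": evaluation.mean_ndcg,
        "sse": evaluation.sse,
        "n_selected_pairs": selection.n_selected,
        "total_pairs": selection.total_pairs,
        "outputs": [
            "pathway_activity.csv",
            "model.json",
            "evaluation.tsv",
            "drug_pathway_correlation.csv",
            "functional_similarity.csv",
            "structural_similarity.csv",
            "target_distance_similarity.csv",
            "repurposing_pairs.tsv",
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
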