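"""Seeded, logged end-to-end pipeline over the analysis stages.

``run_pipeline`` executes the enabled stages in dependency order --
simulate -> score -> train -> predict -> network -> metrics -> stats --
writing every declared output under one directory and recording a
manifest with checksums, so a run is fully reproducible from
(inputs, config).  Every stochastic stage derives its seed
deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (feature_scoring, graph_metrics, group_analysis,
               interaction_model, io, network, synthetic_data)

logger = logging.getLogger("phagenet")


@dataclass
class PipelineConfig:
    """All pipeline knobs in one validated, serializable object."""

    out_dir: str = "phagenet_out"
    seed: int = 42
    # synthetic inputs
    n_pos: int = 100
    n_neg: int = 100
    genome_length_min: int = 5000
    genome_length_max: int = 8000
    gc: float = 0.5
    # community design
    n_subjects: int = 4
    n_timepoints: int = 2
    n_phage_ogus: int = 30
    n_bacterial_ogus: int = 45
    truth_density: float = 0.8
    within_subject_corr: float = 0.9
    between_subject_corr: float = 0.2
    connectivity: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)
    # scoring thresholds
    nt_evalue_max: float = 1e-10
    aa_evalue_max: float = 1e-10
    crispr_evalue_max: float = 1.0
    # model
    cv_folds: int = 5
    cv_repeats: int = 10
    outer_iters: int = 25
    test_fraction: float = 0.2
    n_estimators: int = 50
    # network / metrics
    weight_fn: str = "mean"
    centrality_kind: str = "eigenvector"
    # noise sweep
    noise_fractions: tuple = (1.0, 0.8, 0.6, 0.4)
    noise_iters: int = 5
    anosim_permutations: int = 999
    # stage toggles
    stages: tuple = ("simulate", "score", "train", "predict",
                     "network", "metrics", "stats", "noise")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)!r}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ResultsBundle:
    out_dir: Path
    manifest: dict[str, str]
    config: PipelineConfig

    def checksum(self, name: str) -> str:
        return self.manifest[name]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Run the enabled stages and write outputs + manifest + log."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    stages = set(config.stages)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config: %s", json.dumps(asdict(config), default=list))

        scoring_config = feature_scoring.ScoringConfig(
            nt_evalue_max=config.nt_evalue_max,
            aa_evalue_max=config.aa_evalue_max,
            crispr_evalue_max=config.crispr_evalue_max)
        model_config = interaction_model.ModelConfig(
            n_estimators=config.n_estimators, cv_folds=config.cv_folds,
            cv_repeats=config.cv_repeats)
        domain_table = synthetic_data.default_domain_table()

        genomes = truths = feature_table = model = None

        if "simulate" in stages:
            logger.info("stage simulate")
            genomes, truths = synthetic_data.generate_training_set(
                config.n_pos, config.n_neg,
                length_range=(config.genome_length_min,
                              config.genome_length_max),
                gc=config.gc, domain_table=domain_table,
                seed=config.stage_seed("simulate"))
            io.write_fasta(genomes.values(), out / "genomes.fasta")
            io.write_tsv(synthetic_data.truth_to_frame(truths),
                         out / "truth_pairs.tsv")
            domain_table.to_tsv(out / "domain_profiles.tsv",
                                out / "domain_interactions.tsv")
            produced += [out / "genomes.fasta", out / "truth_pairs.tsv",
                         out / "domain_profiles.tsv",
                         out / "domain_interactions.tsv"]

        if "score" in stages:
            logger.info("stage score")
            if genomes is None:
                raise FileNotFoundError(
                    "stage 'score' needs genomes from stage 'simulate'")
            pairs = [(t.phage_id, t.bacterium_id) for t in truths]
            feature_table = feature_scoring.build_feature_table(
                pairs, genomes, domain_table=domain_table,
                config=scoring_config, path=out / "features.tsv")
            produced.append(out / "features.tsv")

        if "train" in stages:
            logger.info("stage train")
            if feature_table is None:
                raise FileNotFoundError(
                    "stage 'train' needs features from stage 'score'")
            labels = {(t.phage_id, t.bacterium_id): t.label for t in truths}
            y = [labels[(r.phage_id, r.bacterium_id)]
                 for r in feature_table.itertuples(index=False)]
            model = interaction_model.train_classifier(
                feature_table, y, config=model_config,
                seed=config.stage_seed("train"))
            perf = interaction_model.nested_cv(
                feature_table, y, outer_iters=config.outer_iters,
                test_fraction=config.test_fraction, config=model_config,
                seed=config.stage_seed("nested_cv"))
            io.write_tsv(perf.to_frame(), out / "nested_cv.tsv")
            roc_rows = [{"iteration": i, "fpr": float(f), "tpr": float(t)}
                        for i, (fpr, tpr) in enumerate(perf.roc_curves)
                        for f, t in zip(fpr, tpr)]
            io.write_tsv(pd.DataFrame(roc_rows), out / "roc_points.tsv")
            model.save(out / "model.joblib")
            importance = interaction_model.feature_importance(
                model, feature_table, y,
                seed=config.stage_seed("importance"))
            io.write_tsv(importance, out / "importance.tsv")
            logger.info("nested CV: median AUC %.3f, sens %.3f, spec %.3f",
                        perf.median_auc, perf.median_sensitivity,
                        perf.median_specificity)
            produced += [out / "nested_cv.tsv", out / "roc_points.tsv",
                         out / "importance.tsv", out / "model.joblib"]

        if "predict" in stages:
            logger.info("stage predict")
            if model is None or feature_table is None:
                raise FileNotFoundError(
                    "stage 'predict' needs a model from stage 'train'")
            predictions = interaction_model.predict_interactions(
                model, feature_table)
            io.write_tsv(predictions, out / "predictions.tsv")
            produced.append(out / "predictions.tsv")

        master = sample_graphs = metadata = None
        if "network" in stages:
            logger.info("stage network")
            truth_net = synthetic_data.generate_truth_network(
                config.n_phage_ogus, config.n_bacterial_ogus,
                config.truth_density, seed=config.stage_seed("truth_net"))
            design = synthetic_data.CommunityDesign(
                n_subjects=config.n_subjects,
                n_timepoints=config.n_timepoints,
                groups={g: tuple(m) for g, m in config.groups.items()}
                or None,
                connectivity=dict(config.connectivity) or None,
                within_subject_corr=config.within_subject_corr,
                between_subject_corr=config.between_subject_corr)
            abundance, metadata = synthetic_data.generate_community(
                design, truth_net, seed=config.stage_seed("community"))
            phages, bacts, edges = truth_net
            roles = {**{p: "phage" for p in phages},
                     **{b: "bacterium" for b in bacts}}
            pred_frame = pd.DataFrame(edges,
                                      columns=["phage_id", "bacterium_id"])
            pred_frame["prediction"] = "interacts"
            master = network.build_master_network(pred_frame, abundance,
                                                  roles, metadata)
            io.write_graphml(master, out / "master_network.graphml")
            io.write_tsv(abundance.reset_index(), out / "ogu_abundance.tsv")
            io.write_tsv(metadata, out / "metadata.tsv")
            sample_graphs = {s: network.extract_sample_graph(
                master, s, config.weight_fn)
                for s in abundance.columns}
            io.write_tsv(network.summarize_samples(
                master, abundance.columns, config.weight_fn),
                out / "sample_summary.tsv")
            produced += [out / "master_network.graphml",
                         out / "ogu_abundance.tsv", out / "metadata.tsv",
                         out / "sample_summary.tsv"]

        dist = None
        if "metrics" in stages:
            logger.info("stage metrics")
            if sample_graphs is None:
                raise FileNotFoundError(
                    "stage 'metrics' needs graphs from stage 'network'")
            rows = []
            for sid, G in sample_graphs.items():
                cents = graph_metrics.centrality(G, config.centrality_kind,
                                                 weighted=True)
                rows += [{"sample_id": sid, "node_id": v,
                          "kind": config.centrality_kind, "value": c}
                         for v, c in cents.items()]
            io.write_tsv(pd.DataFrame(rows), out / "centrality.tsv")
            dist = graph_metrics.dissimilarity_matrix(
                sample_graphs, kind=config.centrality_kind, weighted=True)
            io.write_matrix_tsv(dist, out / "dissimilarity.tsv")
            produced += [out / "centrality.tsv", out / "dissimilarity.tsv"]

        if "stats" in stages:
            logger.info("stage stats")
            if dist is None or metadata is None:
                raise FileNotFoundError(
                    "stage 'stats' needs the dissimilarity matrix from "
                    "stage 'metrics'")
            groups = dict(zip(metadata["sample_id"], metadata["subject"]))
            res = group_analysis.anosim(
                dist, groups, n_perm=config.anosim_permutations,
                seed=config.stage_seed("anosim"))
            stat_rows = [{"test": res.name, "statistic": res.statistic,
                          "p_value": res.p_value, "n": res.n}]
            try:
                pairs, wres = group_analysis.intra_inter_contrast(
                    dist, metadata, level="subject")
                stat_rows.append({"test": "intra_vs_inter_" + wres.name,
                                  "statistic": wres.statistic,
                                  "p_value": wres.p_value, "n": wres.n})
                io.write_tsv(pairs, out / "intra_inter.tsv")
                produced.append(out / "intra_inter.tsv")
            except ValueError as err:
                logger.warning("intra/inter contrast skipped: %s", err)
            coords, stress = group_analysis.nmds(
                dist, seed=config.stage_seed("nmds"))
            io.write_tsv(coords.reset_index(names="sample_id"),
                         out / "nmds.tsv")
            io.write_tsv(pd.DataFrame(stat_rows), out / "stats.tsv")
            produced += [out / "nmds.tsv", out / "stats.tsv"]

        if "noise" in stages:
            logger.info("stage noise")
            if sample_graphs is None or metadata is None:
                raise FileNotFoundError(
                    "stage 'noise' needs graphs from stage 'network'")
            groups = dict(zip(metadata["sample_id"], metadata["subject"]))

            def _anosim_p(graphs) -> float:
                d = graph_metrics.dissimilarity_matrix(
                    graphs, kind=config.centrality_kind, weighted=True)
                return group_analysis.anosim(
                    d, groups, n_perm=config.anosim_permutations,
                    seed=config.stage_seed("noise_anosim")).p_value

            sweep = graph_metrics.noise_sweep(
                sample_graphs, _anosim_p,
                fractions=list(config.noise_fractions),
                n_iter=config.noise_iters,
                seed=config.stage_seed("noise"))
            io.write_tsv(sweep, out / "noise_sweep.tsv")
            produced.append(out / "noise_sweep.tsv")

        manifest = {p.name: _sha256(p) for p in produced}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("pipeline complete: %d outputs", len(manifest))
        return ResultsBundle(out_dir=out, manifest=manifest, config=config)
    finally:
        logger.removeHandler(handler)
        handler.close()
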