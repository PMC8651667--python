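"""End-to-end orchestration: batch correction -> DE -> profiles -> gap/K ->
clustering -> enrichment -> candidate discovery, with per-stage TSV artifacts
and a deterministic run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import batch, de, discover, enrich, gapstat, profiles as prof
from . import io as gio

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "adjusted_counts.tsv", "de_results.tsv", "top_degs.txt", "tpm.tsv",
    "profiles_median.tsv", "profiles_zscore.tsv", "gap_curve.tsv",
    "clusters.tsv", "cluster_profiles.tsv", "enrichment.tsv",
    "functional_clusters.tsv", "candidates.tsv",
)


@dataclass
class PipelineConfig:
    counts: str
    metadata: str
    annotation: str
    gene_sets: str
    known_genes: str
    evidence: str
    output_dir: str
    target_terms: list = field(default_factory=list)
    skip_batch_correction: bool = False
    include_condition_in_batch_model: bool = True
    n_top: int = 3000
    de_alpha: float = 0.05
    rank_by: str = "pvalue"
    kmax: int = 100
    gap_B: int = 50
    gap_clusterer: str = "kmeans"
    gap_restarts: int = 10
    selection_rule: str = "tibshirani_1se"
    fixed_k: int | None = None  # bypass gap selection (e.g. compare K=10/30/100)
    cluster_method: str = "hierarchical"
    enrich_alpha: float = 0.05
    min_set: int = 10
    max_set: int = 500
    require_rising: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def content_hash(self) -> str:
        """Hash of the semantic configuration; excludes output_dir so reruns
        into different directories produce identical manifests."""
        d = asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    output_dir: Path
    selected_k: int
    report: discover.CandidateReport
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages in order, writing every artifact plus ``manifest.json``
    (config hash, seed, per-artifact checksums; no timestamps, so identical
    seed and config give byte-identical manifests). Any stage failure leaves a
    ``FAILED`` marker naming the stage alongside the artifacts produced so far."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    try:
        counts = gio.read_count_matrix(config.counts)
        meta = gio.read_sample_metadata(config.metadata)
        ann = gio.read_gene_annotation(config.annotation)
        sets = gio.read_gene_sets(config.gene_sets)
        known = gio.read_known_genes(config.known_genes)
        evidence = gio.read_evidence(config.evidence)
        meta.check_against(counts)

        stage = "batch-correction"
        if config.skip_batch_correction or len(meta.batches) == 1:
            adjusted = counts
        else:
            model = batch.fit_batch_model(
                counts, meta, include_condition=config.include_condition_in_batch_model)
            adjusted = batch.adjust_counts(counts, model)
        gio.write_count_matrix(adjusted, out / "adjusted_counts.tsv")

        stage = "differential-expression"
        de_table = de.wald_de(adjusted, meta)
        de_table.to_csv(out / "de_results.tsv", sep="\t", index=False,
                        float_format="%.6g")
        top = de.top_degs(de_table, n=config.n_top, alpha=config.de_alpha,
                          rank_by=config.rank_by)
        (out / "top_degs.txt").write_text("\n".join(top) + "\n")

        stage = "normalization"
        tpm_all = prof.tpm(adjusted, ann)
        tpm_top = tpm_all.loc[top]
        tpm_top.to_csv(out / "tpm.tsv", sep="\t", index_label="gene_id",
                       float_format="%.6g")
        med = prof.median_profiles(tpm_top, meta)
        med.to_csv(out / "profiles_median.tsv", sep="\t", index_label="gene_id",
                   float_format="%.6g")
        pm = prof.zscore_profiles(med)
        pm.zscores.to_csv(out / "profiles_zscore.tsv", sep="\t",
                          index_label="gene_id", float_format="%.6g")

        stage = "gap-statistic"
        X = pm.values()
        gcfg = gapstat.GapConfig(kmax=config.kmax, B=config.gap_B,
                                 clusterer=config.gap_clusterer,
                                 restarts=config.gap_restarts,
                                 rule=config.selection_rule, seed=config.seed)
        curve = gapstat.gap_statistic(X, gcfg)
        curve.to_frame().to_csv(out / "gap_curve.tsv", sep="\t", index=False,
                                float_format="%.8g")
        K = (config.fixed_k if config.fixed_k is not None
             else gapstat.select_k(curve, config.selection_rule))

        stage = "clustering"
        assignment = gapstat.assign_clusters(X, K, pm.gene_ids,
                                             method=config.cluster_method,
                                             restarts=config.gap_restarts,
                                             seed=config.seed)
        assignment.labels.rename("cluster").to_csv(
            out / "clusters.tsv", sep="\t", index_label="gene_id")
        cluster_means = pm.zscores.groupby(assignment.labels).mean()
        cluster_means.to_csv(out / "cluster_profiles.tsv", sep="\t",
                             index_label="cluster", float_format="%.6g")

        stage = "enrichment"
        universe = enrich.default_universe(pm.gene_ids, sets)
        enr = enrich.enrich_clusters(
            assignment, universe, sets,
            min_set=config.min_set, max_set=config.max_set)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")

        stage = "discovery"
        targets = config.target_terms or _default_targets(sets)
        post_tps = [tp for tp, c in meta.condition_of_timepoint().items()
                    if c == "postnatal"]
        fclusters = discover.designate_functional_clusters(
            assignment, known, enr, targets, alpha=config.enrich_alpha, sets=sets,
            require_rising=config.require_rising, profiles=pm,
            postnatal_timepoints=post_tps)
        report = discover.predict_candidates(fclusters, assignment, known, evidence)
        report = discover.rank_candidates(report, pm, post_tps)
        _write_functional_clusters(fclusters, out / "functional_clusters.tsv")
        report.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False,
                                 float_format="%.6g")

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "config_sha256": config.content_hash(),
            "selected_k": int(K),
            "summary": report.summary,
            "artifacts": {name: _sha256(out / name) for name in ARTIFACTS},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    except Exception as e:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {e}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    return PipelineResult(output_dir=out, selected_k=int(K), report=report,
                          manifest=manifest)


def _default_targets(sets: gio.GeneSetCollection) -> list:
    # without user-specified target terms, every term is eligible; discovery
    # then hinges on known-gene membership plus enrichment alone
    return list(sets.sets)


def _write_functional_clusters(fclusters: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster\ttriggering_terms\tknown_members\n")
        for c, fc in sorted(fclusters.items()):
            fh.write(f"{c}\t{','.join(fc.triggering_terms)}\t"
                     f"{','.join(fc.known_members)}\n")
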