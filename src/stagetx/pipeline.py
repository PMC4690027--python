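"""End-to-end orchestration of the life-cycle transcriptome analysis.

``run_full_analysis`` composes the module operations in order: parse
inputs, build the non-redundant reference, apply the detection filter,
profile correlations (all detected contigs and the stage-specific subset),
cluster stages by UPGMA, select and enrich the two transitions, compare
their up/down frequencies, compute the assembly QC suite, and re-run the
expression analyses on depth-normalized counts as a robustness check.
Every output is stamped with the config hash, seeds and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .correlation import (
    build_correlation_profile,
    distance_matrix,
    upgma_dendrogram,
    write_correlation_table,
)
from .enrichment import (
    compare_transitions,
    enrich_transition,
    write_comparison_table,
    write_enrichment_table,
)
from .filters import (
    FilterConfig,
    apply_detection_filter,
    log_transform,
    select_stage_specific,
    select_transition_changed,
    write_selection_table,
)
from .formats import (
    newick_string,
    parse_annotation_table,
    parse_blast_tabular,
    parse_count_table,
    write_count_table,
    write_newick,
)
from .metrics import (
    build_nonredundant_reference,
    estimate_redundancy,
    normalize_by_subsampling,
    saturation_assessment,
    summarize_assembly,
    summarize_ohr,
    write_ohr_summary,
    write_redundancy_report,
    write_saturation_curve,
)
from .synthetic import make_saturation_evaluator

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts_path: str
    blast_path: str
    annotations_path: str
    output_dir: str
    stage_order: list[str] = field(default_factory=lambda: [
        "pre-competent larva", "post-larva", "adult",
    ])
    filters: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    evalue_cutoff: float = 1e-5
    seed: int = 0
    min_overlap: int = 1

    @property
    def transitions(self) -> list[tuple[str, str]]:
        return [tuple(self.stage_order[i:i + 2]) for i in range(len(self.stage_order) - 1)]

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fc = raw.pop("filters", {})
        return cls(filters=FilterConfig(**fc), **raw)


def _analyse_expression(matrix, cfg: PipelineConfig, tag: str, outdir: Path) -> dict:
    """Detection filter, correlation profiles, UPGMA, selections, per run."""
    filters = cfg.filters
    detected = apply_detection_filter(matrix, filters)
    results: dict = {"tag": tag, "n_input": matrix.n_contigs, "n_detected": detected.n_contigs}
    write_count_table(detected, outdir / f"{tag}_detected_counts.tsv")

    profile = log_transform(detected, filters)
    corr_all = build_correlation_profile(profile)
    write_correlation_table(corr_all, outdir / f"{tag}_correlations_all.tsv")
    results["correlations_all"] = corr_all

    stage_specific = select_stage_specific(detected, filters)
    ss_matrix = detected.subset(stage_specific)
    results["n_stage_specific"] = ss_matrix.n_contigs
    corr_ss = build_correlation_profile(log_transform(ss_matrix, filters))
    write_correlation_table(corr_ss, outdir / f"{tag}_correlations_stage_specific.tsv")
    results["correlations_stage_specific"] = corr_ss

    dist = distance_matrix(corr_ss)
    dist.to_csv(outdir / f"{tag}_distances.tsv", sep="\t")
    tree = upgma_dendrogram(dist)
    write_newick(tree, outdir / f"{tag}_upgma.nwk")
    results["dendrogram"] = tree

    selections = [
        select_transition_changed(detected, tr, filters) for tr in cfg.transitions
    ]
    write_selection_table(
        outdir / f"{tag}_selections.tsv", stage_specific=stage_specific, transitions=selections
    )
    results["stage_specific_ids"] = stage_specific
    results["transition_selections"] = selections
    return results


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the report bundle as a dict of artifacts."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("stagetx")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        return _run(cfg, outdir)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, outdir: Path) -> dict:
    header = {
        "stagetx_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "min_reads": cfg.filters.min_reads,
        "fold_threshold": cfg.filters.fold_threshold,
        "pseudocount": cfg.filters.pseudocount,
        "alpha": cfg.alpha,
        "evalue_cutoff": cfg.evalue_cutoff,
        "stage_order": cfg.stage_order,
        "note": "fold rules use pseudocounted raw-count ratios (arithmetic mean of "
                "the other two stages); normalization thins count columns without "
                "replacement as a stand-in for raw-read resampling",
    }
    with open(outdir / "run_header.json", "w") as fh:
        json.dump(header, fh, indent=2)

    stage = "parse inputs"
    try:
        matrix = parse_count_table(cfg.counts_path, expected_stages=cfg.stage_order)
        hits = parse_blast_tabular(cfg.blast_path, evalue_cutoff=cfg.evalue_cutoff)
        annotations = parse_annotation_table(cfg.annotations_path)

        stage = "non-redundant reference"
        nonredundant = build_nonredundant_reference(
            hits, set(matrix.contig_ids), min_overlap=cfg.min_overlap
        )
        matrix_nr = matrix.subset(nonredundant)
        logger.info("non-redundant reference: %d of %d contigs", matrix_nr.n_contigs,
                    matrix.n_contigs)

        stage = "expression analyses"
        expr = _analyse_expression(matrix_nr, cfg, "original", outdir)

        stage = "GO enrichment"
        reference = nonredundant & annotations.annotated_contigs
        enrichments = []
        for sel in expr["transition_selections"]:
            records = enrich_transition(sel, annotations, reference, alpha=cfg.alpha)
            tag = f"{sel.transition[0]}_{sel.transition[1]}".replace(" ", "_")
            write_enrichment_table(records, outdir / f"enrichment_{tag}.tsv")
            enrichments.append(records)
        comparison = compare_transitions(enrichments[0], enrichments[1])
        write_comparison_table(comparison, outdir / "transition_comparison.tsv")

        stage = "assembly metrics"
        lengths = hits.records["qlen"].tolist()
        assembly = summarize_assembly(lengths)
        ohr = summarize_ohr(hits)
        write_ohr_summary(ohr, outdir / "ohr_summary.tsv")
        redundancy = estimate_redundancy(hits, min_overlap=cfg.min_overlap)
        write_redundancy_report(redundancy, outdir / "redundancy.tsv")
        length_by_contig = dict(zip(hits.records["qseqid"], hits.records["qlen"]))
        pool = matrix.counts.loc[
            [c for c in matrix.contig_ids if c in length_by_contig]
        ].sum(axis=1)
        saturation = saturation_assessment(
            pool, make_saturation_evaluator(length_by_contig), seed=cfg.seed
        )
        write_saturation_curve(saturation, outdir / "saturation_curve.tsv")
        with open(outdir / "assembly_summary.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in asdict(assembly).items():
                fh.write(f"{k}\t{v}\n")

        stage = "normalization robustness"
        normalized = normalize_by_subsampling(matrix_nr, seed=cfg.seed)
        write_count_table(normalized, outdir / "normalized_counts.tsv")
        expr_norm = _analyse_expression(normalized, cfg, "normalized", outdir)
        delta_r = {
            (a.stage_a, a.stage_b): abs(a.r - b.r)
            for a, b in zip(expr["correlations_stage_specific"],
                            expr_norm["correlations_stage_specific"])
        }
        same_topology = (
            newick_topology(expr["dendrogram"]) == newick_topology(expr_norm["dendrogram"])
        )
        with open(outdir / "normalization_comparison.tsv", "w") as fh:
            fh.write("stage_a\tstage_b\tabs_delta_r\n")
            for (a, b), d in delta_r.items():
                fh.write(f"{a}\t{b}\t{d:.6g}\n")
            fh.write(f"# identical UPGMA topology: {same_topology}\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "header": header,
        "expression": expr,
        "enrichments": enrichments,
        "comparison": comparison,
        "assembly": assembly,
        "ohr": ohr,
        "redundancy": redundancy,
        "saturation": saturation,
        "normalized_expression": expr_norm,
        "delta_r": delta_r,
        "same_topology": same_topology,
    }


def newick_topology(tree) -> frozenset:
    """Topology signature: the set of leaf sets of internal nodes."""
    return frozenset(leaves for leaves, _h in tree.merge_order())
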