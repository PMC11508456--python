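"""End-to-end orchestration of the five analysis stages.

``run_all`` executes univariate -> PLS-DA/RFE -> merge -> network -> ORA on
a configured input quadruple (abundance TSV, annotation TSV, MITAB, GMT),
writes each stage's tabular output into the output directory, and returns a
manifest recording every count, the parameters, the seed and a SHA-256
checksum per output file — so two runs with the same config and seed are
verifiably identical and the stage-by-stage count chain is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .errors import ProteomarkError
from .matrix import AbundanceMatrix
from .merge import collapse_isoforms, inherit_statistics, union_with_stats
from .network import (
    annotate_directions,
    filter_records,
    prune_to_input,
    read_mitab,
    write_edge_list,
    write_graphml,
    write_node_table,
)
from .ora import affinity_propagation_reduce, fisher_ora, read_gmt
from .splsda import rfe
from .univariate import differential_abundance, select_univariate

logger = logging.getLogger("proteomark")


@dataclass
class PipelineConfig:
    """Paths and stage parameters of a full pipeline run.

    Defaults reproduce the reference configuration: FC gate 1.3 on the
    ratio scale with alpha 0.05, two PLS-DA components with a 5% RFE
    target, human protein-only interactions, ORA FDR cutoff 0.05.
    """

    abundance: str = "abundance.tsv"
    annotation: str = "annotation.tsv"
    mitab: str = "interactome.mitab"
    gmt: str = "gene_sets.gmt"
    out_dir: str = "results"
    # univariate
    fc_threshold: float = 1.3
    fc_scale: str = "ratio"
    alpha: float = 0.05
    pseudocount: float | None = None
    # splsda
    n_components: int = 2
    target_fraction: float = 0.05
    chunk: int = 1
    keep_per_component: int | None = None
    # network
    taxid: int = 9606
    protein_only: bool = True
    # ora
    ora_fdr_cutoff: float = 0.05
    ap_damping: float = 0.5
    ap_preference: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Stage failures abort with the stage name and cause; outputs written
    before the failure are flagged as partial in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
        "outputs": {},
        "partial": False,
    }
    stage = "load"
    try:
        matrix = AbundanceMatrix.from_tsv(config.abundance, config.annotation)

        # -- stage 1: univariate differential abundance -----------------------
        stage = "univariate"
        uni = differential_abundance(
            matrix,
            fc_threshold=config.fc_threshold,
            alpha=config.alpha,
            pseudocount=config.pseudocount,
            fc_scale=config.fc_scale,
        )
        summary = select_univariate(uni, config.fc_threshold, config.alpha, config.fc_scale)
        uni_out = uni.copy()
        uni_out.index.name = "accession"
        uni_out.to_csv(out / "univariate.tsv", sep="\t", float_format="%.8g")
        manifest["stages"]["univariate"] = {
            "n_proteins": matrix.n_proteins,
            "n_selected": summary.n_selected,
            "n_up": summary.n_up,
            "n_down": summary.n_down,
        }
        logger.info("univariate: %d/%d selected (%d up, %d down)",
                    summary.n_selected, matrix.n_proteins, summary.n_up, summary.n_down)

        # -- stage 2: PLS-DA with recursive feature elimination ---------------
        stage = "splsda"
        trace = rfe(
            matrix,
            n_components=config.n_components,
            target_fraction=config.target_fraction,
            chunk=config.chunk,
            keep_per_component=config.keep_per_component,
        )
        trace.to_frame().to_csv(out / "rfe_trace.tsv", sep="\t", index=False, float_format="%.8g")
        scores = pd.DataFrame(
            trace.final_model.scores,
            index=trace.final_model.sample_ids,
            columns=[f"component_{k + 1}" for k in range(trace.final_model.n_components)],
        )
        scores.index.name = "sample_id"
        scores.to_csv(out / "splsda_scores.tsv", sep="\t", float_format="%.8g")
        manifest["stages"]["splsda"] = {
            "n_retained": trace.n_retained,
            "variance_explained": [float(v) for v in trace.variance_explained_final],
        }
        logger.info("splsda: RFE retained %d proteins", trace.n_retained)

        # -- stage 3: merge and isoform collapse ------------------------------
        stage = "merge"
        stats = union_with_stats(summary.selected, trace.retained)
        bases, n_iso = collapse_isoforms(stats.union)
        base_stats = inherit_statistics(stats.union, uni)
        base_out = base_stats.reset_index()
        base_out.to_csv(out / "merged_candidates.tsv", sep="\t", index=False, float_format="%.8g")
        venn = {
            "n_univariate": stats.n_a,
            "n_multivariate": stats.n_b,
            "n_common": stats.n_common,
            "n_union": stats.n_union,
            "n_isoform_entries": n_iso,
            "n_unique_bases": len(bases),
        }
        (out / "venn_counts.json").write_text(json.dumps(venn, indent=2))
        manifest["stages"]["merge"] = venn
        logger.info("merge: %d union (%d common) -> %d unique bases (%d isoform entries)",
                    stats.n_union, stats.n_common, len(bases), n_iso)

        # -- stage 4: PPI network ---------------------------------------------
        stage = "network"
        records = read_mitab(config.mitab)
        records = filter_records(records, taxid=config.taxid, protein_only=config.protein_only)
        graph = prune_to_input(records, bases)
        direction_counts = annotate_directions(graph, base_stats)
        write_edge_list(graph, out / "network_edges.tsv")
        write_node_table(graph, out / "network_nodes.tsv")
        write_graphml(graph, out / "network.graphml")
        manifest["stages"]["network"] = {
            "n_records_kept": len(records),
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            **direction_counts,
        }
        logger.info("network: %d nodes, %d edges (%d up, %d down)",
                    graph.number_of_nodes(), graph.number_of_edges(),
                    direction_counts["n_up"], direction_counts["n_down"])

        # -- stage 5: over-representation analysis ----------------------------
        stage = "ora"
        collection = read_gmt(config.gmt)
        node_list = sorted(graph.nodes)
        if node_list:
            enrichment = fisher_ora(node_list, collection)
            n_sig = int((enrichment["fdr"] <= config.ora_fdr_cutoff).sum())
            if n_sig:
                enrichment = affinity_propagation_reduce(
                    enrichment,
                    collection,
                    fdr_cutoff=config.ora_fdr_cutoff,
                    damping=config.ap_damping,
                    preference=config.ap_preference,
                )
                n_ex = int(enrichment["is_exemplar"].sum())
            else:
                enrichment["is_exemplar"] = False
                n_ex = 0
            enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.8g")
            manifest["stages"]["ora"] = {
                "n_sets": len(collection.sets),
                "n_significant": n_sig,
                "n_exemplars": n_ex,
            }
            logger.info("ora: %d/%d sets significant, %d exemplars",
                        n_sig, len(collection.sets), n_ex)
        else:
            manifest["stages"]["ora"] = {
                "n_sets": len(collection.sets),
                "n_significant": 0,
                "n_exemplars": 0,
                "skipped": "empty network",
            }
            logger.info("ora: skipped (empty network)")
    except ProteomarkError as exc:
        manifest["partial"] = True
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _finalize(out, manifest)
        raise ProteomarkError(f"stage {stage!r} failed: {exc}") from exc

    _finalize(out, manifest)
    return manifest


def _finalize(out: Path, manifest: dict) -> None:
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
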