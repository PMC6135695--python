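"""End-to-end orchestration of the epigenotyping cascade.

Stages: FFPE concordance (optional) -> promoter / high-CpG gene selection ->
variance filter -> four-epigenotype clustering -> marker extraction ->
FAP-vs-sporadic marker comparisons -> FAP two-subtype reclustering and
mutation/location/histology associations.  A RunManifest records the config,
seed, input digests and per-stage probe/sample counts (counts are
non-increasing through the filter cascade).  Outputs are plain TSV/Newick/
JSON with no timestamps, so a rerun with the same inputs and seed is
byte-identical; timings go to the stderr log only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .association import AssociationResult, associate
from .clustering import (EpigenotypeAssignment, assign_epigenotypes, linkage_to_newick,
                         recluster_subset)
from .io import BetaMatrix, InputError, PipelineConfig
from .markers import (GroupComparison, MarkerSets, compare_marker_methylation,
                      extract_marker_genes, per_me_means)
from .probe_filtering import concordant_probes, high_cpg_genes, variance_filter

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("epigenotyper")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the manifest accumulated so far."""

    def __init__(self, stage: str, message: str, manifest: dict):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.manifest = manifest


@dataclasses.dataclass
class PipelineResult:
    assignment: EpigenotypeAssignment
    marker_sets: MarkerSets
    comparisons: list[GroupComparison]
    associations: list[AssociationResult]
    fap_assignment: EpigenotypeAssignment | None
    analysis_matrix: pd.DataFrame          # genes x samples after the full cascade
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.assignment.to_frame().to_csv(out / "assignments.tsv", sep="\t")
        markers = self.marker_sets.classes.to_frame().join(self.marker_sets.mean_table)
        markers.to_csv(out / "markers.tsv", sep="\t", float_format="%.6g")
        comp = pd.DataFrame([dataclasses.asdict(c) for c in self.comparisons])
        comp.to_csv(out / "comparisons.tsv", sep="\t", index=False, float_format="%.6g")
        assoc = pd.DataFrame([a.to_dict() for a in self.associations])
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.6g")
        (out / "sample_dendrogram.nwk").write_text(
            linkage_to_newick(self.assignment.sample_linkage, self.assignment.sample_order) + "\n")
        (out / "probe_dendrogram.nwk").write_text(
            linkage_to_newick(self.assignment.probe_linkage, self.assignment.probes) + "\n")
        if self.fap_assignment is not None:
            self.fap_assignment.to_frame().to_csv(out / "fap_assignments.tsv", sep="\t")
            (out / "fap_dendrogram.nwk").write_text(
                linkage_to_newick(self.fap_assignment.sample_linkage,
                                  self.fap_assignment.sample_order) + "\n")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig,
                 beta: BetaMatrix,
                 annotation: pd.DataFrame,
                 metadata: pd.DataFrame,
                 pairs: Sequence[tuple[pd.Series, pd.Series]] | None = None,
                 out_dir: str | Path | None = None,
                 input_paths: dict[str, str] | None = None,
                 min_cluster_size: int | None = 2) -> PipelineResult:
    """Run the full cascade on in-memory inputs; optionally write the output set.

    ``pairs`` are frozen/FFPE beta-vector pairs enabling the concordance
    stage.  Deterministic for fixed inputs + config.
    """
    manifest: dict = {
        "tool": "epigenotyper",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {name: _digest(p) for name, p in (input_paths or {}).items()},
        "stages": {},
    }

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                elapsed = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s failed after %.2fs: %s", name, elapsed, exc)
                    raise PipelineError(name, str(exc), manifest) from exc
                logger.info("stage %s done in %.2fs", name, elapsed)
                return False

        return _Stage()

    values = beta.values
    manifest["stages"]["input"] = {"probes": int(values.shape[0]),
                                   "samples": int(values.shape[1])}

    if pairs is not None:
        with stage("concordance"):
            result = concordant_probes(pairs, threshold=config.delta_beta_threshold)
            keep = [p for p in values.index if p in result.intersection]
            values = values.loc[keep]
            manifest["stages"]["concordance"] = {
                "per_pair_counts": result.per_pair_counts,
                "probes": int(values.shape[0])}

    with stage("promoter_high_cpg"):
        ann = annotation.loc[annotation.index.isin(values.index)]
        if ann.empty:
            raise InputError("no annotation rows for the current probe set")
        genes = high_cpg_genes(ann, threshold=config.cpg_score_threshold)
        probe_to_gene = dict(zip(genes["probe_id"], genes.index))
        keep = [p for p in values.index if p in probe_to_gene]
        values = values.loc[keep].rename(index=probe_to_gene)
        manifest["stages"]["promoter_high_cpg"] = {"probes": int(values.shape[0]),
                                                   "genes": int(values.shape[0])}

    with stage("variance_filter"):
        variable = variance_filter(values, sd_threshold=config.sd_threshold)
        values = values.loc[variable]
        manifest["stages"]["variance_filter"] = {"probes": int(values.shape[0])}

    with stage("clustering"):
        assignment = assign_epigenotypes(values, metadata=metadata,
                                         k=config.n_epigenotypes,
                                         min_cluster_size=min_cluster_size)
        counts = assignment.labels.value_counts().to_dict()
        manifest["stages"]["clustering"] = {
            "samples": int(assignment.labels.size),
            "outliers": len(assignment.outliers),
            "epigenotype_counts": {k: int(v) for k, v in sorted(counts.items())}}

    with stage("marker_extraction"):
        sporadic = [s for s in assignment.labels.index
                    if metadata.loc[s, "cohort"] == "sporadic_CRC"]
        mean_table = per_me_means(values, assignment, samples=sporadic)
        marker_sets = extract_marker_genes(mean_table, threshold=config.marker_beta_threshold)
        manifest["stages"]["marker_extraction"] = {
            k: int(v) for k, v in marker_sets.counts().items()}

    comparisons: list[GroupComparison] = []
    with stage("comparisons"):
        fap_ime = [s for s in assignment.samples_with_label("IME")
                   if metadata.loc[s, "cohort"] == "FAP"]
        sporadic_ime = [s for s in assignment.samples_with_label("IME")
                        if metadata.loc[s, "cohort"] == "sporadic_CRC"]
        if fap_ime and sporadic_ime:
            for cls in ("high", "intermediate", "common", "normal"):
                genes_cls = sorted(marker_sets[cls])
                if not genes_cls:
                    continue
                comparisons.append(compare_marker_methylation(
                    values, genes_cls, fap_ime, sporadic_ime,
                    group_a="FAP_IME", group_b="sporadic_IME", marker_class=cls))
        manifest["stages"]["comparisons"] = {"n": len(comparisons)}

    fap_assignment = None
    associations: list[AssociationResult] = []
    fap_samples = [s for s in values.columns if metadata.loc[s, "cohort"] == "FAP"]
    if len(fap_samples) >= 4:
        with stage("fap_subtypes"):
            fap_assignment = recluster_subset(values, fap_samples, k=2, min_cluster_size=2)
            manifest["stages"]["fap_subtypes"] = {
                "samples": int(fap_assignment.labels.size),
                "outliers": len(fap_assignment.outliers),
                "counts": {k: int(v) for k, v in
                           sorted(fap_assignment.labels.value_counts().items())}}
        with stage("associations"):
            for variable in ("kras_status", "location", "histology"):
                try:
                    associations.append(associate(fap_assignment, metadata, variable))
                except InputError as exc:
                    logger.info("association %s skipped: %s", variable, exc)
            manifest["stages"]["associations"] = {"n": len(associations)}

    result = PipelineResult(assignment=assignment, marker_sets=marker_sets,
                            comparisons=comparisons, associations=associations,
                            fap_assignment=fap_assignment, analysis_matrix=values,
                            manifest=manifest)
    if out_dir is not None:
        result.write(out_dir)
    return result
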