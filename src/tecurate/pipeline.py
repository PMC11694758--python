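"""Orchestration of the full curation run.

Stage order: preprocess -> redundancy reduction -> consensus extension
(with subfamily splitting) -> false-positive filtering -> homology
identification -> structural check / unknown rescue -> final redundancy
reduction -> write.  Three automation modes: ``fully_automatic`` keeps
complete and ``_inc`` records, ``semiautomatic`` keeps complete records
and routes ``_inc`` ones to an inspection report, ``manual_report`` emits
the inspection report for everything and no curated library.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .benchmark import (
    compute_metrics,
    evaluate_family_quality,
    quality_summary,
    write_family_labels,
)
from .classify import (
    ClassificationDecision,
    check_structure,
    classify_unknown,
    compute_features,
    homology_assign,
    write_decision_table,
)
from .extension import ExtensionState, extend_consensus, polish_consensus, split_subfamilies, write_extension_report
from .filters import filter_false_positives
from .library_io import (
    normalize_nomenclature,
    parse_library,
    read_genome,
    write_exclusion_log,
    write_library,
)
from .models import ConsensusRecord, LibraryDocument, Order, Status
from .profiles import Profile, builtin_te_profiles, read_profiles
from .redundancy import cluster_library, select_representatives, write_cluster_table
from .search import SubjectIndex


@dataclass
class PipelineConfig:
    """All tunables of the curation pipeline (defaults mirror the tool's
    standard settings)."""

    identity_threshold: float = 0.95
    coverage_threshold: float = 0.98
    extension_iterations: int = 16
    flank_bp: int = 500
    extension_evalue: float = 1e-20
    max_copies: int = 40
    min_flf: int = 1
    ssr_max: float = 0.60
    flf_coverage: float = 0.94
    profile_evalue: float = 10.0
    rule_classified: tuple[int, float, float] = (80, 0.80, 0.80)
    rule_unknown: tuple[int, float, float] = (70, 0.70, 0.70)
    short_copy_bp: int = 100
    chimera_rule: tuple[float, float] = (0.80, 0.50)
    subfamily_cutoff: float = 0.10
    subfamily_min_members: int = 5
    mode: str = "fully_automatic"  # fully_automatic | semiautomatic | manual_report
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fully_automatic", "semiautomatic", "manual_report"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.rule_classified = tuple(self.rule_classified)  # type: ignore[assignment]
        self.rule_unknown = tuple(self.rule_unknown)  # type: ignore[assignment]
        self.chimera_rule = tuple(self.chimera_rule)  # type: ignore[assignment]

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunManifest:
    config_hash: str = ""
    version: str = ""
    stage_counts: dict[str, int] = field(default_factory=dict)
    removals_by_reason: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _as_document(library) -> LibraryDocument:
    if isinstance(library, LibraryDocument):
        return copy.deepcopy(library)  # never mutate the caller's document
    return parse_library(library)


def _as_genome_index(genome) -> SubjectIndex:
    if isinstance(genome, SubjectIndex):
        return genome
    if isinstance(genome, dict):
        return SubjectIndex(genome)
    return SubjectIndex(read_genome(genome))


def _as_profiles(profiles) -> list[Profile]:
    if profiles is None:
        return []
    if isinstance(profiles, (str, Path)):
        return read_profiles(profiles)
    return list(profiles)


def run_pipeline(
    library,
    genome,
    gene_profiles=None,
    rrna_profiles=None,
    reference_db=None,
    config: PipelineConfig | None = None,
    outdir: str | Path = "tecurate_out",
) -> tuple[LibraryDocument, RunManifest]:
    """Curate a raw TE library against its genome.

    ``library``/``reference_db`` accept paths or LibraryDocuments,
    ``genome`` a path, dict or prebuilt index, profile sets paths or
    Profile lists.  Returns the curated library document and the run
    manifest; stage outputs land in ``outdir``.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)

    # stage 1: preprocessing
    doc = _as_document(library)
    manifest.stage_counts["input"] = len(doc.records)
    doc = normalize_nomenclature(doc)
    manifest.outputs["exclusion_log"] = str(
        write_exclusion_log(doc, outdir / "excluded.tsv")
    )
    manifest.stage_counts["after_preprocess"] = len(doc.kept())

    genome_index = _as_genome_index(genome)
    gene_profiles = _as_profiles(gene_profiles)
    rrna_profiles = _as_profiles(rrna_profiles)
    te_profiles = builtin_te_profiles()
    refdb = _as_document(reference_db) if reference_db is not None else LibraryDocument()

    # stage 2: redundancy reduction (first pass)
    kept = doc.kept()
    if kept:
        clusters = cluster_library(
            kept, config.identity_threshold, config.coverage_threshold
        )
        select_representatives(clusters, doc)
        manifest.outputs["clusters_initial"] = str(
            write_cluster_table(clusters, outdir / "clusters_initial.tsv")
        )
    manifest.stage_counts["after_redundancy"] = len(doc.kept())

    # stage 3: consensus extension + subfamily splitting
    states: dict[str, ExtensionState] = {}
    new_records: list[ConsensusRecord] = []
    for record in doc.records:
        if not record.is_kept():
            new_records.append(record)
            continue
        state = extend_consensus(
            record.sequence,
            genome_index,
            max_iterations=config.extension_iterations,
            flank_bp=config.flank_bp,
            max_evalue=config.extension_evalue,
            max_copies=config.max_copies,
        )
        states[record.id] = state
        subfamilies = (
            split_subfamilies(
                state.msa,
                distance_cutoff=config.subfamily_cutoff,
                min_members=config.subfamily_min_members,
            )
            if state.msa is not None
            else []
        )
        if len(subfamilies) > 1:
            record.note("extension", f"split into {len(subfamilies)} subfamilies")
            for k, sub in enumerate(subfamilies, 1):
                sub_rec = ConsensusRecord(
                    f"{record.id}_sub{k}",
                    polish_consensus(sub),
                    record.classification,
                    provenance=list(record.provenance),
                )
                sub_rec.note(
                    "extension", f"subfamily {k}/{len(subfamilies)} of {record.id}"
                )
                new_records.append(sub_rec)
        else:
            record.sequence = state.consensus
            record.note(
                "extension",
                f"{state.iteration} iterations, ends "
                f"{'closed' if state.left_done and state.right_done else 'open'}",
            )
            new_records.append(record)
    doc.records = new_records
    manifest.outputs["extension_report"] = str(
        write_extension_report(states, outdir / "extension.tsv")
    )
    manifest.stage_counts["after_extension"] = len(doc.kept())

    # stage 4: false positive filtering
    filter_false_positives(
        doc,
        genome_index,
        gene_profiles,
        rrna_profiles,
        min_flf=config.min_flf,
        ssr_max=config.ssr_max,
        flf_coverage=config.flf_coverage,
        profile_evalue=config.profile_evalue,
        copy_evalue=config.extension_evalue,
        report_path=outdir / "false_positives.tsv",
    )
    manifest.outputs["false_positive_report"] = str(outdir / "false_positives.tsv")
    manifest.stage_counts["after_false_positive_filter"] = len(doc.kept())

    # stages 5-6: homology identification, structural check, unknown rescue
    decisions: dict[str, ClassificationDecision] = {}
    inspection_rows: list[tuple] = []
    for record in doc.records:
        if not record.is_kept():
            continue
        decision = (
            homology_assign(record, refdb, rule=config.rule_classified)
            if refdb.records
            else None
        )
        if decision is not None:
            record.classification = decision.final
            record.status = Status.KEPT
        else:
            features = compute_features(
                record, te_profiles, profile_evalue=config.profile_evalue
            )
            if record.classification.order is not Order.UNCLASSIFIED:
                decision = check_structure(record, features)
                if decision.step == "structural_pass":
                    record.status = Status.KEPT
                else:
                    record.mark_incomplete(
                        "classification", "expected structural features missing"
                    )
            else:
                decision = classify_unknown(
                    record, refdb, features, rule=config.rule_unknown
                )
                record.classification = decision.final
                record.status = Status.KEPT
            inspection_rows.append(
                (
                    record.id,
                    len(record.sequence),
                    decision.step,
                    decision.final.label,
                    decision.evidence,
                )
            )
        record.note("classification", f"{decision.step}: {decision.final.label}")
        decisions[record.id] = decision
    manifest.outputs["decisions"] = str(
        write_decision_table(decisions, outdir / "decisions.tsv")
    )
    manifest.stage_counts["after_classification"] = len(doc.kept())
    manifest.stage_counts["incomplete"] = sum(
        1 for r in doc.records if r.status is Status.INCOMPLETE
    )

    # stage 7: final redundancy reduction
    kept = doc.kept()
    if kept:
        clusters = cluster_library(
            kept, config.identity_threshold, config.coverage_threshold
        )
        select_representatives(clusters, doc)
        manifest.outputs["clusters_final"] = str(
            write_cluster_table(clusters, outdir / "clusters_final.tsv")
        )
    manifest.stage_counts["curated"] = len(doc.kept())

    # stage 8: write outputs per mode
    if config.mode in ("semiautomatic", "manual_report"):
        rows = inspection_rows if config.mode == "semiautomatic" else [
            (r.id, len(r.sequence), r.status.value, r.classification.label, "")
            for r in doc.records
        ]
        with open(outdir / "inspection.tsv", "w") as fh:
            fh.write("id\tlength\tstep\tclassification\tevidence\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        manifest.outputs["inspection"] = str(outdir / "inspection.tsv")
    if config.mode != "manual_report":
        curated_path = write_library(
            doc,
            outdir / "curated_library.fa",
            include_incomplete=(config.mode == "fully_automatic"),
        )
        manifest.outputs["curated_library"] = str(curated_path)
    if not doc.kept():
        warnings.warn("curated library is empty")
        manifest.notes.append("curated library is empty")

    for record in doc.records:
        if record.status is Status.RAW:
            record.status = Status.KEPT
    reasons: dict[str, int] = {}
    for record in doc.removed():
        reasons[record.removal_reason.value] = reasons.get(
            record.removal_reason.value, 0
        ) + 1
    manifest.removals_by_reason = dict(sorted(reasons.items()))
    manifest.write(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return doc, manifest


def run_benchmark(
    reference_lib,
    test_lib,
    annotations: list | None = None,
    genome_bp: int | None = None,
    mobilome_target_bp: int | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Library-level (family quality) and, when annotations are supplied,
    annotation-level metrics as one JSON-ready dict."""
    reference_lib = _as_document(reference_lib)
    test_lib = _as_document(test_lib)
    labels = evaluate_family_quality(reference_lib, test_lib)
    result: dict = {
        "family_quality": quality_summary(labels),
        "n_reference_families": len(reference_lib.kept()),
        "n_test_sequences": len(test_lib.kept()),
    }
    if annotations:
        if genome_bp is None:
            raise ValueError("genome_bp required with annotations")
        metrics = compute_metrics(
            annotations, genome_bp, mobilome_target_bp=mobilome_target_bp
        )
        result["annotation_metrics"] = metrics.to_dict()
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
        label_path = out_path.with_suffix(".labels.tsv")
        write_family_labels(labels, label_path)
    return result
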