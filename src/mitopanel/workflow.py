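"""End-to-end pipeline orchestration.

Runs build-panel -> simulate-chip -> impute -> assign-haplogroups ->
evaluate as one reproducible run driven by a plain YAML config.  Each
stage writes its outputs into the run directory and the run manifest
records parameters and a sha256 checksum for every file, so re-running
an identical config reproduces identical checksums (every stage is
deterministic).  Orchestration is native — no external workflow engine
— and each stage remains independently invocable through the library
or CLI.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .alignment import (
    DEFAULT_AMBIGUOUS_THRESHOLD,
    DEFAULT_GAP_THRESHOLD,
    project_to_rcrs,
    qc_filter,
    read_msa,
)
from .chip_sim import mask_to_chip, parse_strand_file
from .evaluation import evaluate_run
from .haplogroup import load_haplogroup_table
from .imputation import DEFAULT_INFO_THRESHOLD, DEFAULT_K_HAP, HaplotypeImputer, result_to_panel
from .panel import extract_variant_sites
from .panel_io import typed_to_panel, write_gen, write_impute2, write_map, write_vcf


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    msa: str
    rcrs_id: str
    strand_file: str
    targets_file: str
    haplogroup_table: str
    out_dir: str
    ambiguous_threshold: int = DEFAULT_AMBIGUOUS_THRESHOLD
    gap_threshold: int = DEFAULT_GAP_THRESHOLD
    maf_threshold: float = 0.001
    k_hap: int = DEFAULT_K_HAP
    copying_error: float | str = "auto"
    info_threshold: float = DEFAULT_INFO_THRESHOLD
    min_score: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        for name in ("msa", "strand_file", "targets_file", "haplogroup_table"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"config {name}: no such file {path!r}")
        if not 1 <= self.ambiguous_threshold or not 1 <= self.gap_threshold:
            raise ValueError("QC thresholds must be >= 1")
        if not 0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5)")
        if self.k_hap < 1:
            raise ValueError("k_hap must be >= 1")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StageRecord:
    name: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute all five stages and return the run manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    stages: list[StageRecord] = []

    def _record(name: str, paths: list[str]) -> None:
        stages.append(
            StageRecord(name=name, outputs={p: _sha256(p) for p in paths})
        )

    out = lambda name: os.path.join(config.out_dir, name)

    # stage 1: build panel
    try:
        aln = project_to_rcrs(read_msa(config.msa, rcrs_id=config.rcrs_id))
        aln, qc_report = qc_filter(
            aln, config.ambiguous_threshold, config.gap_threshold
        )
        truth_panel = extract_variant_sites(aln)
        write_vcf(truth_panel, out("panel.vcf"))
        write_impute2(truth_panel, out("panel"), collapse=True)
        write_map(truth_panel, out("panel.map"))
        qc_report.table.to_csv(out("qc_report.tsv"), sep="\t", index=False)
        _record(
            "build_panel",
            [out("panel.vcf"), out("panel.hap"), out("panel.legend"),
             out("panel.sample"), out("panel.map"), out("qc_report.tsv")],
        )
    except Exception as exc:
        raise PipelineError("build_panel", exc) from exc

    # stage 2: in-silico chip
    try:
        chip = parse_strand_file(config.strand_file)
        with open(config.targets_file) as fh:
            target_ids = [line.strip() for line in fh if line.strip()]
        typed = mask_to_chip(truth_panel, chip, target_ids)
        write_vcf(typed_to_panel(typed, truth_panel), out("typed.vcf"))
        _record("simulate_chip", [out("typed.vcf")])
    except Exception as exc:
        raise PipelineError("simulate_chip", exc) from exc

    # stage 3: imputation
    try:
        reference_ids = [s for s in truth_panel.sample_ids if s not in set(target_ids)]
        reference = truth_panel.subset_samples(reference_ids)
        imputer = HaplotypeImputer(
            k_hap=config.k_hap,
            copying_error=config.copying_error,
            info_threshold=config.info_threshold,
            maf_threshold=config.maf_threshold,
        )
        result = imputer.fit(reference).predict(typed)
        write_gen(result, out("imputed.gen"))
        write_vcf(result_to_panel(result), out("imputed.vcf"))
        _record("impute", [out("imputed.gen"), out("imputed.vcf")])
    except Exception as exc:
        raise PipelineError("impute", exc) from exc

    # stage 4: haplogroup assignment
    try:
        table = load_haplogroup_table(config.haplogroup_table)
        from .haplogroup import call_haplogroup  # local to keep import cycle-free

        calls_path = out("haplogroups.tsv")
        with open(calls_path, "w") as fh:
            fh.write("#sample_id\tstage\tlabel\tscore\tn_typed_defining\n")
            for sid in target_ids:
                for stage_name, amap in (
                    ("truth", truth_panel.allele_map(sid)),
                    ("masked", typed.allele_map(sid)),
                    ("imputed", result.allele_map(sid)),
                ):
                    call = call_haplogroup(amap, table, sid, config.min_score)
                    fh.write(
                        f"{sid}\t{stage_name}\t{call.label or 'NA'}"
                        f"\t{call.score:.4f}\t{call.n_typed_defining}\n"
                    )
        _record("assign_haplogroups", [calls_path])
    except Exception as exc:
        raise PipelineError("assign_haplogroups", exc) from exc

    # stage 5: evaluation
    try:
        from .haplogroup import call_samples

        truth_calls = call_samples(
            {sid: truth_panel.allele_map(sid) for sid in target_ids},
            table, config.min_score,
        )
        truth_labels = {
            sid: call.label for sid, call in truth_calls.items() if call.label
        }
        report = evaluate_run(
            truth_panel, truth_labels, typed, result, table, config.min_score
        )
        report.site_mcc.to_csv(out("site_mcc.tsv"), sep="\t", index=False)
        summary = {
            "mu_mcc": report.mu_mcc,
            "mcc_ci": list(report.mcc_ci),
            **report.concordance,
            "improvement_macro": report.improvement_macro,
            "improvement_full": report.improvement_full,
        }
        with open(out("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        _record("evaluate", [out("site_mcc.tsv"), out("summary.json")])
    except Exception as exc:
        raise PipelineError("evaluate", exc) from exc

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "stages": [asdict(s) for s in stages],
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
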