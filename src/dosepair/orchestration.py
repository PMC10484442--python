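"""End-to-end pipeline: generate -> ADD -> episodes -> fit -> posthoc -> annotate.

A single seeded configuration reproduces the whole synthetic study: one
global seed fans out to per-stage seeds through a fixed SeedSequence
derivation, so each stage is also independently reproducible.  Every
stage writes TSV outputs into the run directory, and a run manifest
records versions, seeds, per-stage row counts and a content digest of
every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes_dosage_model import DownsampleConfig, ModelSpec, fit_all_index_drugs
from .clinical_posthoc import run_posthoc
from .ddi_pk_annotation import annotate_pairs, compare_groups
from .dosage_add import compute_add_frame
from .episode_builder import apply_selection_filters, build_episodes, merge_readmissions
from .synthetic_cohort import CohortConfig, generate_cohort, read_cohort_tables, write_cohort

logger = logging.getLogger(__name__)

_STAGES = ["generate", "add", "episodes", "fit", "posthoc", "annotate"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    run_dir: str = "run"
    seed: int = 0
    # selection thresholds
    min_index_patients: int = 50
    min_pair_patients: int = 50
    one_time_max_fraction: float = 0.70
    downsample_threshold: int = 500_000
    top_comedications: int = 300
    # model settings
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    hdi_mass: float = 0.89
    rope_low: float = -0.05
    rope_high: float = 0.05
    hierarchical: bool = False
    # synthetic cohort settings (used by the generate stage)
    cohort: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.rope_low < 0 < self.rope_high:
            raise PipelineError("ROPE must bracket zero (rope_low < 0 < rope_high)")
        for name in ("min_index_patients", "min_pair_patients",
                     "downsample_threshold", "top_comedications",
                     "chains", "iterations", "warmup"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")
        if not 0 < self.one_time_max_fraction < 1:
            raise PipelineError("one_time_max_fraction must be in (0,1)")
        if self.warmup >= self.iterations:
            raise PipelineError("warmup must be below iterations")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def model_spec(self) -> ModelSpec:
        return ModelSpec(chains=self.chains, iterations=self.iterations,
                         warmup=self.warmup, hdi_mass=self.hdi_mass,
                         rope=(self.rope_low, self.rope_high),
                         hierarchical=self.hierarchical)

    def cohort_config(self, seed: int) -> CohortConfig:
        kw = dict(self.cohort)
        if "planted_effects" in kw:
            kw["planted_effects"] = {
                tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                for k, v in kw["planted_effects"].items()
            }
        if "admission_los_distribution" in kw:
            kw["admission_los_distribution"] = tuple(kw["admission_los_distribution"])
        if "effect_pair" in kw and kw["effect_pair"] is not None:
            kw["effect_pair"] = tuple(kw["effect_pair"])
        kw.setdefault("seed", seed)
        return CohortConfig(**kw)


def stage_seeds(seed: int) -> dict[str, int]:
    """Fixed fan-out of the global seed to per-stage seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {stage: int(c.generate_state(1)[0] % (2**31))
            for stage, c in zip(_STAGES, children)}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def setup_logging(run_dir: Optional[Path] = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(run_dir / "pipeline.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory.

    Re-running with the same config and seed reproduces all outputs
    byte-identically.  On stage failure, outputs written so far are
    retained and a status file records the failed stage.
    """
    config.validate()
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(run_dir)
    seeds = stage_seeds(config.seed)
    status: dict = {"stages": {}}
    cfg_dict = asdict(config)
    cohort_cfg = dict(cfg_dict.get("cohort", {}))
    if isinstance(cohort_cfg.get("planted_effects"), dict):
        cohort_cfg["planted_effects"] = {
            "|".join(map(str, k)) if isinstance(k, tuple) else str(k): v
            for k, v in cohort_cfg["planted_effects"].items()}
    if isinstance(cohort_cfg.get("effect_pair"), tuple):
        cohort_cfg["effect_pair"] = list(cohort_cfg["effect_pair"])
    cfg_dict["cohort"] = cohort_cfg
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed, "stage_seeds": seeds,
        "config": cfg_dict, "row_counts": {}, "files": {},
    }

    def record(stage: str, tables: dict[str, pd.DataFrame]) -> None:
        for name, df in tables.items():
            path = run_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            manifest["row_counts"][name] = len(df)
        status["stages"][stage] = "ok"
        logger.info("stage %s done (%s)", stage,
                    ", ".join(f"{k}={len(v)}" for k, v in tables.items()))

    try:
        # generate
        cohort_cfg = config.cohort_config(seeds["generate"])
        cohort = generate_cohort(cohort_cfg)
        cohort_dir = run_dir / "cohort"
        write_cohort(cohort, cohort_dir)
        for name, df in (("admissions", cohort.admissions),
                         ("prescriptions", cohort.prescriptions)):
            manifest["row_counts"][name] = len(df)
        status["stages"]["generate"] = "ok"
        logger.info("stage generate done (%d admissions, %d prescriptions)",
                    len(cohort.admissions), len(cohort.prescriptions))

        # ingest pre-pass + ADD
        admissions = merge_readmissions(cohort.admissions)
        add_table = compute_add_frame(cohort.prescriptions)
        record("add", {"add": add_table})

        # episodes + selection
        episodes = build_episodes(cohort.prescriptions, add_table)
        episodes_kept, report = apply_selection_filters(
            episodes, cohort.prescriptions,
            min_index_patients=config.min_index_patients,
            min_pair_patients=config.min_pair_patients,
            one_time_max_fraction=config.one_time_max_fraction)
        sel = pd.DataFrame(
            [{"metric": "drugs_considered", "value": report.drugs_considered},
             {"metric": "drugs_retained", "value": report.drugs_retained},
             {"metric": "pairs_considered", "value": report.pairs_considered},
             {"metric": "pairs_retained", "value": report.pairs_retained}]
            + [{"metric": f"excluded:{k}", "value": v}
               for k, v in sorted(report.exclusions.items())])
        record("episodes", {"episodes": episodes_kept, "selection_report": sel})
        logger.info("selection attrition: %s", report.exclusions)

        # fit
        spec = config.model_spec()
        ds = DownsampleConfig(episode_threshold=config.downsample_threshold,
                              top_comedications=config.top_comedications,
                              min_pair_patients=config.min_pair_patients)
        posteriors, diagnostics = fit_all_index_drugs(
            episodes_kept, admissions, spec, seeds["fit"], downsample=ds)
        (run_dir / "model_config.json").write_text(
            json.dumps(asdict(spec) | {"seed": seeds["fit"]}, indent=2))
        record("fit", {"pair_posteriors": posteriors, "diagnostics": diagnostics})

        # posthoc
        sig = posteriors[posteriors["significant"]] if len(posteriors) else posteriors
        sig_pairs = list(map(tuple, sig[["index_drug", "co_med"]].to_numpy())) \
            if len(sig) else []
        assoc, matched = run_posthoc(sig_pairs, episodes_kept, admissions,
                                     cohort.diagnoses, cohort.blood_tests,
                                     seeds["posthoc"])
        record("posthoc", {"associations": assoc, "matched_cohorts": matched})

        # annotate
        if len(sig):
            pair_meta = sig[["index_drug", "co_med", "n_patients"]]
            annotations = annotate_pairs(pair_meta, cohort.ddi_reference,
                                         cohort.pk_annotations,
                                         cohort.comention_counts,
                                         cohort.variants)
            comparisons = compare_groups(annotations, posteriors)
        else:
            annotations = pd.DataFrame()
            comparisons = pd.DataFrame()
        record("annotate", {"annotations": annotations, "comparisons": comparisons})
    except Exception as exc:
        stage = next((s for s in _STAGES if s not in status["stages"]), "unknown")
        status["stages"][stage] = f"failed: {exc}"
        (run_dir / "status.json").write_text(json.dumps(status, indent=2))
        raise

    for path in sorted(run_dir.rglob("*.tsv")):
        manifest["files"][str(path.relative_to(run_dir))] = _digest(path)
    (run_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    (run_dir / "status.json").write_text(json.dumps(status, indent=2))
    return run_dir
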