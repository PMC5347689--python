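"""End-to-end orchestration: simulate -> normalize -> filter -> train ->
score -> classify -> validate -> power.

A :class:`PipelineConfig` (YAML or JSON) names the training cohorts, the
validation cohorts, the paired technical-optimization set, the trial
design and the power specs.  :func:`run_pipeline` executes every stage
per platform, writes all artifacts into the output directory, and
records them in a manifest with content hashes so a rerun with the same
config and seed is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, write_clinical
from .preprocess import concordance_filter, housekeeping_normalize
from .score import classify_by_percentile, cutoff_sweep, score_samples, train_signature
from .simulate import (
    CohortSpec,
    PairedTissueSpec,
    TrialDesign,
    concordance_screen_targets,
    generate_cohort,
    generate_paired_set,
    generate_trial,
)
from .survival import cohort_report
from .power import (
    PredictivePowerSpec,
    detectable_hr,
    hr_ratio_from_survival,
    predictive_power_sim,
    prognostic_power,
)

log = logging.getLogger("e2fscore.pipeline")

#: Order in which per-stage child seeds are derived from the global seed.
STAGE_NAMES = ("paired", "train_ff", "train_ffpe", "validation", "trial", "power")


@dataclass
class PipelineConfig:
    """Everything a full run needs; see ``examples/demo_config.yaml``."""

    seed: int = 0
    endpoint: str = "os"
    filter_threshold: float = 0.5
    percentiles: list[int] = field(default_factory=lambda: list(range(25, 80, 5)))
    n_candidate_genes: int = 106
    n_discordant_genes: int = 32
    n_control_genes: int = 18
    paired_n_patients: int = 36
    training_ff: dict = field(default_factory=lambda: {"cohort_id": "FF_TRAIN", "n_patients": 300})
    training_ffpe: dict = field(default_factory=lambda: {"cohort_id": "FFPE_TRAIN", "n_patients": 150})
    validation: list[dict] = field(
        default_factory=lambda: [
            {"cohort_id": "FF_VAL1", "platform": "FF", "n_patients": 200},
            {"cohort_id": "FFPE_VAL1", "platform": "FFPE", "n_patients": 120},
        ]
    )
    cohort_defaults: dict = field(default_factory=lambda: {"latent_hazard_coef": 0.6})
    trial: dict = field(
        default_factory=lambda: {"n_patients": 400, "surv5": [0.66, 0.20, 0.66, 0.66]}
    )
    prognostic_power: list[dict] = field(
        default_factory=lambda: [
            {"n_events": 287, "prevalence": 0.5, "hazard_ratio": 1.4, "alpha": 0.05},
            {"n_events": 68, "prevalence": 0.5, "hazard_ratio": 2.03, "alpha": 0.05},
        ]
    )
    predictive_power: dict = field(default_factory=lambda: {"n_reps": 200, "alpha": 0.05})

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)

    def to_canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:16]


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Fan the global seed out into named per-stage child seeds."""
    state = np.random.SeedSequence(global_seed).generate_state(len(STAGE_NAMES)) % (2**31)
    return dict(zip(STAGE_NAMES, (int(s) for s in state)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cohort_spec(cfg: PipelineConfig, entry: dict, platform: str, n_genes: int, seed: int) -> CohortSpec:
    kwargs = {**cfg.cohort_defaults, **entry}
    kwargs.pop("platform", None)
    return CohortSpec(
        platform=platform,
        n_signature_genes=n_genes,
        n_control_genes=cfg.n_control_genes,
        seed=seed,
        **kwargs,
    )


def _prepare_matrix(expr: ExpressionMatrix, control_ids: list[str]) -> ExpressionMatrix:
    """NanoString-like count matrices get housekeeping-normalized; FF
    log-scale matrices pass through."""
    if expr.scale == "raw_counts":
        return housekeeping_normalize(expr, control_ids)
    return expr


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full per-platform pipeline; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        try:
            prior = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            prior = {}
        if (
            prior.get("config_hash") == cfg_hash
            and prior.get("seed") == config.seed
            and all((outdir / f).exists() and _sha256(outdir / f) == h for f, h in prior.get("files", {}).items())
        ):
            log.info("cached run found for config %s, seed %s; skipping", cfg_hash, config.seed)
            return prior

    seeds = stage_seeds(config.seed)
    artifacts: list[Path] = []

    def save(obj, name: str, writer: str = "tsv") -> Path:
        path = outdir / name
        if writer == "tsv":
            obj.to_csv(path, sep="\t", index=False)
        elif writer == "csv":
            obj.to_csv(path, index=False)
        artifacts.append(path)
        return path

    # --- stage: paired technical-optimization set + concordance filter ---
    candidate_ids = [f"E2F_G{j + 1:03d}" for j in range(config.n_candidate_genes)]
    paired = generate_paired_set(
        PairedTissueSpec(
            n_patients=config.paired_n_patients,
            n_genes=config.n_candidate_genes,
            target_correlations=concordance_screen_targets(
                config.n_candidate_genes, config.n_discordant_genes
            ),
            gene_ids=candidate_ids,
            seed=seeds["paired"],
        )
    )
    report = concordance_filter(paired, threshold=config.filter_threshold)
    retained = report.retained_genes
    log.info(
        "concordance filter: %d candidate genes in, %d retained (threshold %.2f)",
        config.n_candidate_genes,
        len(retained),
        config.filter_threshold,
    )
    save(report.table, "concordance_report.tsv")

    # --- stage: training cohorts, one per platform ---
    models = {}
    training_clinical = {}
    training_scores = {}
    for platform, entry, seed_name in (
        ("FF", config.training_ff, "train_ff"),
        ("FFPE", config.training_ffpe, "train_ffpe"),
    ):
        spec = _cohort_spec(config, entry, platform, config.n_candidate_genes, seeds[seed_name])
        expr, clinical = generate_cohort(spec)
        expr.to_tsv(outdir / f"expression_{spec.cohort_id}.tsv")
        artifacts.append(outdir / f"expression_{spec.cohort_id}.tsv")
        write_clinical(clinical, outdir / f"clinical_{spec.cohort_id}.csv")
        artifacts.append(outdir / f"clinical_{spec.cohort_id}.csv")

        control_ids = [g for g in expr.gene_ids if g.startswith("CTRL_")]
        prepared = _prepare_matrix(expr, control_ids)
        model = train_signature(prepared, retained, training_cohort_id=spec.cohort_id)
        model.to_json(outdir / f"model_{platform.lower()}.json")
        artifacts.append(outdir / f"model_{platform.lower()}.json")
        models[platform] = model
        training_clinical[platform] = clinical
        scores = classify_by_percentile(score_samples(model, prepared))
        training_scores[platform] = scores
        save(scores.to_frame(), f"scores_{spec.cohort_id}.csv", writer="csv")
        log.info(
            "trained %s model on %s: PC1 explains %.1f%% of variance",
            platform,
            spec.cohort_id,
            100 * model.pct_variance_pc1,
        )

    # --- stage: cutoff sweep on the FF training cohort ---
    sweep = cutoff_sweep(
        training_scores["FF"],
        training_clinical["FF"],
        percentiles=config.percentiles,
        endpoint=config.endpoint,
    )
    save(sweep, "cutoff_sweep.tsv")

    # --- stage: validation cohorts, pooled per platform ---
    val_seeds = np.random.SeedSequence(seeds["validation"]).generate_state(
        max(1, len(config.validation))
    ) % (2**31)
    pooled: dict[str, list[pd.DataFrame]] = {"FF": [], "FFPE": []}
    for entry, vseed in zip(config.validation, val_seeds):
        entry = dict(entry)
        platform = entry.pop("platform", "FF")
        spec = _cohort_spec(config, entry, platform, config.n_candidate_genes, int(vseed))
        expr, clinical = generate_cohort(spec)
        control_ids = [g for g in expr.gene_ids if g.startswith("CTRL_")]
        prepared = _prepare_matrix(expr, control_ids)
        scores = classify_by_percentile(score_samples(models[platform], prepared))
        save(scores.to_frame(), f"scores_{spec.cohort_id}.csv", writer="csv")
        labelled = clinical.assign(e2f_group=scores.labels.loc[clinical["sample_id"]].to_numpy())
        pooled[platform].append(labelled)
        log.info("scored validation cohort %s (%s, n=%d)", spec.cohort_id, platform, spec.n_patients)

    for platform, frames in pooled.items():
        if not frames:
            continue
        combined = pd.concat(frames, ignore_index=True)
        table = cohort_report(combined, "e2f_group", endpoint=config.endpoint, mode="prognostic")
        save(table, f"prognostic_report_{platform.lower()}.tsv")

    # --- stage: randomized trial, predictive validation ---
    trial_design = TrialDesign(seed=seeds["trial"], **{k: tuple(v) if k == "surv5" else v for k, v in config.trial.items()})
    trial = generate_trial(trial_design)
    write_clinical(trial, outdir / "clinical_trial.csv")
    artifacts.append(outdir / "clinical_trial.csv")
    predictive = cohort_report(
        trial, "e2f_group", endpoint=config.endpoint, mode="predictive", stages=()
    )
    save(predictive, "predictive_report.tsv")

    # --- stage: power table ---
    rows = []
    for p in config.prognostic_power:
        rows.append(
            {
                "analysis": "prognostic",
                **p,
                "power": prognostic_power(**p),
                "detectable_hr_80": detectable_hr(p["n_events"], p["prevalence"], 0.80, p["alpha"]),
            }
        )
    sim = predictive_power_sim(
        PredictivePowerSpec(
            design=trial_design,
            alpha=config.predictive_power.get("alpha", 0.05),
            n_reps=config.predictive_power.get("n_reps", 200),
            seed=seeds["power"],
        )
    )
    rows.append(
        {
            "analysis": "predictive",
            "hr_ratio": hr_ratio_from_survival(trial_design.surv5, trial_design.horizon_months),
            "power": sim.power,
            "mc_se": sim.mc_se,
            "n_reps": sim.n_reps,
        }
    )
    save(pd.DataFrame(rows), "power_table.tsv")

    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stage_seeds": seeds,
        "package_version": __version__,
        "files": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("wrote %d artifacts to %s", len(manifest["files"]), outdir)
    return manifest
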