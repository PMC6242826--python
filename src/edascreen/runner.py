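"""End-to-end orchestration: configuration, staging and reproducible runs.

A single :class:`PipelineConfig` (serialisable to YAML/JSON) carries every
stage's parameters plus one master seed; reruns with the same config and
seed produce byte-identical artifacts.  Every output file embeds the config
hash and master seed, either in a leading comment line (CSV) or a ``meta``
object (JSON).  Stages write their artifacts to disk so each one is
independently inspectable and resumable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decomp, featureset, groupstats, learn, sigproc, synthcohort

log = logging.getLogger("edascreen")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the study-analog pipeline, one section per stage."""

    protocol: synthcohort.ProtocolSpec = field(default_factory=synthcohort.ProtocolSpec)
    n_control: int = 37
    n_case: int = 30
    control_effects: synthcohort.GroupEffectSpec = field(
        default_factory=synthcohort.control_effects
    )
    case_effects: synthcohort.GroupEffectSpec = field(
        default_factory=synthcohort.case_effects
    )
    filter: sigproc.FilterSpec = field(default_factory=sigproc.FilterSpec)
    decomposition: decomp.DecompositionConfig = field(
        default_factory=decomp.DecompositionConfig
    )
    window: featureset.WindowPolicy = field(default_factory=featureset.WindowPolicy)
    scr: featureset.ScrParams = field(default_factory=featureset.ScrParams)
    model: learn.ModelConfig = field(default_factory=learn.ModelConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"]["phase_names"] = list(self.protocol.phase_names)
        d["model"]["subset_sizes"] = list(self.model.subset_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(spec_cls, key):
            sub = dict(d.get(key, {}))
            if not sub:
                return spec_cls()
            if key == "protocol" and "phase_names" in sub:
                sub["phase_names"] = tuple(sub["phase_names"])
            if key == "model" and "subset_sizes" in sub:
                sub["subset_sizes"] = tuple(sub["subset_sizes"])
            return spec_cls(**sub)

        return cls(
            protocol=build(synthcohort.ProtocolSpec, "protocol"),
            n_control=int(d.get("n_control", 37)),
            n_case=int(d.get("n_case", 30)),
            control_effects=build(synthcohort.GroupEffectSpec, "control_effects"),
            case_effects=build(synthcohort.GroupEffectSpec, "case_effects"),
            filter=build(sigproc.FilterSpec, "filter"),
            decomposition=build(decomp.DecompositionConfig, "decomposition"),
            window=build(featureset.WindowPolicy, "window"),
            scr=build(featureset.ScrParams, "scr"),
            model=build(learn.ModelConfig, "model"),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def meta_line(self) -> str:
        return f"config={self.config_hash} seed={self.seed}"


def _meta(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash, "seed": config.seed}


def _write_csv(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    body = frame.to_csv(index=False, lineterminator="\n")
    path.write_text(f"# edascreen {config.meta_line}\n" + body)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def cmd_simulate(config: PipelineConfig, outdir: str | Path) -> Path:
    """Write the synthetic cohort (CSV + sidecars + ground truth + manifest)."""
    outdir = Path(outdir)
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    cohort = synthcohort.simulate_cohort(
        config.n_control,
        config.n_case,
        config.control_effects,
        config.case_effects,
        config.protocol,
        config.seed,
    )
    files = []
    for rec, truth in cohort:
        files.append(synthcohort.write_recording(rec, rec_dir, truth))
    manifest = {
        "meta": _meta(config),
        "n_control": config.n_control,
        "n_case": config.n_case,
        "files": {p.name: _sha256(p) for p in sorted(rec_dir.iterdir())},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("simulated %d recordings into %s", len(files), rec_dir)
    return path


def load_cohort(outdir: str | Path) -> list[sigproc.EDARecording]:
    rec_dir = Path(outdir) / "recordings"
    paths = sorted(rec_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no recordings found under {rec_dir}")
    return [synthcohort.read_recording(p) for p in paths]


def preprocess_cohort(
    recordings: list[sigproc.EDARecording], config: PipelineConfig
) -> list[sigproc.EDARecording]:
    """Clean and filter every usable recording; log and skip unusable ones."""
    out = []
    for rec in recordings:
        try:
            out.append(sigproc.preprocess(rec, config.filter))
        except sigproc.UnusableRecordingError as err:
            log.warning("excluding %s: %s", rec.subject_id, err)
    return out


def decompose_cohort(
    recordings: list[sigproc.EDARecording], config: PipelineConfig
) -> list[tuple[sigproc.EDARecording, decomp.DecompositionResult]]:
    out = []
    for rec in recordings:
        t0 = time.perf_counter()
        result = decomp.decompose(rec.samples, rec.sampling_rate_hz, config.decomposition)
        log.info("decomposed %s in %.1fs", rec.subject_id, time.perf_counter() - t0)
        out.append((rec, result))
    return out


def write_decomposition(
    rec: sigproc.EDARecording,
    result: decomp.DecompositionResult,
    outdir: str | Path,
    config: PipelineConfig,
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(result.tonic)) / result.rate_hz
    frame = pd.DataFrame(
        {
            "time_s": t,
            "tonic_uS": result.tonic,
            "phasic_uS": result.phasic,
            "driver": result.driver,
            "residual_uS": result.residual,
        }
    )
    path = outdir / f"{rec.subject_id}.decomp.csv"
    _write_csv(frame.round(8), path, config)
    return path


def cmd_run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute the full pipeline and write every artifact.

    Order: simulate -> preprocess -> decompose -> features -> statistics ->
    repeated CV.  Returns the paths of the written artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage = "simulate"
    try:
        paths["manifest"] = cmd_simulate(config, outdir)
        stage = "preprocess"
        recordings = preprocess_cohort(load_cohort(outdir), config)
        stage = "decompose"
        decomposed = decompose_cohort(recordings, config)
        stage = "features"
        table = featureset.assemble_feature_table(decomposed, config.window, config.scr)
        feat_path = outdir / "features.csv"
        featureset.write_feature_table(table, feat_path, meta=config.meta_line)
        paths["features"] = feat_path
        stage = "stats"
        stats_report = groupstats.feature_stats_report(table)
        stats_path = outdir / "stats.csv"
        _write_csv(stats_report, stats_path, config)
        ats = groupstats.ats_report(table)
        ats_path = outdir / "ats.csv"
        _write_csv(ats, ats_path, config)
        paths["stats"], paths["ats"] = stats_path, ats_path
        stage = "cv"
        report, ranks = learn.repeated_cv(table, config.model)
        cv_path = outdir / "cv_report.csv"
        _write_csv(report.metrics.round(10), cv_path, config)
        rank_path = outdir / "rank_table.csv"
        _write_csv(ranks.round(10), rank_path, config)
        cv_json = outdir / "cv_report.json"
        cv_json.write_text(
            json.dumps(
                {
                    "meta": _meta(config),
                    "n_rankings": report.n_rankings,
                    "metrics": report.metrics.round(10).to_dict(orient="records"),
                },
                indent=1,
                sort_keys=True,
            )
        )
        paths["cv"], paths["ranks"], paths["cv_json"] = cv_path, rank_path, cv_json
        # pooled-test ROC points of the best tree configuration, for plotting
        tree = report.metrics[report.metrics["classifier"] == "tree"]
        best_k = int(tree.loc[tree["accuracy"].idxmax(), "subset_size"])
        roc = report.roc("tree", best_k, "test")
        roc_path = outdir / "roc_tree_test.csv"
        _write_csv(roc.round(8), roc_path, config)
        paths["roc"] = roc_path
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
    config.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths
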