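"""End-to-end orchestration: simulate/load -> validate -> summarize ->
correlate -> spline fits -> clusterings -> report bundle.

A single pipeline seed governs every stochastic stage through stage-keyed
substreams (the substream seed is derived from the pipeline seed and the
stage name), so adding a stage never perturbs the draws of earlier ones.
All outputs are plain CSV/JSON; a provenance block (config hash, seed,
package version) makes every bundle reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    FEATURES,
    INSTRUCTIONS,
    CohortTable,
    ValidationReport,
    load_cohort,
    save_cohort,
    validate_design,
)
from .synthetic import ClusterGroup, GeneratorConfig, generate_cohort
from .summaries import (
    STATISTICS,
    grand_average_table,
    incoherency_table,
    orientation_summaries,
    summarize_preferences,
    summary_matrix,
)
from .association import CorrelationMatrix, spearman_matrix
from .spline import SplineFitResult, fit_hetero_spline, predict_bands
from .clustering import ClusteringResult, criterion_columns, select_clusters

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "load_pipeline_config",
           "stage_seed", "DEFAULT_CLUSTER_CRITERIA"]

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_CRITERIA = (
    *(f"single:{f}:{i}" for f in FEATURES for i in INSTRUCTIONS),
    "all-features",
    "dangerous",
    "harmless",
    "all-plus-spq",
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of (``trials_path`` + ``participants_path``) or
    ``generator`` must be supplied.
    """

    trials_path: str | None = None
    participants_path: str | None = None
    generator: GeneratorConfig | None = None
    statistic: str = "mmpd"
    incoherency_statistic: str = "mmpd"
    spline_grid_points: int = 101
    clustering_criteria: tuple[str, ...] = DEFAULT_CLUSTER_CRITERIA
    seed: int = 0

    def validated(self) -> "PipelineConfig":
        from_files = self.trials_path is not None or self.participants_path is not None
        if from_files == (self.generator is not None):
            raise ValueError(
                "supply exactly one of (trials_path, participants_path) or generator")
        if from_files and (self.trials_path is None or self.participants_path is None):
            raise ValueError("both trials_path and participants_path are required")
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.incoherency_statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.incoherency_statistic!r}")
        if self.spline_grid_points < 2:
            raise ValueError("spline_grid_points must be >= 2")
        for crit in self.clustering_criteria:
            criterion_columns(crit)  # raises on malformed criteria
        return self

    def to_canonical_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            g = dataclasses.asdict(self.generator)
            g["condition_means"] = {f"{f}:{i}": v for (f, i), v
                                    in self.generator.condition_means.items()}
            if self.generator.cluster_spec is not None:
                g["cluster_spec"] = [
                    {"weight": grp.weight,
                     "offsets": {f"{f}:{i}": v for (f, i), v in grp.offsets.items()}}
                    for grp in self.generator.cluster_spec
                ]
            d["generator"] = g
        d["clustering_criteria"] = list(self.clustering_criteria)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _parse_condition_key(key: str) -> tuple[str, str]:
    parts = key.split(":")
    if len(parts) != 2:
        raise ValueError(f"condition key {key!r} must be '<feature>:<instruction>'")
    return parts[0], parts[1]


def generator_config_from_dict(d: Mapping[str, Any]) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML/JSON mapping.

    Condition and offset keys are ``"<feature>:<instruction>"`` strings.
    Fields omitted fall back to the reference defaults.
    """
    from .synthetic import reference_config

    ref = reference_config()
    kwargs: dict[str, Any] = {}
    d = dict(d)
    if "condition_means" in d:
        kwargs["condition_means"] = {
            _parse_condition_key(k): float(v) for k, v in d.pop("condition_means").items()}
    else:
        kwargs["condition_means"] = dict(ref.condition_means)
    if "cluster_spec" in d:
        spec = d.pop("cluster_spec")
        if spec is None:
            kwargs["cluster_spec"] = None
        else:
            kwargs["cluster_spec"] = tuple(
                ClusterGroup(
                    weight=float(g["weight"]),
                    offsets={_parse_condition_key(k): float(v)
                             for k, v in g.get("offsets", {}).items()},
                ) for g in spec)
    else:
        kwargs["cluster_spec"] = ref.cluster_spec
    if "spq_range" in d:
        kwargs["spq_range"] = tuple(d.pop("spq_range"))
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    for k, v in d.items():
        if k not in known:
            raise ValueError(f"unknown generator field {k!r}")
        kwargs[k] = v
    return GeneratorConfig(**kwargs).validated()


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    if "generator" in d and d["generator"] is not None:
        d["generator"] = generator_config_from_dict(d["generator"])
    if "clustering_criteria" in d:
        d["clustering_criteria"] = tuple(d["clustering_criteria"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown pipeline config field(s) {sorted(unknown)}")
    return PipelineConfig(**d).validated()


@dataclass
class ReportBundle:
    """All artifacts of one pipeline run plus provenance."""

    cohort: CohortTable
    validation: ValidationReport
    summaries: dict[str, pd.DataFrame]
    incoherency: pd.DataFrame
    grand_averages: pd.DataFrame
    orientation: pd.DataFrame
    correlation: CorrelationMatrix
    spline_fits: list[dict[str, Any]]
    bands: pd.DataFrame
    clusterings: dict[str, ClusteringResult]
    provenance: dict[str, Any]

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle as CSV/JSON files, atomically.

        Files are staged in a scratch subdirectory and moved into place
        only when every artifact serialized successfully.
        """
        out = Path(out_dir)
        staging = out.with_name(out.name + ".partial")
        if staging.exists():
            shutil.rmtree(staging)
        staging.mkdir(parents=True)
        try:
            save_cohort(self.cohort, staging / "trials.csv", staging / "participants.csv")
            (staging / "validation.json").write_text(self.validation.to_json())
            for stat, df in self.summaries.items():
                df.to_csv(staging / f"preference_summaries_{stat}.csv", index=False)
            self.incoherency.to_csv(staging / "incoherency.csv", index=False)
            self.grand_averages.to_csv(staging / "grand_averages.csv", index=False)
            self.orientation.to_csv(staging / "orientation_summaries.csv", index=False)
            self.correlation.to_long().to_csv(staging / "correlation_matrix.csv",
                                              index=False)
            corr_json = {
                "variables": self.correlation.variables,
                "rho": self.correlation.rho.to_numpy().tolist(),
                "p": self.correlation.p.to_numpy().tolist(),
                "n": self.correlation.n,
            }
            (staging / "correlation.json").write_text(json.dumps(corr_json, indent=2))
            (staging / "spline_fits.json").write_text(
                json.dumps(self.spline_fits, indent=2))
            self.bands.to_csv(staging / "bands.csv", index=False)
            labels = pd.concat([res.labels_frame(crit)
                                for crit, res in self.clusterings.items()],
                               ignore_index=True)
            labels.to_csv(staging / "clusters.csv", index=False)
            bic_rows = [{"criterion": crit, "k": k, "bic": v}
                        for crit, res in self.clusterings.items()
                        for k, v in sorted(res.bic.items())]
            pd.DataFrame(bic_rows).to_csv(staging / "cluster_bic.csv", index=False)
            (staging / "provenance.json").write_text(
                json.dumps(self.provenance, indent=2, sort_keys=True))
        except Exception:
            shutil.rmtree(staging, ignore_errors=True)
            raise
        if out.exists():
            shutil.rmtree(out)
        staging.rename(out)


def _fit_record(response: str, fit: SplineFitResult) -> dict[str, Any]:
    return {
        "response": response,
        "beta": [float(b) for b in fit.beta],
        "gamma": [float(g) for g in fit.gamma],
        "internal_knots": list(fit.basis.internal_knots),
        "boundary_knots": list(fit.basis.boundary_knots),
        "loglik": float(fit.loglik),
        "converged": bool(fit.converged),
        "n": fit.n,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 ) -> ReportBundle:
    """Execute every analysis stage and return (optionally write) the bundle.

    Stage failures raise :class:`StageError` naming the stage; when
    ``out_dir`` is given, nothing is written unless every stage succeeded.
    """
    cfg = config.validated()

    def run_stage(name, fn):
        logger.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
        logger.info("stage %s: done", name)
        return result

    def _data() -> CohortTable:
        if cfg.generator is not None:
            gen = dataclasses.replace(cfg.generator,
                                      seed=stage_seed(cfg.seed, "simulate"))
            cohort = generate_cohort(gen)
            logger.info("simulated cohort: %d participants, %d trials",
                        cohort.n_participants, cohort.n_trials)
            return cohort
        return load_cohort(cfg.trials_path, cfg.participants_path)

    cohort = run_stage("data_model", _data)
    validation = run_stage("validate", lambda: validate_design(cohort))

    def _summaries():
        summaries = {stat: summarize_preferences(cohort, stat) for stat in STATISTICS}
        inco = incoherency_table(summaries[cfg.incoherency_statistic])
        grand = grand_average_table(cohort, cfg.incoherency_statistic)
        orient = orientation_summaries(cohort, cfg.statistic)
        return summaries, inco, grand, orient

    summaries, inco, grand, orient = run_stage("summarize", _summaries)
    matrix = summary_matrix(cohort, cfg.statistic)
    correlation = run_stage("correlate", lambda: spearman_matrix(matrix))

    def _splines():
        fits: list[dict[str, Any]] = []
        bands_frames = []
        spq = matrix["spq"].to_numpy()
        grid = np.linspace(spq.min(), spq.max(), cfg.spline_grid_points)
        for col in matrix.columns[1:]:
            fit = fit_hetero_spline(spq, matrix[col].to_numpy())
            fits.append(_fit_record(col, fit))
            b = predict_bands(fit, grid)
            b.insert(0, "response", col)
            bands_frames.append(b)
        inco_wide = inco.pivot(index="participant_id", columns="feature", values="x")
        inco_wide = inco_wide.reindex(matrix.index)
        for f in FEATURES:
            fit = fit_hetero_spline(spq, inco_wide[f].to_numpy())
            name = f"incoherency_{f}"
            fits.append(_fit_record(name, fit))
            b = predict_bands(fit, grid)
            b.insert(0, "response", name)
            bands_frames.append(b)
        return fits, pd.concat(bands_frames, ignore_index=True)

    spline_fits, bands = run_stage("splinefit", _splines)

    def _clusters():
        out: dict[str, ClusteringResult] = {}
        for crit in cfg.clustering_criteria:
            cols = criterion_columns(crit)
            out[crit] = select_clusters(matrix[cols])
        return out

    clusterings = run_stage("cluster", _clusters)

    provenance = {
        "package": "spiderpref",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_canonical_dict(),
        "n_participants": cohort.n_participants,
        "n_trials": cohort.n_trials,
    }
    bundle = ReportBundle(
        cohort=cohort, validation=validation, summaries=summaries,
        incoherency=inco, grand_averages=grand, orientation=orient,
        correlation=correlation, spline_fits=spline_fits, bands=bands,
        clusterings=clusterings, provenance=provenance,
    )
    if out_dir is not None:
        run_stage("report", lambda: bundle.write(out_dir))
    return bundle
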