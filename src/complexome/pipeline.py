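"""Config-driven pipeline: simulate -> quantify -> calibrate -> compare.

One ``RunConfig`` drives the whole chain and a single seed governs every
stochastic stage, so two runs with identical config and seed produce
byte-identical report files. During a run every artifact is written with a
``.partial`` suffix and only renamed to its final name once its stage has
completed, so an aborted run never leaves files that look finished.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .analysis import (
    build_comparison_report,
    self_calibration_markers,
    write_report,
)
from .calibration import fit_mass_calibration
from .quant import (
    condition_profiles,
    map_channels_to_conditions,
    normalize_total_intensity,
    protein_abundance_table,
    protein_ratio,
)
from .scenario import (
    ScenarioConfig,
    build_default_scenario,
    default_annotation,
    scenario_from_dict,
    simulate_evidence,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run", "load_run_config"]

#: Proteins scored for co-migration by default: the residual cIV-related
#: species whose shared ~130 kDa band is the knockout's hallmark.
DEFAULT_COMIGRATION_SET = ("MT-CO1", "COA3", "HIGD2A", "HIGD1A", "COX5B", "NDUFA4")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``mode``: "simulate" (write evidence only), "analyze" (read existing
    evidence), or "full" (simulate then analyze). For analyze mode the
    gel geometry and label-swap design must be supplied explicitly; for
    simulate/full they come from the scenario.
    """

    mode: str = "full"
    output_dir: str = "out"
    scenario: ScenarioConfig | None = None
    evidence_path: str | None = None
    annotation_path: str | None = None
    markers_path: str | None = None
    # analyze-mode experiment description (defaulted from scenario otherwise)
    conditions: tuple[str, str] | None = None
    replicate_heavy: tuple[str, ...] | None = None
    n_slices: int | None = None
    gel_log10_top: float = 3.5
    gel_log10_bottom: float = 1.5
    experiment_id: str = "exp1"
    # quantification options
    ratio_all_peptides: bool = False
    total_intensity_normalization: bool = False
    # analysis thresholds
    min_rel_height: float = 0.2
    match_tol: float = 1.5
    comigration_proteins: tuple[str, ...] = DEFAULT_COMIGRATION_SET
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise PipelineError("config", f"unknown mode {self.mode!r}")
        if self.mode in ("simulate", "full") and self.scenario is None:
            raise PipelineError("config", f"mode {self.mode!r} requires a scenario")
        if self.mode == "analyze":
            if self.evidence_path is None:
                raise PipelineError("config", "analyze mode requires an evidence path")
            if self.conditions is None or self.replicate_heavy is None:
                raise PipelineError(
                    "config",
                    "analyze mode requires conditions and the per-replicate "
                    "heavy-label assignment",
                )
            if self.n_slices is None:
                raise PipelineError("config", "analyze mode requires n_slices")


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file mirroring the field names."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    paths = raw.get("paths", {})
    scen = raw.get("scenario")
    if scen == "default" or (raw.get("mode", "full") in ("simulate", "full") and scen is None):
        scenario = build_default_scenario(seed=int(raw.get("seed", 0)))
    elif isinstance(scen, dict):
        scenario = scenario_from_dict(scen)
    else:
        scenario = None
    quant = raw.get("quantification", {})
    analysis = raw.get("analysis", {})
    return RunConfig(
        mode=raw.get("mode", "full"),
        output_dir=paths.get("output_dir", raw.get("output_dir", "out")),
        scenario=scenario,
        evidence_path=paths.get("evidence"),
        annotation_path=paths.get("annotation"),
        markers_path=paths.get("markers"),
        conditions=tuple(raw["conditions"]) if "conditions" in raw else None,
        replicate_heavy=tuple(raw["replicate_heavy"]) if "replicate_heavy" in raw else None,
        n_slices=raw.get("n_slices"),
        gel_log10_top=float(raw.get("gel_log10_top", 3.5)),
        gel_log10_bottom=float(raw.get("gel_log10_bottom", 1.5)),
        experiment_id=raw.get("experiment_id", "exp1"),
        ratio_all_peptides=bool(quant.get("ratio_all_peptides", False)),
        total_intensity_normalization=bool(
            quant.get("total_intensity_normalization", False)
        ),
        min_rel_height=float(analysis.get("min_rel_height", 0.2)),
        match_tol=float(analysis.get("match_tol", 1.5)),
        comigration_proteins=tuple(
            analysis.get("comigration_proteins", DEFAULT_COMIGRATION_SET)
        ),
        seed=raw.get("seed"),
        log_level=raw.get("log_level", "INFO"),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Artifacts:
    """Write-to-.partial-then-rename bookkeeping."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.pending: dict[str, Path] = {}

    def partial(self, name: str) -> Path:
        p = self.outdir / (name + ".partial")
        self.pending[name] = p
        return p

    def finalize(self) -> dict[str, str]:
        final = {}
        for name, partial in self.pending.items():
            target = self.outdir / name
            partial.replace(target)
            final[name] = str(target)
        return final


def run(config: RunConfig) -> dict[str, str]:
    """Execute the configured pipeline; returns {artifact name: path}."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_file = outdir / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("complexome").addHandler(handler)
    art = _Artifacts(outdir)
    inputs: dict[str, str] = {}
    seed = config.seed

    try:
        # --- stage: evidence ------------------------------------------------
        if config.mode in ("simulate", "full"):
            scenario = config.scenario
            if seed is None:
                seed = scenario.seed
            try:
                evidence = simulate_evidence(scenario, seed=seed)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("simulate", str(exc)) from exc
            cio.write_evidence(evidence, art.partial("evidence.tsv"))
            conditions = scenario.conditions
            swap_map = scenario.swap_map()
            n_slices = scenario.gel.n_slices
            gel_top, gel_bottom = scenario.gel.log10_mass_top, scenario.gel.log10_mass_bottom
        else:
            try:
                evidence = cio.read_evidence(config.evidence_path)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("read-evidence", str(exc)) from exc
            inputs["evidence"] = _sha256(Path(config.evidence_path))
            conditions = config.conditions
            swap_map = {
                (config.experiment_id, r): heavy
                for r, heavy in enumerate(config.replicate_heavy, start=1)
            }
            n_slices = config.n_slices
            gel_top, gel_bottom = config.gel_log10_top, config.gel_log10_bottom

        if config.annotation_path:
            annotation = cio.read_annotation(config.annotation_path)
            inputs["annotation"] = _sha256(Path(config.annotation_path))
        elif config.mode in ("simulate", "full"):
            annotation = default_annotation()
        else:
            annotation = pd.DataFrame(columns=list(cio.ANNOTATION_COLUMNS))

        artifacts: dict[str, str] = {}
        if config.mode != "simulate":
            # --- stage: quantify -------------------------------------------
            try:
                if config.total_intensity_normalization:
                    evidence = normalize_total_intensity(evidence)
                mapped = map_channels_to_conditions(evidence, swap_map, conditions)
                profiles = condition_profiles(mapped, conditions, n_slices)
                ratios = {
                    pid: protein_ratio(
                        pid, mapped, conditions,
                        all_peptides=config.ratio_all_peptides,
                    )
                    for pid in sorted(mapped["protein_id"].unique())
                }
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("quantify", str(exc)) from exc
            cio.write_profile_matrix(
                profiles.values(), annotation,
                art.partial("profiles_wide.tsv"),
                long_path=art.partial("profiles_long.csv"),
            )

            # --- stage: calibrate ------------------------------------------
            try:
                if config.markers_path:
                    markers = cio.read_markers(config.markers_path)
                    inputs["markers"] = _sha256(Path(config.markers_path))
                else:
                    markers = self_calibration_markers(
                        profiles, gel_top, gel_bottom, n_slices, conditions[0],
                        min_rel_height=config.min_rel_height,
                    )
                calibration = fit_mass_calibration(markers, n_slices=n_slices)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("calibrate", str(exc)) from exc
            cio.write_markers(markers, art.partial("markers.tsv"))

            # --- stage: compare --------------------------------------------
            try:
                report = build_comparison_report(
                    profiles, ratios, annotation, calibration, conditions,
                    min_rel_height=config.min_rel_height,
                    match_tol=config.match_tol,
                    comigration_proteins=list(config.comigration_proteins),
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("compare", str(exc)) from exc
            for name, df in (
                ("report.tsv", report.per_protein),
                ("complexes.tsv", report.per_complex),
                ("shifts.tsv", report.shifts),
                ("comigration.tsv", report.comigration),
            ):
                df.to_csv(
                    art.partial(name), sep="\t", index=False,
                    lineterminator="\n", float_format="%.6g",
                )
            # LFQ-style per-protein summary over summed evidence
            abundance = protein_abundance_table(mapped, conditions)
            lfq = None
            try:
                from .analysis import lfq_log2fc_summary

                lfq = lfq_log2fc_summary(abundance, annotation, conditions[0])
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("compare", str(exc)) from exc
            lfq.to_csv(
                art.partial("lfq_log2fc.tsv"), sep="\t", index=False,
                lineterminator="\n", float_format="%.6g",
            )

        # --- stage: manifest ----------------------------------------------
        manifest = {
            "package": "complexome",
            "version": __version__,
            "mode": config.mode,
            "seed": seed,
            "config": _config_echo(config),
            "input_checksums": inputs,
            "artifacts": sorted(art.pending),
        }
        with open(art.partial("run_manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        artifacts = art.finalize()
        return artifacts
    finally:
        logging.getLogger("complexome").removeHandler(handler)
        handler.close()


def _config_echo(config: RunConfig) -> dict:
    from .scenario import scenario_to_dict

    echo = {
        "mode": config.mode,
        "output_dir": str(config.output_dir),
        "paths": {
            "evidence": config.evidence_path,
            "annotation": config.annotation_path,
            "markers": config.markers_path,
        },
        "quantification": {
            "ratio_all_peptides": config.ratio_all_peptides,
            "total_intensity_normalization": config.total_intensity_normalization,
        },
        "analysis": {
            "min_rel_height": config.min_rel_height,
            "match_tol": config.match_tol,
            "comigration_proteins": list(config.comigration_proteins),
        },
        "seed": config.seed,
        "log_level": config.log_level,
    }
    if config.scenario is not None:
        echo["scenario"] = scenario_to_dict(config.scenario)
    else:
        echo.update(
            {
                "conditions": list(config.conditions or ()),
                "replicate_heavy": list(config.replicate_heavy or ()),
                "n_slices": config.n_slices,
                "gel_log10_top": config.gel_log10_top,
                "gel_log10_bottom": config.gel_log10_bottom,
            }
        )
    return echo
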