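"""End-to-end orchestration: simulate -> preprocess -> GLM -> group -> behavior.

`run_pipeline` drives the whole analysis from a single config (dict or YAML
file) with explicit seeds, returning a results bundle and writing tables
under the requested output directory.  Each stage is also callable on its
own (see the stage functions), so intermediates can be re-run and audited.

Sign convention: deoxyhemoglobin falls during activation, so when the
analysis chromophore is HbR the preprocessed series is negated before the
GLM; reported betas and t-values are activation-positive for both
chromophores.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import accuracy, rt_summary
from .geometry import (ProbeLayout, default_analysis_grid,
                       default_probe_layout, fiducial_transform,
                       interpolation_weights, register_to_median)
from .glm import CONTRAST_PRESETS, build_design, contrast, fit_glm
from .group import (channelwise_t, dual_criterion, group_t_map, signflip_mc,
                    threshold_and_cluster)
from .hemodynamics import ExtinctionTable, mbll_invert, od_from_intensity
from .preprocess import PreprocessConfig, preprocess
from .simulate import SimulationConfig, SubjectData, simulate_cohort

__all__ = ["RunManifest", "PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "seed", "output_dir", "simulation", "preprocess", "group", "glm",
    "behavior", "run_signflip", "n_permutations", "contrasts",
}


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def identity(self) -> str:
        """Hash over everything except timings and absolute paths."""
        payload = json.dumps({"config": self.config_hash, "seed": self.seed,
                              "version": self.package_version}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    contrasts: tuple = ("I>C", "G>C")
    run_signflip: bool = False
    n_permutations: int = 1000

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        sim = raw.get("simulation", {})
        pre = raw.get("preprocess", {})
        for section, klass in (("simulation", SimulationConfig),
                               ("preprocess", PreprocessConfig)):
            extra = set(raw.get(section, {})) - {
                f.name for f in klass.__dataclass_fields__.values()}
            if extra:
                raise ValueError(
                    f"unknown config key(s) in {section}: {sorted(extra)}")
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir"),
            simulation=SimulationConfig(**sim),
            preprocess=PreprocessConfig(**pre),
            contrasts=tuple(raw.get("contrasts", ("I>C", "G>C"))),
            run_signflip=bool(raw.get("run_signflip", False)),
            n_permutations=int(raw.get("n_permutations", 1000)),
        )
        cfg.simulation.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        payload = json.dumps(
            {"seed": self.seed, "simulation": asdict(self.simulation),
             "preprocess": asdict(self.preprocess),
             "contrasts": list(self.contrasts)},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def first_level_subject(
    sub: SubjectData,
    pre_config: PreprocessConfig,
    ext: ExtinctionTable | None = None,
    trial_duration: float = 1.5,
) -> dict:
    """Raw intensities -> OD -> concentrations -> preprocessing -> GLM.

    Returns per-task BetaMaps plus QC, on the analysis chromophore with the
    activation-positive sign convention applied.
    """
    ext = ext or ExtinctionTable()
    betas, qc = {}, {}
    for task, intensity in sub.intensity.items():
        od = od_from_intensity(intensity,
                               sub.hemo[task].sample_period,
                               ext.wavelengths)
        hemo = mbll_invert(od, ext)
        result = preprocess(hemo, pre_config, raw_for_qc=intensity)
        series = result["series"]
        if result["chromophore"] == "hbr":
            series = -series  # activation-positive convention
        n_frames = series.shape[1]
        frame_times = np.arange(n_frames) * result["sample_period"]
        design = build_design(sub.schedules[task].trials, frame_times,
                              trial_duration=trial_duration)
        bm = fit_glm(series, design, subject=sub.subject)
        # dead channels carry no data; mark their stats unusable
        bm.betas[result["dead_mask"]] = np.nan
        betas[task] = bm
        qc[task] = {"dead_mask": result["dead_mask"],
                    "channel_rms": result["channel_rms"],
                    "provenance": result["provenance"]}
    return {"betas": betas, "qc": qc}


def subject_contrast(task_betas: dict, preset: str) -> np.ndarray:
    """Combined-across-runs contrast values per channel for one subject.

    Preset weights are split by task and applied to each run's betas; the
    run contributions are summed (runs are independent fits).
    """
    weights = CONTRAST_PRESETS[preset]
    total = None
    for task, bm in task_betas.items():
        w = {name: wt for name, wt in weights.items() if name in bm.names}
        if not w:
            continue
        values, _ = contrast(bm, w)
        total = values if total is None else total + values
    if total is None:
        raise KeyError(f"no regressors match contrast {preset!r}")
    return total


def align_subjects(subjects: list[SubjectData],
                   contrast_values: np.ndarray,
                   template: ProbeLayout) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Register each subject's channels to template space and the median grid.

    Each subject's digitized fiducials drive a similarity transform to the
    template head; channel values are then interpolated at the group-median
    channel coordinates.  Returns (aligned values, median coordinates,
    per-subject registration residuals).
    """
    coords, resids = [], []
    for sub in subjects:
        affine, rms = fiducial_transform(sub.layout.fiducials,
                                         template.fiducials)
        coords.append(sub.layout.transformed(affine).channel_coordinates())
        resids.append({"subject": sub.subject, "residual_rms_mm": rms})
    coords = np.stack(coords)
    aligned, median_coords = register_to_median(coords, contrast_values)
    return aligned, median_coords, pd.DataFrame(resids)


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the full analysis; returns the results bundle.

    The bundle maps stages to their outputs: subjects, per-contrast channel
    stats / cluster tables / dual-criterion findings, behavioral summaries
    and the run manifest.  With ``output_dir`` set, tables are also written
    as TSV/JSON.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    manifest = RunManifest(config_hash=config.hash(), seed=config.seed,
                           package_version=__version__)
    results: dict = {"manifest": manifest}
    t0 = time.perf_counter()

    template = default_probe_layout()
    subjects = simulate_cohort(config.simulation, layout=template)
    manifest.stage_seconds["simulate"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    first_level = [first_level_subject(sub, config.preprocess,
                                       trial_duration=config.simulation.trial_duration)
                   for sub in subjects]
    manifest.stage_seconds["first_level"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    grid = default_analysis_grid(template)
    results["grid"] = grid
    results["contrast"] = {}
    for preset in config.contrasts:
        chan_vals = np.stack([subject_contrast(fl["betas"], preset)
                              for fl in first_level])
        aligned, median_coords, reg = align_subjects(subjects, chan_vals,
                                                     template)
        weights = interpolation_weights(median_coords, grid)
        volumes = aligned @ weights.T
        tmap = group_t_map(volumes, grid)
        clusters, labels = threshold_and_cluster(tmap, return_labels=True)
        chan_stats = channelwise_t(aligned)
        findings = dual_criterion(clusters, labels, grid, chan_stats,
                                  median_coords)
        entry = {
            "channel_values": aligned,
            "median_coords": median_coords,
            "registration": reg,
            "volumes": volumes,
            "tmap": tmap,
            "clusters": clusters,
            "channel_stats": chan_stats,
            "findings": findings,
        }
        if config.run_signflip:
            entry["fpr_table"] = signflip_mc(
                volumes, grid, n_perm=config.n_permutations,
                seed=config.seed)
        results["contrast"][preset] = entry
    manifest.stage_seconds["group"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    trials = pd.concat([sub.behavior for sub in subjects], ignore_index=True)
    results["behavior"] = {
        "trials": trials,
        "congruency": rt_summary(trials, "congruency"),
        "task": rt_summary(trials, "task"),
        "per_task_congruency": {
            task: rt_summary(trials[trials["task"] == task], "congruency")
            for task in trials["task"].unique()
        },
        "accuracy": accuracy(trials),
    }
    manifest.stage_seconds["behavior"] = round(time.perf_counter() - t0, 3)

    if config.output_dir:
        _write_outputs(Path(config.output_dir), results, config)
    return results


def _write_outputs(outdir: Path, results: dict, config: PipelineConfig) -> None:
    from .io import write_json

    outdir.mkdir(parents=True, exist_ok=True)
    manifest: RunManifest = results["manifest"]
    for preset, entry in results["contrast"].items():
        tag = preset.replace(">", "gt")
        entry["clusters"].clusters.to_csv(outdir / f"clusters_{tag}.tsv",
                                          sep="\t", index=False)
        entry["channel_stats"].to_csv(outdir / f"channels_{tag}.tsv",
                                      sep="\t", index=False)
        entry["findings"].to_csv(outdir / f"findings_{tag}.tsv",
                                 sep="\t", index=False)
        if "fpr_table" in entry:
            ft = entry["fpr_table"]
            write_json(outdir / f"fpr_{tag}.json", {
                "cluster_sizes": list(ft.cluster_sizes),
                "p_thresholds": list(ft.p_thresholds),
                "rates": ft.rates,
                "n_permutations": ft.n_permutations,
                "seed": ft.seed,
            })
        manifest.outputs[preset] = str(outdir / f"findings_{tag}.tsv")
    beh = results["behavior"]
    beh["congruency"].conditions.to_csv(outdir / "rt_congruency.tsv",
                                        sep="\t", index=False)
    beh["task"].conditions.to_csv(outdir / "rt_task.tsv", sep="\t",
                                  index=False)
    write_json(outdir / "manifest.json", {
        "config_hash": manifest.config_hash,
        "identity": manifest.identity(),
        "seed": manifest.seed,
        "package_version": manifest.package_version,
        "stage_seconds": manifest.stage_seconds,
        "outputs": manifest.outputs,
    })
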