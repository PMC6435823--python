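"""Seeded end-to-end orchestration: simulate -> detect -> map Pr -> paired analysis.

Each stage writes its artifacts (CSV tables, TIFF images, JSON reports)
under the output directory together with a resolved configuration copy and
a provenance record (stage parameters, seed, package version, counts in and
out). A stage failure aborts the run with the failing stage named; partial
outputs are retained.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .io import write_image, write_json
from .plasticity import (
    fit_scaling_models,
    paired_change_test,
    tercile_change_analysis,
    vehicle_correct,
)
from .puncta import DetectionParams, mask_transfer_measure
from .release import assign_events, correlate_intensity_pr, estimate_pr
from .synthetic import PerturbationModel, gen_az_map, gen_paired_intensities, gen_release_trials, render_puncta_image

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("azquant")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _detection_params(cfg) -> DetectionParams:
    if cfg.background_method == "opening":
        background = {"method": "opening", "radius": cfg.background_radius}
    elif cfg.background_method == "constant":
        background = {"method": "constant"}
    else:
        background = {"method": "none"}
    return DetectionParams(
        gaussian_sigma=cfg.gaussian_sigma,
        noise_tolerance=cfg.noise_tolerance,
        min_intensity=cfg.min_intensity,
        background=background,
    )


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages in order and return the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    dump_config(config, out / "resolved_config.yaml")
    provenance: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    state: dict = {}
    try:
        for stage in config.stages:
            try:
                counts = _STAGES[stage](config, out, state)
            except Exception as exc:
                raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
            provenance["stages"][stage] = counts
            log.info("stage %s: %s", stage, counts)
    finally:
        write_json(out / "provenance.json", provenance)
        log.removeHandler(handler)
        handler.close()
    return out


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    cfg = config.simulate
    seeds = np.random.SeedSequence(config.seed).generate_state(6)
    level_dist = {"shape": cfg.level_shape, "scale": cfg.level_scale, "loc": cfg.level_loc}
    coupling = {"slope": cfg.coupling_slope, "noise_sd": cfg.coupling_noise_sd}
    az_map = gen_az_map(
        cfg.n_az,
        field=tuple(cfg.field),
        level_dist=level_dist,
        coupling=coupling,
        second_channel_r=cfg.second_channel_r,
        min_spacing=cfg.min_spacing,
        seed=int(seeds[0]),
    )
    noise = {"gaussian_sd": cfg.noise_sd} if cfg.noise_sd > 0 else None
    cac = render_puncta_image(
        az_map, psf_sigma=cfg.psf_sigma, background=cfg.background, noise=noise,
        channel="cac", seed=int(seeds[1]),
    )
    brp = render_puncta_image(
        az_map, psf_sigma=cfg.psf_sigma, background=cfg.background, noise=noise,
        channel="brp", use_second_level=True, seed=int(seeds[2]),
    )
    events = gen_release_trials(az_map, cfg.n_stimuli, cfg.jitter_sd, seed=int(seeds[3]))
    model = PerturbationModel(
        mode=cfg.perturbation_mode,
        param=cfg.perturbation_param,
        noise_cv=cfg.perturbation_noise_cv,
        vehicle_drift=cfg.vehicle_drift,
    )
    vehicle_map = gen_az_map(
        cfg.n_vehicle_az,
        field=tuple(cfg.field),
        level_dist=level_dist,
        coupling=coupling,
        second_channel_r=cfg.second_channel_r,
        min_spacing=cfg.min_spacing,
        seed=int(seeds[4]),
    )
    treated, vehicle = gen_paired_intensities(
        az_map, model, vehicle_az_map=vehicle_map, seed=int(seeds[5])
    )

    truth = out / "truth"
    truth.mkdir(exist_ok=True)
    images = out / "images"
    images.mkdir(exist_ok=True)
    az_map.to_frame().to_csv(truth / "az_map.csv", index=False)
    events.events.to_csv(truth / "events.csv", index=False)
    treated.to_csv(truth / "paired_treated.csv", index=False)
    vehicle.to_csv(truth / "paired_vehicle.csv", index=False)
    write_image(images / "cac.tif", cac.pixels)
    write_image(images / "brp.tif", brp.pixels)
    write_json(truth / "generation_params.json", {"seed": config.seed, **asdict(cfg)})

    state.update(
        {"az_map": az_map, "cac": cac, "brp": brp, "events": events,
         "treated": treated, "vehicle": vehicle}
    )
    return {"n_az": len(az_map), "n_events": len(events), "n_stimuli": cfg.n_stimuli}


def _stage_puncta(config: RunConfig, out: Path, state: dict) -> dict:
    params = _detection_params(config.puncta)
    # Brp is the mask-source channel; identical geometry measures both channels
    tables, labels = mask_transfer_measure(
        state["brp"].pixels,
        {"brp": state["brp"].pixels, "cac": state["cac"].pixels},
        params=params,
    )
    pdir = out / "puncta"
    pdir.mkdir(exist_ok=True)
    for name, table in tables.items():
        table.to_csv(pdir / f"puncta_{name}.csv")
    write_image(pdir / "labels.tif", labels.astype(np.uint16))
    state["puncta"] = tables
    return {"n_puncta": len(tables["cac"])}


def _stage_release(config: RunConfig, out: Path, state: dict) -> dict:
    events = state["events"]
    cac = state["puncta"]["cac"]
    assignments = assign_events(events, cac, max_radius=config.events.max_radius)
    release = estimate_pr(assignments, events.n_stimuli, punctum_ids=cac)
    corr = correlate_intensity_pr({"nmj_0": (cac, release)})
    rdir = out / "release"
    rdir.mkdir(exist_ok=True)
    assignments.to_csv(rdir / "events_assigned.csv", index=False)
    release.to_csv(rdir / "release_table.csv")
    write_json(
        rdir / "correlation.json",
        {
            "per_nmj": corr.per_nmj.to_dict(orient="records"),
            "average_r": corr.average_r,
            "excluded": corr.excluded,
        },
    )
    state["release"] = release
    return {
        "n_assigned": int((assignments["punctum_id"] >= 0).sum()),
        "n_unassigned": release.unassigned_event_count,
        "median_pr": float(release.table["pr_estimate"].median()),
    }


def _stage_paired(config: RunConfig, out: Path, state: dict) -> dict:
    corrected = vehicle_correct(state["treated"], state["vehicle"])
    fit = fit_scaling_models(
        corrected.table, rel_tol=config.paired.rel_tol, use_corrected=config.paired.use_corrected
    )
    test = paired_change_test(corrected.table)
    pdir = out / "paired"
    pdir.mkdir(exist_ok=True)
    corrected.table.to_csv(pdir / "paired_corrected.csv", index=False)
    write_json(pdir / "scaling_fit.json", fit.to_dict())
    write_json(pdir / "paired_test.json", {**test, "vehicle_factor": corrected.vehicle_factor})
    counts = {"selected_model": fit.selected_model, "vehicle_factor": corrected.vehicle_factor}
    if len(corrected.table) >= 9:
        terc = tercile_change_analysis(corrected.table)
        terc.table.to_csv(pdir / "terciles.csv", index=False)
        write_json(
            pdir / "tercile_pvalues.json",
            {f"{a}_vs_{b}": p for (a, b), p in terc.pvalues.items()},
        )
    return counts


_STAGES = {
    "simulate": _stage_simulate,
    "puncta": _stage_puncta,
    "release": _stage_release,
    "paired": _stage_paired,
}
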