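"""End-to-end workflow: loading -> imaging -> extraction -> analysis.

One run simulates a chip per cohort (drug condition), renders the
synthetic time-lapse image bundle, runs the image pipeline back over it,
and computes the clonal growth statistics.  Every stage derives its random
stream from the global seed and its stage name, so stages are individually
reproducible, and every output artifact is stamped with the configuration
hash.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .analysis import (assemble_trajectories, cohort_summary, detect_rare_large,
                       filter_trajectories, fit_growth, fits_to_frame,
                       occupancy_heatmap, resample_pvalue)
from .extract import (decode_address, detect_markers, estimate_rotation,
                      extract_apartments)
from .loading import (ChipLayout, LoadingParams, apply_transfer_pulse,
                      make_chip_layout, occupancy_histogram, simulate_loading)
from .population import ClonePopulationSpec, sample_clone_population
from .quantify import RoiSpec, detections_to_frame, segment_cells
from .render import ApartmentTemplate, SceneSpec, render_experiment

__all__ = ["run_pipeline", "default_config", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("load", "render", "extract", "quantify", "analyze")

_KNOWN_KEYS = {"seed", "outdir", "layout", "loading", "population", "scene",
               "timepoints", "cohorts", "analysis", "n_cells_factor"}


def default_config() -> dict:
    """The demo configuration: a small two-street chip, two cohorts."""
    return {
        "seed": 0,
        "layout": {"n_streets": 2, "apartments_per_street": 10},
        "loading": {"defect_prob": 0.05, "doublet_prob": 0.08},
        "n_cells_factor": 1.5,
        "population": {"resistant_fraction": 0.0, "large_cell_fraction": 0.0},
        "scene": {"noise_sigma": 0.0, "rotation_jitter": 0.0},
        "timepoints": [0, 1, 2, 3, 4],
        "cohorts": ["DMSO", "0.5nM"],
        "analysis": {"n_sample": 1000, "n_perm": 999, "z_threshold": 5.0},
    }


def _stage_seed(seed: int, stage: str, cohort: int = 0) -> int:
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage), cohort])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _validate(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")


def run_pipeline(config: dict, outdir: str | Path | None = None,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the workflow and return (and write) the output bundle.

    ``stages`` must be a prefix of the full stage list; artifacts for the
    executed stages are written under ``outdir`` when given.
    """
    _validate(config)
    if list(stages) != list(STAGES[:len(stages)]):
        raise ValueError(f"stages must be a prefix of {STAGES}")
    seed = int(config.get("seed", 0))
    chash = tio.config_hash(config)
    out = Path(outdir or config.get("outdir", ".")) if (
        outdir or config.get("outdir")) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        tio.save_config(config, out / "config.yaml")

    layout = make_chip_layout(config.get("layout", {}))
    template = ApartmentTemplate(
        street_digits=max(2, len(str(layout.n_streets - 1))),
        position_digits=max(2, len(str(layout.apartments_per_street - 1))))
    scene = SceneSpec(template=template, **config.get("scene", {}))
    timepoints = list(config.get("timepoints", [0, 1, 2, 3, 4]))
    cohorts = list(config.get("cohorts", ["DMSO"]))
    results: dict = {"config_hash": chash, "cohorts": {}}

    for ci, cohort in enumerate(cohorts):
        res = _run_cohort(config, layout, template, scene, timepoints,
                          cohort, ci, seed, chash, out, stages)
        results["cohorts"][cohort] = res

    if "analyze" in stages and len(cohorts) > 1:
        control = cohorts[0]
        acfg = config.get("analysis", {})
        pvals = {}
        for cohort in cohorts[1:]:
            fits_a = results["cohorts"][control].get("fits", [])
            fits_b = results["cohorts"][cohort].get("fits", [])
            if fits_a and fits_b:
                p, obs = resample_pvalue(
                    fits_a, fits_b, n_sample=acfg.get("n_sample", 1000),
                    n_perm=acfg.get("n_perm", 999),
                    seed=_stage_seed(seed, "analyze", ci + 100))
                pvals[cohort] = {"p_value": p, "observed_median_shift": obs}
        results["p_values"] = pvals
        if out is not None:
            tio.write_json({"p_values": pvals}, out / "significance.json", chash)
    return results


def _run_cohort(config, layout, template, scene, timepoints, cohort, ci,
                seed, chash, out, stages):
    res: dict = {}
    cohort_dir = out / f"cohort_{cohort.replace('.', 'p')}" if out is not None else None
    if cohort_dir is not None:
        cohort_dir.mkdir(exist_ok=True)

    # --- load ---------------------------------------------------------
    try:
        params = LoadingParams(seed=_stage_seed(seed, "load", ci),
                               **config.get("loading", {}))
        n_cells = int(config.get("n_cells_factor", 1.5) * layout.total_traps)
        state = simulate_loading(layout, params, n_cells)
        state = apply_transfer_pulse(state, params)
        res["occupancy"] = occupancy_histogram(state)
        res["state"] = state
        if cohort_dir is not None:
            occ = pd.DataFrame({
                "street": np.repeat(np.arange(layout.n_streets),
                                    layout.apartments_per_street),
                "position": np.tile(np.arange(layout.apartments_per_street),
                                    layout.n_streets),
                "trap_count": state.trap_counts.ravel(),
                "apartment_count": state.apartment_counts.ravel(),
                "defect": state.defect_flags.ravel(),
            })
            tio.write_table(occ, cohort_dir / "occupancy.csv", chash)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed for cohort {cohort}: {exc}") from exc
    if "render" not in stages:
        return res

    # --- population + render -----------------------------------------
    try:
        counts = state.site_counts.ravel()
        addresses = [(int(i // layout.apartments_per_street),
                      int(i % layout.apartments_per_street))
                     for i in range(layout.total_traps)]
        popspec = ClonePopulationSpec.from_preset(
            cohort, n_clones=layout.total_traps,
            seed=_stage_seed(seed, "render", ci),
            **config.get("population", {}))
        clones = sample_clone_population(popspec, timepoints,
                                         founding_counts=counts)
        bundle = render_experiment(clones, scene, addresses, timepoints,
                                   seed=_stage_seed(seed, "render", ci + 50),
                                   outdir=cohort_dir)
        res["clones"] = clones
        res["bundle"] = bundle
        if cohort_dir is not None:
            tio.write_table(bundle["manifest"], cohort_dir / "manifest.csv", chash)
            tio.write_table(clones, cohort_dir / "ground_truth_clones.csv", chash)
            tio.write_table(bundle["cells"], cohort_dir / "ground_truth_cells.csv", chash)
    except Exception as exc:
        raise RuntimeError(f"stage 'render' failed for cohort {cohort}: {exc}") from exc
    if "extract" not in stages:
        return res

    # --- extract + quantify ------------------------------------------
    try:
        det_frames = []
        manifest = bundle["manifest"]
        roi = RoiSpec.from_template(template)
        for (fov, day), grp in manifest.groupby(["fov", "timepoint"]):
            imgs = {}
            for row in grp.itertuples():
                if cohort_dir is not None:
                    imgs[row.channel] = tio.read_image(cohort_dir / row.file)
                else:
                    imgs[row.channel] = bundle["images"][(fov, day, row.channel)]
            bf = imgs["brightfield"]
            markers = detect_markers(bf, scene)
            if len(markers) == 0:
                logger.warning("no markers in fov %s t=%s", fov, day)
                continue
            angle = estimate_rotation(markers, col_pitch=scene.pitch[1]) \
                if len(markers) >= 2 else 0.0
            crops = {ch: extract_apartments(img, markers, angle, scene, fov=int(fov))
                     for ch, img in imgs.items()}
            if "quantify" not in stages:
                continue
            for k, ap in enumerate(crops["brightfield"]):
                addr = decode_address(ap, template, layout=layout)
                if not addr.reliable:
                    continue
                chans = {ch: crops[ch][k].pixels for ch in crops if ch != "brightfield"}
                dets = segment_cells(ap.pixels, roi, scene.pixel_size,
                                     channel_images=chans)
                if dets:
                    det_frames.append(detections_to_frame(
                        dets, fov=int(fov), street=addr.street,
                        position=addr.position, timepoint=float(day)))
        detections = (pd.concat(det_frames, ignore_index=True) if det_frames
                      else detections_to_frame([]))
        res["detections"] = detections
        if cohort_dir is not None and "quantify" in stages:
            tio.write_table(detections, cohort_dir / "detections.csv", chash)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'extract/quantify' failed for cohort {cohort}: "
                           f"{exc}") from exc
    if "analyze" not in stages or not len(detections):
        return res

    # --- analyze ------------------------------------------------------
    try:
        acfg = config.get("analysis", {})
        trajectories = assemble_trajectories(detections, cohort=cohort)
        kept = filter_trajectories(trajectories)
        fits = [fit_growth(tr) for tr in kept if len(tr.timepoints) >= 3]
        res["fits"] = fits
        if fits:
            res["summary"] = cohort_summary(fits)
            if len(fits) >= 10:
                try:
                    rare, freq = detect_rare_large(
                        fits, z_threshold=acfg.get("z_threshold", 5.0))
                    res["rare"] = {"n": len(rare), "frequency": freq}
                except ValueError:
                    res["rare"] = {"n": 0, "frequency": 0.0}
        mat, logmat = occupancy_heatmap(detections, layout,
                                        timepoint=float(timepoints[0]))
        res["heatmap"] = mat
        if cohort_dir is not None:
            tio.write_table(fits_to_frame(fits), cohort_dir / "growth_fits.csv", chash)
            tio.write_table(pd.DataFrame(mat), cohort_dir / "heatmap_t0.csv", chash)
            if res.get("summary"):
                s = res["summary"]
                tio.write_json({k: getattr(s, k) for k in (
                    "n", "median_lam", "lam_q1", "lam_q3", "max_lam",
                    "median_area", "area_q1", "area_q3")},
                    cohort_dir / "cohort_summary.json", chash)
            _save_heatmap_figure(logmat, cohort_dir / "heatmap_t0.png")
    except Exception as exc:
        raise RuntimeError(f"stage 'analyze' failed for cohort {cohort}: {exc}") from exc
    return res


def _save_heatmap_figure(logmat: np.ndarray, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(logmat, aspect="auto", cmap="viridis")
    ax.set_xlabel("apartment position")
    ax.set_ylabel("street")
    fig.colorbar(im, ax=ax, label="log10(cells + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
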