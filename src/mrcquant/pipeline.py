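"""End-to-end orchestration: simulate (or load), analyze, and report.

A pipeline run is driven by a single config mapping (usually loaded from
YAML) naming one or more conditions and the stages to execute.  Every
quantity in the report is computed by the stage modules; the report embeds
the config hash and seed so identical inputs reproduce byte-identical
output.

Config layout (all blocks optional except ``conditions``)::

    seed: 7
    stages: [spots, coloc, condensates, frap, spt]
    detection: {threshold_k: 5.0}
    coloc: {max_dist_um: 0.3}
    conditions:
      - name: strong_binder
        n_replicates: 3
        cells_per_replicate: 15
        simulation: {coloc_fraction: 0.9, prey_to_bait_ratio: 0.7}
        frap: {A: 0.55, tau: 3.0, n_traces: 5, noise_sd: 1.0}
        spt: {D_inside: 0.01, D_outside: 0.1, n_tracks: 15,
              confinement_radius: 0.2}
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np

from . import __version__
from .coloc import match_spots, snr_ratio_stat, spot_snr
from .condensates import (classify_condensate_vs_punctum, morphology_summary,
                          segment_condensates)
from .frap import correct_and_normalize, fit_recovery, fractional_recovery
from .simulate import (SimulationConfig, default_frap_time_grid,
                       generate_cell_image, generate_condensate_image,
                       generate_frap_trace, generate_trajectories)
from .spots import detect_spots, summarize_cells
from .spt import compare_regions, fit_diffusion, time_averaged_msd
from .stats import group_compare

__all__ = ["run_pipeline", "config_hash"]

_DEFAULT_STAGES = ("spots", "coloc", "condensates", "frap", "spt")


def config_hash(config: dict) -> str:
    """Stable SHA-256 of the canonical JSON form of the config."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sub_seed(base: int, *tags: Any) -> int:
    """Deterministic per-stage seed below 2**31 derived from the base seed."""
    h = hashlib.sha256(repr((base, tags)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _spots_and_coloc(
    cond: dict, seed: int, detection: dict, coloc_cfg: dict, stages: set[str]
) -> dict:
    """Simulate replicates of bait/prey fields, detect spots, and score
    colocalization and SNR ratios."""
    n_reps = int(cond.get("n_replicates", 3))
    n_cells = int(cond.get("cells_per_replicate", 15))
    sim_kwargs = dict(cond.get("simulation", {}))
    threshold_k = float(detection.get("threshold_k", 5.0))
    psf_sigma = float(sim_kwargs.get("psf_sigma", 1.6))
    max_dist = float(coloc_cfg.get("max_dist_um", 0.3))

    rep_coloc_means: list[float] = []
    rep_pct_with_spots: list[float] = []
    all_counts: list[int] = []
    all_ratios: list[float] = []
    for rep in range(n_reps):
        side = int(np.ceil(np.sqrt(n_cells)))
        cfg = SimulationConfig(
            n_cells=n_cells,
            image_shape=(64 * side, 64 * side),
            seed=_sub_seed(seed, cond["name"], "cells", rep),
            **sim_kwargs,
        )
        stack, mask, _truth = generate_cell_image(cfg)
        bait = detect_spots(stack, mask, channel=0, threshold_k=threshold_k,
                            psf_sigma=psf_sigma)
        prey = detect_spots(stack, mask, channel=1, threshold_k=threshold_k,
                            psf_sigma=psf_sigma)
        _summaries, pop = summarize_cells(bait + prey, mask)
        rep_pct_with_spots.append(pop["channels"][0]["percent_cells_with_spots"])
        for cid in (int(i) for i in np.unique(mask) if i > 0):
            all_counts.append(sum(1 for s in bait if s.cell_id == cid))

        if "coloc" in stages:
            cell_pcts = []
            for cid in (int(i) for i in np.unique(mask) if i > 0):
                b = [s for s in bait if s.cell_id == cid]
                p = [s for s in prey if s.cell_id == cid]
                if not b:
                    continue  # cells without bait spots are excluded
                res = match_spots(b, p, max_dist_um=max_dist)
                cell_pcts.append(res.coloc_percent)
                all_spots = bait + prey
                for bs, ps, _d in res.pairs:
                    try:
                        mb = spot_snr(stack, bs, exclusion_spots=all_spots,
                                      psf_sigma=psf_sigma)
                        mp = spot_snr(stack, ps, exclusion_spots=all_spots,
                                      psf_sigma=psf_sigma)
                    except ValueError:
                        continue
                    if mp.snr > 0:
                        all_ratios.append(mb.snr / mp.snr)
            if cell_pcts:
                rep_coloc_means.append(float(np.mean(cell_pcts)))

    counts = np.array(all_counts)
    hist = {int(k): 100.0 * float(np.mean(counts == k))
            for k in range(int(counts.max()) + 1)} if counts.size else {}
    out: dict = {
        "n_replicates": n_reps,
        "cells_per_replicate": n_cells,
        "percent_cells_with_spots": {
            "mean": float(np.mean(rep_pct_with_spots)),
            "sd": float(np.std(rep_pct_with_spots, ddof=1))
            if len(rep_pct_with_spots) > 1 else 0.0,
            "n": len(rep_pct_with_spots),
        },
        "spot_count_distribution_percent": hist,
    }
    if "coloc" in stages:
        out["coloc_percent"] = {
            "mean": float(np.mean(rep_coloc_means)) if rep_coloc_means else 0.0,
            "sd": float(np.std(rep_coloc_means, ddof=1))
            if len(rep_coloc_means) > 1 else 0.0,
            "n": len(rep_coloc_means),
            "max_dist_um": max_dist,
        }
        if all_ratios:
            stat = snr_ratio_stat_from_values(all_ratios)
            out["snr_ratio"] = stat
    return out


def snr_ratio_stat_from_values(ratios: list[float]) -> dict:
    arr = np.asarray(ratios, dtype=float)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "n": int(arr.size),
    }


def _condensate_stage(cond: dict, seed: int, detection: dict) -> dict:
    sim_kwargs = dict(cond.get("condensate_simulation", {}))
    n_cells = int(cond.get("cells_per_replicate", 15))
    side = int(np.ceil(np.sqrt(n_cells)))
    cfg = SimulationConfig(
        n_cells=n_cells,
        image_shape=(96 * side, 96 * side),
        seed=_sub_seed(seed, cond["name"], "condensates"),
        **sim_kwargs,
    )
    stack, mask, _truth = generate_condensate_image(cfg)
    objs = segment_condensates(
        stack.channel(0), mask,
        threshold_k=float(detection.get("condensate_threshold_k", 3.0)),
        pixel_size_um=cfg.pixel_size,
    )
    summary = morphology_summary(objs, n_cells=n_cells)
    labels = classify_condensate_vs_punctum(objs)
    return {
        "n_condensates": len(objs),
        "percent_cells_with_condensates": summary.percent_cells_with_condensates,
        "mean_log10_area": float(summary.log10_areas.mean())
        if summary.log10_areas.size else None,
        "mean_circularity": float(summary.circularities.mean())
        if summary.circularities.size else None,
        "n_classified_condensate": labels.count("condensate"),
        "n_classified_punctum": labels.count("punctum"),
    }


def _frap_stage(cond: dict, seed: int) -> dict:
    frap_cfg = dict(cond.get("frap", {}))
    A = float(frap_cfg.get("A", 0.55))
    tau = float(frap_cfg.get("tau", 3.0))
    n_traces = int(frap_cfg.get("n_traces", 5))
    noise_sd = float(frap_cfg.get("noise_sd", 1.0))
    drift = float(frap_cfg.get("drift_rate", 0.2))
    t = default_frap_time_grid()
    bleach_index = int(np.sum(t < 0))
    fits = []
    for i in range(n_traces):
        bleached, control = generate_frap_trace(
            A, tau, t, noise_sd=noise_sd, drift_rate=drift,
            seed=_sub_seed(seed, cond["name"], "frap", i),
        )
        trace = correct_and_normalize(bleached, control, bleach_index, time=t)
        trace = fractional_recovery(trace)
        fits.append(fit_recovery(trace))
    mob = np.array([f.mobile_fraction for f in fits])
    taus = np.array([f.tau_s for f in fits])
    return {
        "n_traces": n_traces,
        "per_trace_mobile_fraction": [float(v) for v in mob],
        "mobile_fraction": {"mean": float(mob.mean()),
                            "sd": float(mob.std(ddof=1)) if mob.size > 1 else 0.0},
        "tau_s": {"mean": float(taus.mean()),
                  "sd": float(taus.std(ddof=1)) if taus.size > 1 else 0.0},
        "percent_recovery": {"mean": float(mob.mean() * 100.0),
                             "sd": float(mob.std(ddof=1) * 100.0)
                             if mob.size > 1 else 0.0},
        "n_converged": int(sum(f.converged for f in fits)),
    }


def _spt_stage(cond: dict, seed: int) -> dict:
    spt_cfg = dict(cond.get("spt", {}))
    d_in = float(spt_cfg.get("D_inside", 0.01))
    d_out = float(spt_cfg.get("D_outside", 0.1))
    n_tracks = int(spt_cfg.get("n_tracks", 15))
    conf = spt_cfg.get("confinement_radius", 0.2)
    dt = float(spt_cfg.get("dt", 0.1))
    n_steps = int(spt_cfg.get("n_steps", 100))

    from .spt import Trajectory  # local import to keep module load light

    def _fits(D, confinement, tag):
        tracks = generate_trajectories(
            D, dt, n_steps, n_tracks, confinement_radius=confinement,
            seed=_sub_seed(seed, cond["name"], "spt", tag),
        )
        fits = []
        for k, pos in enumerate(tracks):
            traj = Trajectory(track_id=k, frames=np.arange(pos.shape[0]),
                              positions=pos, dt=dt)
            fits.append(fit_diffusion(time_averaged_msd(traj)))
        return fits

    fits_in = _fits(d_in, conf, "inside")
    fits_out = _fits(d_out, None, "outside")
    comparison = compare_regions(fits_in, fits_out)
    return {
        "n_tracks_per_group": n_tracks,
        "mean_alpha_inside": float(np.mean([f.alpha for f in fits_in])),
        "mean_alpha_outside": float(np.mean([f.alpha for f in fits_out])),
        "comparison": comparison,
    }


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages for every condition and return the
    report as a JSON-serializable dict.

    Identical config + seed produce an identical report.  When more than
    one condition provides FRAP mobile fractions, a cross-condition group
    comparison (t-test or ANOVA + Tukey) is appended.
    """
    if "conditions" not in config or not config["conditions"]:
        raise ValueError("pipeline config must name at least one condition")
    seed = int(config.get("seed", 0))
    stages = set(config.get("stages", _DEFAULT_STAGES))
    detection = dict(config.get("detection", {}))
    coloc_cfg = dict(config.get("coloc", {}))

    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(config),
            "stages": sorted(stages),
        },
        "conditions": {},
    }
    frap_mobiles: dict[str, list[float]] = {}
    for cond in config["conditions"]:
        name = cond["name"]
        block: dict = {}
        try:
            if "spots" in stages:
                block.update(_spots_and_coloc(cond, seed, detection,
                                              coloc_cfg, stages))
            if "condensates" in stages:
                block["condensates"] = _condensate_stage(cond, seed, detection)
            if "frap" in stages:
                block["frap"] = _frap_stage(cond, seed)
            if "spt" in stages:
                block["spt"] = _spt_stage(cond, seed)
        except Exception as exc:  # structured error naming the stage
            raise RuntimeError(
                f"pipeline failed for condition {name!r}: {exc}"
            ) from exc
        report["conditions"][name] = block

    if "frap" in stages and len(config["conditions"]) >= 2:
        for cond in config["conditions"]:
            name = cond["name"]
            frap_mobiles[name] = report["conditions"][name]["frap"][
                "per_trace_mobile_fraction"]
        test = group_compare({k: np.asarray(v) for k, v in frap_mobiles.items()})
        report["frap_group_test"] = {
            "test": test.test,
            "groups": test.groups,
            "statistic": test.statistic,
            "p_value": test.p_value,
            "stars": test.stars,
            "letters": test.letters,
        }
    report["notes"] = [
        "multiple-testing beyond Tukey HSD is not adjusted across conditions",
    ]
    return report
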