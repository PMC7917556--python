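"""End-to-end pipeline: generate/load → segment → trace → fit → cluster.

``analyze_cell`` turns one recording bundle (two channels + ephys) into
per-synapse records; ``run_pipeline`` orchestrates a multi-cell synthetic
experiment, assembles the profile table, clusters it, and writes CSV/JSON
outputs plus a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import IHCSynapseError, NormalizationError, FitError
from .imaging import (ROISet, background_region, background_trace, best_plane,
                      delta_f_image, detect_rois)
from .fvfit import (apparent_cooperativity_truth, cooperativity_from_fits,
                    fit_ca_fv, fit_release_boltzmann, rhodff_peak)
from .population import (CLUSTER_PROPERTIES, axis_position, build_table,
                         cluster, compare_groups, correlate, fit_cell_ellipse,
                         pca_project)
from .synthgen import (AcquisitionParams, GradientParams, RecordingBundle,
                       render_experiment, sample_ground_truth)
from .traces import FluorescenceTrace, auc, bandstop_33, bleach_correct, normalize

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the study's analysis constants."""

    out_dir: str = "runs/synthetic"
    n_cells: int = 4
    synapses_per_cell: int = 2
    seed: int = 0
    # analysis constants
    baseline_frames: int = 15
    response_avg_frames: int = 5       # frames averaged for the dF image
    auc_frames: int = 40
    notch_hz: float = 100.0 / 3.0
    hanning_window: int = 7
    r2_gate: float = 0.7
    coop_grid_mV: tuple[float, float] = (-57.0, -17.0)
    coop_cutoff: float = 0.25
    v_r_mV: float = 47.6
    filter_kind: str = "gaussian"      # dual-color recipe
    filter_param: float = 2.0
    min_area_px: int = 20
    match_dist_px: float = 10.0        # bouton ↔ Ca hot-spot gate
    pillar_side: str = "left"
    k_clusters: int = 3
    # generator conditions
    gradient: GradientParams = field(default_factory=GradientParams)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def to_dict(self) -> dict:
        return asdict(self)


def paper_scale_config(out_dir: str = "runs/paper_scale",
                       seed: int = 0) -> PipelineConfig:
    """The 34-cell / 55-synapse study-scale preset (21 cells with two
    synapses, 13 with one)."""
    cfg = PipelineConfig(out_dir=out_dir, n_cells=34, synapses_per_cell=0,
                         seed=seed)
    cfg._synapse_counts = [2] * 21 + [1] * 13   # type: ignore[attr-defined]
    return cfg


def _synapse_counts(cfg: PipelineConfig) -> list[int]:
    counts = getattr(cfg, "_synapse_counts", None)
    if counts is None:
        counts = [cfg.synapses_per_cell] * cfg.n_cells
    return counts


# ---------------------------------------------------------------------------
# Per-cell analysis


def analyze_cell(bundle: RecordingBundle, cfg: PipelineConfig | None = None,
                 cell_id: int = 0) -> list[dict]:
    """Full single-cell analysis of a dual-color bundle.

    Returns one record dict per matched synapse (iGluSnFR bouton paired
    with a Rhod-FF Ca2+ hot spot within ``match_dist_px``), carrying the
    11 clustering properties, the axis position, QC flags, and — when the
    bundle has ground truth — the matched true parameters (``true_*``).
    """
    cfg = cfg or PipelineConfig()
    glu_sweeps = bundle.channels["iGluSnFR"]
    rhod_sweeps = bundle.channels["RhodFF"]

    # --- iGluSnFR: mask from the strongest stimulation -------------------
    strongest = max(glu_sweeps, key=lambda s: s.stim["level_mV"])
    onset = strongest.stim_onset_index
    dfi = delta_f_image(strongest.movie[0],
                        (onset - cfg.baseline_frames, onset),
                        (onset, onset + cfg.response_avg_frames))
    glu_rois = detect_rois(dfi, filter_kind=cfg.filter_kind,
                           size_or_sigma=cfg.filter_param,
                           min_area_px=cfg.min_area_px)
    frame_shape = strongest.movie.shape[2:]
    bg_rect = background_region(frame_shape, glu_rois,
                                pillar_side=cfg.pillar_side)
    glu_rois.background_rect = bg_rect

    # --- per-bouton AUC versus step level --------------------------------
    auc_by_roi: dict[int, list[tuple[float, float]]] = {r.id: []
                                                        for r in glu_rois.rois}
    for sw in glu_sweeps:
        bg = background_trace(sw.movie[0], bg_rect)
        for roi in glu_rois.rois:
            raw = sw.movie[0][:, roi.pixel_mask].mean(axis=1)
            tr = FluorescenceTrace(
                raw, rate_hz=sw.rate_hz,
                baseline_window=(sw.stim_onset_index - cfg.baseline_frames,
                                 sw.stim_onset_index),
                stim_onset_index=sw.stim_onset_index)
            try:
                dff = normalize(tr, bg)
            except NormalizationError:
                continue
            corrected, _ = bleach_correct(dff, response_frames=cfg.auc_frames)
            auc_by_roi[roi.id].append(
                (sw.stim["level_mV"],
                 auc(corrected, n_frames=cfg.auc_frames)))

    # --- Rhod-FF: hot spots from the plane-mean dF image -----------------
    ramp = rhod_sweeps[0]
    v_frames = np.asarray(ramp.stim["frame_voltage_mV"], dtype=float)
    r_onset = ramp.stim_onset_index
    resp_sel = np.flatnonzero((v_frames >= -37.0) & (v_frames <= 3.0))
    mean_movie = ramp.movie.mean(axis=0)
    resp_window = (int(resp_sel[0]), int(resp_sel[-1]) + 1)
    rhod_dfi = delta_f_image(mean_movie,
                             (r_onset - cfg.baseline_frames, r_onset),
                             resp_window)
    hotspots = detect_rois(rhod_dfi, filter_kind=cfg.filter_kind,
                           size_or_sigma=cfg.filter_param,
                           min_area_px=cfg.min_area_px)
    rhod_bg_rect = background_region(frame_shape, hotspots,
                                     pillar_side=cfg.pillar_side)

    # cell boundary from the baseline Rhod-FF image (central plane)
    n_planes = ramp.movie.shape[0]
    baseline_img = ramp.movie[n_planes // 2,
                              r_onset - cfg.baseline_frames:r_onset].mean(axis=0)
    ellipse = fit_cell_ellipse(baseline_img, pillar_side=cfg.pillar_side)

    plane_dF = np.stack([
        delta_f_image(ramp.movie[p], (r_onset - cfg.baseline_frames, r_onset),
                      resp_window).pixels
        for p in range(n_planes)])

    in_ramp = np.flatnonzero(v_frames > ramp.stim.get("range_mV", [-87])[0])
    records = []
    for spot in hotspots.rois:
        plane = best_plane(plane_dF, spot)
        spot.best_plane = plane
        movie = ramp.movie[plane]
        raw = movie[:, spot.pixel_mask].mean(axis=1)
        tr = FluorescenceTrace(
            raw, rate_hz=ramp.rate_hz,
            baseline_window=(r_onset - cfg.baseline_frames, r_onset),
            stim_onset_index=r_onset)
        tr = bandstop_33(tr, center_hz=cfg.notch_hz)
        bg = background_trace(movie, rhod_bg_rect)
        try:
            dff = normalize(tr, bg.mean())
        except NormalizationError:
            continue
        ca_fit = fit_ca_fv(v_frames[in_ramp], dff.samples[in_ramp],
                           v_r_mV=cfg.v_r_mV, r2_gate=cfg.r2_gate)
        peak = rhodff_peak(v_frames, dff.samples)

        # pair with the nearest iGluSnFR bouton
        partner, best_d = None, np.inf
        for roi in glu_rois.rois:
            d = float(np.hypot(roi.centroid_xy[0] - spot.centroid_xy[0],
                               roi.centroid_xy[1] - spot.centroid_xy[1]))
            if d < best_d:
                partner, best_d = roi, d
        if partner is None or best_d > cfg.match_dist_px:
            log.info("cell %s: hot spot %d has no bouton within %.0f px",
                     cell_id, spot.id, cfg.match_dist_px)
            continue
        pairs = sorted(auc_by_roi[partner.id])
        if len(pairs) < 5:
            continue
        levels = np.array([p[0] for p in pairs])
        aucs = np.array([p[1] for p in pairs])
        rel_fit = fit_release_boltzmann(levels, aucs, r2_gate=cfg.r2_gate)

        rec = {
            "cell_id": cell_id, "synapse_id": spot.id,
            "hotspot_x_px": spot.centroid_xy[0],
            "hotspot_y_px": spot.centroid_xy[1],
            "best_plane": plane,
            "position_01": axis_position(ellipse, spot.centroid_xy),
            "v_half_ca_mV": ca_fit.v_half_mV, "k_ca_mV": ca_fit.k_mV,
            "v10_ca_mV": ca_fit.v10_mV, "dr_ca_mV": ca_fit.dynamic_range_mV,
            "peak_rhod_dff": peak,
            "v_half_rel_mV": rel_fit.v_half_mV, "k_rel_mV": rel_fit.k_mV,
            "v10_rel_mV": rel_fit.v10_mV, "dr_rel_mV": rel_fit.dynamic_range_mV,
            "max_auc_rel": float(aucs.max()),
            "ca_r2": ca_fit.r_squared, "rel_r2": rel_fit.r_squared,
            "excluded": bool(ca_fit.excluded or rel_fit.excluded),
        }
        if not (ca_fit.excluded or rel_fit.excluded):
            try:
                coop = cooperativity_from_fits(
                    ca_fit, rel_fit, grid_mV=cfg.coop_grid_mV,
                    cutoff=cfg.coop_cutoff)
                rec["m"] = coop.m
                rec["coop_r2"] = coop.r_squared
                rec["excluded"] = rec["excluded"] or coop.excluded
            except FitError:
                rec["m"] = np.nan
        else:
            rec["m"] = np.nan
        records.append(rec)

    if bundle.ground_truth is not None:
        _attach_ground_truth(records, bundle.ground_truth)
    return records


def _attach_ground_truth(records, gt, max_dist_px: float = 5.0):
    """Pair analyzed hot spots with ground-truth synapses by distance."""
    for rec in records:
        best, best_d = None, np.inf
        for syn in gt.synapses:
            d = float(np.hypot(syn.hotspot_xy_px[0] - rec["hotspot_x_px"],
                               syn.hotspot_xy_px[1] - rec["hotspot_y_px"]))
            if d < best_d:
                best, best_d = syn, d
        if best is not None and best_d <= max_dist_px:
            rec.update({"true_v_half_ca_mV": best.v_half_ca_mV,
                        "true_k_ca_mV": best.k_ca_mV,
                        "true_m": best.m,
                        "true_m_apparent": apparent_cooperativity_truth(best),
                        "true_position_01": best.position_01,
                        "true_plane": best.plane_index,
                        "match_dist_px": best_d})


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run a full synthetic experiment and write all outputs.

    Per cell: sample ground truth, render both channels and ephys, analyze.
    Population stage: profile table, Pearson correlations, K-means (K=3),
    PCA, pillar-vs-modiolar statistics.  A manifest records the config
    hash, seeds and package version; reruns with the same config are
    bit-identical.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, errors = [], []
    counts = _synapse_counts(cfg)
    for i, n_syn in enumerate(counts):
        try:
            gt = sample_ground_truth(n_syn, cfg.gradient,
                                     seed=cfg.seed + 1000 + i)
            bundle = render_experiment(gt, cfg.acquisition,
                                       seed=cfg.seed + 5000 + 10 * i)
            records.extend(analyze_cell(bundle, cfg, cell_id=i))
        except IHCSynapseError as exc:     # record, keep going
            errors.append({"cell_id": i, "error": str(exc)})
            log.warning("cell %d failed: %s", i, exc)

    table = build_table(records)
    n_ok = int(table["qc_pass"].sum()) if len(table) else 0
    if n_ok >= max(cfg.k_clusters, 3):
        table = cluster(table, k=cfg.k_clusters, seed=cfg.seed)
        corr = correlate(table)
        corr.to_csv(out / "correlations.csv")
        scores, loadings, evr = pca_project(table)
        pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
                     ).to_csv(out / "pca_scores.csv", index=False)
        np.savetxt(out / "pca_explained_variance.csv", evr, delimiter=",")
        try:
            stats_df = compare_groups(table)
            stats_df.to_csv(out / "group_stats.csv", index=False)
        except IHCSynapseError as exc:
            errors.append({"stage": "group_stats", "error": str(exc)})
    table.to_csv(out / "synapse_profiles.csv", index=False)

    cfg_dict = cfg.to_dict()
    manifest = {
        "package_version": _pkg_version,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": cfg.seed,
        "n_cells": len(counts),
        "n_synapses_analyzed": int(len(table)),
        "n_synapses_qc_pass": n_ok,
        "cluster_properties": list(CLUSTER_PROPERTIES),
        "errors": errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
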