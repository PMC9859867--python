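"""End-to-end cohort pipeline: simulate -> curves -> phases -> align -> profile -> stats.

Every stage is seeded from the run configuration, so a rerun with the same
configuration is bit-identical; output file names embed the configuration
hash and seed for provenance.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ctio
from .alignment import align_mcta, summarize_phase_distribution
from .curves import (ExtractionParams, av_ratio, extract_tics,
                     mip_collateral_ratio, roi_enhancement)
from .errors import CollateralTimeError
from .io import RunConfig
from .phases import normalize_av_curve
from .stats import association_table, correlation_matrix, summary_table, upper_triangle
from .synthetic import PhantomModel, cohort_configs, sample_mcta
from .timepoints import (CR_VARIABLES, extract_cr_profile, find_timepoints)
from .vessels import (SegmentationParams, baseline_volume, collateral_ratio,
                      enhanced_vessel_volume, segment_vessels)

log = logging.getLogger("collateraltime")


def demo_config() -> RunConfig:
    """The packaged demo configuration: a 58-subject synthetic cohort."""
    with resources.files("collateraltime.configs").joinpath("demo.yaml").open() as fh:
        import yaml
        return ctio.run_config_from_dict(yaml.safe_load(fh))


def process_subject(model: PhantomModel,
                    truth,
                    seg: SegmentationParams,
                    ext: ExtractionParams,
                    grid_step_s: float = 0.1,
                    mcta_rng: np.random.Generator | None = None) -> dict:
    """Run the full per-subject analysis; returns a flat cohort record."""
    series = model.simulate_series()
    regions = model.region_spec()
    tics = extract_tics(series, regions, seg, ext)
    landmarks = find_timepoints(tics, ext)
    cr_mip = mip_collateral_ratio(series, regions, seg)

    # mCTA sampling from the continuous model at the bolus-tracked times
    noise = model.config.noise_sd_hu if mcta_rng is not None else 0.0
    volumes, _ = sample_mcta(model, truth.true_mcta_offset_s, truth.mcta_delays_s,
                             noise_sd_hu=noise, rng=mcta_rng)
    baseline = baseline_volume(series, seg)
    vox = series.voxel_size_mm
    mcta_crs, mcta_ratios = [], []
    for vol in volumes:
        m_occ = segment_vessels(vol, baseline, seg, regions.mca_occluded_mask)
        m_con = segment_vessels(vol, baseline, seg, regions.mca_contralateral_mask)
        mcta_crs.append(collateral_ratio(enhanced_vessel_volume(m_occ, vox),
                                         enhanced_vessel_volume(m_con, vox), seg))
        art = roi_enhancement(vol, regions.arterial_roi.center_vox,
                              regions.arterial_roi.radius_mm, vox)
        ven = roi_enhancement(vol, regions.venous_roi.center_vox,
                              regions.venous_roi.radius_mm, vox)
        mcta_ratios.append(av_ratio(art, ven, ext.blood_hu))

    norm = normalize_av_curve(tics, ext.smoothing_window)
    alignment = align_mcta(mcta_ratios, truth.mcta_delays_s, tics,
                           grid_step_s=grid_step_s, phase_curve=norm)
    profile = extract_cr_profile(tics, landmarks, cr_mip, alignment, mcta_crs)

    rec = profile.as_record()
    rec.update({
        "occlusion_side": truth.occlusion_side,
        "collateral_fraction": truth.collateral_fraction,
        "true_mcta_offset_s": truth.true_mcta_offset_s,
        "recovered_mcta_offset_s": alignment.offset_s,
        "alignment_residual": alignment.residual,
        "arrival_s": tics.arrival_s,
        "aspects": truth.covariates.get("aspects"),
        "nihss": truth.covariates.get("nihss"),
    })
    return rec, profile, alignment


def run_cohort(config: RunConfig):
    """Simulate and analyse the whole cohort; returns the cohort DataFrame
    plus the per-subject profiles and alignments."""
    subjects = cohort_configs(config.n_subjects, config.phantom, config.seed,
                              aspects_noise_sd=config.aspects_noise_sd,
                              nihss_noise_sd=config.nihss_noise_sd)
    records, profiles, alignments = [], [], []
    for i, (cfg, truth) in enumerate(subjects):
        mcta_rng = np.random.default_rng(np.random.SeedSequence([config.seed, i, 1]))
        model = PhantomModel(cfg)
        try:
            rec, profile, alignment = process_subject(
                model, truth, config.segmentation, config.extraction,
                config.alignment_grid_step_s, mcta_rng)
        except CollateralTimeError as exc:
            log.error("stage failure in subject %03d: %s", i, exc)
            raise
        rec["subject"] = f"sub-{i:03d}"
        records.append(rec)
        profiles.append(profile)
        alignments.append(alignment)
        log.info("subject %03d done (cf=%.2f)", i, truth.collateral_fraction)
    cohort = pd.DataFrame(records).set_index("subject")
    return cohort, profiles, alignments


def run_pipeline(config: RunConfig | None = None, out_dir=None) -> dict:
    """Execute the full pipeline and write all cohort artifacts.

    Returns a dict with the cohort table, statistics tables and file paths.
    """
    config = config if config is not None else demo_config()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{config.config_hash()}_seed{config.seed}"
    log.info("pipeline start: %d subjects, tag %s", config.n_subjects, tag)

    cohort, profiles, alignments = run_cohort(config)

    corr = correlation_matrix(cohort)
    assoc_aspects = association_table(cohort, "aspects")
    assoc_nihss = association_table(cohort, "nihss")
    phase_counts = summarize_phase_distribution(alignments)
    timing_cols = ([f"t_{lm}_since_arrival_s" for lm in
                    ("vol_max", "vol_occluded_max", "arterial_max",
                     "venous_max", "equi", "av_max")]
                   + [c for c in CR_VARIABLES if c in cohort.columns])
    summary = summary_table(cohort, timing_cols)

    paths = {}
    ff = "%.10g"
    artifacts = {
        "cohort": (cohort, True),
        "correlation_matrix": (upper_triangle(corr), True),
        "association_aspects": (assoc_aspects, True),
        "association_nihss": (assoc_nihss, True),
        "phase_distribution": (phase_counts, True),
        "summary": (summary, True),
    }
    for name, (df, with_index) in artifacts.items():
        p = out / f"{name}_{tag}.csv"
        df.to_csv(p, index=with_index, float_format=ff)
        paths[name] = p
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "n_subjects": config.n_subjects,
                "files": {k: str(v) for k, v in paths.items()}}
    (out / f"manifest_{tag}.json").write_text(json.dumps(manifest, indent=2))
    ctio.save_run_config(config, out / f"config_{tag}.yaml")
    log.info("pipeline done: %s", out)
    return {"cohort": cohort, "correlation_matrix": corr,
            "association_aspects": assoc_aspects, "association_nihss": assoc_nihss,
            "phase_distribution": phase_counts, "summary": summary,
            "profiles": profiles, "alignments": alignments, "paths": paths,
            "tag": tag}
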