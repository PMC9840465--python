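"""End-to-end orchestration: simulate -> reconstruct -> quantify.

Runs the full synthetic-well workflow and writes every intermediate
artifact under a stable directory layout::

    out_dir/
      tiles/       per-tile z-stack TIFFs + metadata.json + ground_truth.csv
      composites/  stitched composite + height-map TIFFs, offsets.csv
      labels/      dome label map TIFF
      metrics/     metrics.csv (well, field, metric, value), provenance.json

Reruns with the same config are bit-identical; every output directory
carries a provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .config import RunConfig, config_hash
from .quantify import (
    MonolayerMetrics,
    ThresholdSpec,
    classify_enlarged,
    count_large_puncta,
    count_nuclei,
    segment_domes,
    segment_mitochondria,
)
from .reconstruction import edf_compose, register_tiles, stitch
from .scene import (
    ScenePars,
    generate_scene,
    random_dome_specs,
    render_zstack,
    save_ground_truth,
    save_tiles,
    tile_mosaic,
)

__all__ = ["scene_pars_from_config", "run_pipeline"]


def scene_pars_from_config(cfg: RunConfig) -> ScenePars:
    """Build scene parameters (including randomized dome placement)."""
    dome_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
    specs = random_dome_specs(
        cfg.scene__n_domes,
        cfg.scene__field_size_um,
        dome_rng,
        radius_range_um=(cfg.scene__dome_radius_min_um,
                         cfg.scene__dome_radius_max_um),
        apex_ratio=cfg.scene__dome_apex_ratio,
    )
    return ScenePars(
        field_size_um=cfg.scene__field_size_um,
        pixel_size_um=cfg.scene__pixel_size_um,
        z_step_um=cfg.scene__z_step_um,
        n_planes=cfg.scene__n_planes,
        n_nuclei=cfg.scene__n_nuclei,
        dome_specs=specs,
        mito_density=cfg.scene__mito_density,
        enlarged_fraction=cfg.scene__enlarged_fraction,
        n_autophagosomes=cfg.scene__n_autophagosomes,
        blur_rate_px_per_um=cfg.scene__blur_rate_px_per_um,
        noise=(cfg.scene__noise_gaussian_sd, cfg.scene__noise_poisson_scale),
        seed=cfg.seed,
    )


def run_pipeline(cfg: RunConfig, out_dir) -> MonolayerMetrics:
    """Execute all stages on one synthetic well and write all artifacts."""
    out = Path(out_dir)
    for sub in ("tiles", "composites", "labels", "metrics"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    pars = scene_pars_from_config(cfg)
    gt, surface, ideal = generate_scene(pars)
    grid = (cfg.grid__rows, cfg.grid__cols)
    stacks = {
        ch: render_zstack(ideal[ch], surface, pars, channel_label=ch)
        for ch in ("brightfield", "nuclear")
    }
    tiles_by_channel = {
        ch: tile_mosaic(stacks[ch], grid, cfg.grid__overlap_fraction)
        for ch in stacks
    }
    save_tiles(out / "tiles", tiles_by_channel, pars, grid,
               cfg.grid__overlap_fraction)
    save_ground_truth(out / "tiles", gt)

    # --- reconstruct ------------------------------------------------------
    composites = {
        ch: [
            edf_compose(t.stack, cfg.recon__focus_method,
                        cfg.recon__window_px, cfg.recon__smooth_radius_px)
            for t in tiles
        ]
        for ch, tiles in tiles_by_channel.items()
    }
    nominal = [t.nominal_offset for t in tiles_by_channel["brightfield"]]
    offsets = register_tiles(
        [c.composite for c in composites["brightfield"]],
        nominal, cfg.recon__search_radius_px,
    )
    mosaics = {
        ch: stitch(composites[ch], nominal, offsets, blend=cfg.recon__blend)
        for ch in composites
    }
    bf = mosaics["brightfield"]
    tifffile.imwrite(out / "composites" / "composite_brightfield.tif",
                     bf.composite.astype(np.float32))
    tifffile.imwrite(out / "composites" / "heightmap.tif",
                     bf.height_map.astype(np.uint16))
    tifffile.imwrite(out / "composites" / "composite_nuclear.tif",
                     mosaics["nuclear"].composite.astype(np.float32))
    offsets.to_csv(out / "composites" / "offsets.csv",
                   tiles_by_channel["brightfield"])

    # --- quantify ---------------------------------------------------------
    height_um = bf.height_map.astype(float) * pars.z_step_um
    dome_labels, total_dome_area = segment_domes(
        height_um, cfg.min_height_um, cfg.quant__min_dome_area_um2,
        pars.pixel_size_um,
    )
    tifffile.imwrite(out / "labels" / "domes.tif",
                     dome_labels.labels.astype(np.uint16))
    n_nuclei, _ = count_nuclei(
        mosaics["nuclear"].composite, pars.pixel_size_um,
        cfg.quant__nuclei_min_area_um2,
    )

    metrics = MonolayerMetrics(
        nuclei_count=n_nuclei,
        total_dome_area_um2=total_dome_area,
        dome_count=dome_labels.n_objects,
    )

    # optional organelle fields rendered at the same calibration
    if cfg.scene__mito_density > 0:
        _, table, footprint = segment_mitochondria(
            ideal["mito"], pars.pixel_size_um,
            threshold=ThresholdSpec("otsu"),
        )
        n_enl, frac, _ = classify_enlarged(
            table, cfg.quant__enlarged_threshold_um2
        )
        metrics.mito_footprint = footprint
        metrics.enlarged_mito_count = n_enl
        metrics.enlarged_mito_fraction = frac
    if cfg.scene__n_autophagosomes > 0:
        metrics.autophagosome_count = count_large_puncta(
            ideal["autophagosome"], pars.pixel_size_um,
            cfg.quant__puncta_min_area_um2, cfg.quant__puncta_quantile,
        )

    # --- provenance + metrics --------------------------------------------
    provenance = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "n_flagged_tiles": int(offsets.flagged.sum()),
        "true_total_dome_area_um2": gt.true_total_dome_area_um2,
    }
    (out / "metrics" / "provenance.json").write_text(
        json.dumps(provenance, indent=2)
    )
    metrics.to_frame().to_csv(out / "metrics" / "metrics.csv", index=False)
    return metrics
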