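"""End-to-end pipeline: simulate -> invert -> fit -> histo -> stats.

One invocation produces one run directory (never overwritten) holding every
intermediate table, the configuration, and a manifest with the config hash
and seed, so any run is reproducible from its directory alone.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import SyntheticCohortConfig, cohort_to_frame, generate_cohort
from .config import RunConfig
from .errors import PipelineStageError
from .histomorph import analyze_mask_tile, summarize_slide
from .inversion import DispersionPoint, invert_series
from .io import (
    dispersion_to_frame,
    rheology_to_frame,
    write_wave_series,
)
from .masks import generate_nucleus_mask
from .rheology import classify_solid_fluid, fit_springpot
from .response_stats import (
    auc_cutpoint,
    cohort_proportions,
    compare_groups,
    concordance,
    correlate_by_frequency,
)
from .simulate import WaveAcquisition, synthesize_wave_series

log = logging.getLogger("cylmre.pipeline")


def _fresh_run_dir(out_root: str | Path) -> Path:
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    for i in range(10000):
        d = out_root / f"run_{i:04d}"
        if not d.exists():
            d.mkdir()
            return d
    raise RuntimeError("no free run directory index")


def run_pipeline(config: RunConfig, out_root: str | Path,
                 write_hdf5: bool = False) -> Path:
    """Execute the full synthetic study and persist every stage's outputs.

    Returns the run directory.  Deterministic for a fixed config (the seed
    covers cohort generation, wave noise and mask placement).  ``write_hdf5``
    additionally stores the raw simulated wave series (large; off by
    default).
    """
    config.validate()
    run_dir = _fresh_run_dir(out_root)
    (run_dir / "config.json").write_text(config.to_json())
    rng = np.random.default_rng(config.seed)

    # --- stage 1: cohort ---------------------------------------------------
    stage = "cohort"
    try:
        log.info("stage %s", stage)
        cohort_cfg = SyntheticCohortConfig(
            frequencies=config.acquisition.frequencies, seed=config.seed)
        records = generate_cohort(cohort_cfg)
        cohort_to_frame(records).to_csv(run_dir / "cohort.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, str(e)) from e

    acq = WaveAcquisition(
        frequencies=config.acquisition.frequencies,
        n_offsets=config.acquisition.n_offsets,
        matrix=config.acquisition.matrix,
        pixel_size=config.acquisition.pixel_size_m,
        tube_inner_diameter=config.acquisition.tube_inner_diameter_m,
        density=config.acquisition.density_kg_m3,
    )

    # --- stage 2: wave simulation + inversion + rheology --------------------
    stage = "inversion"
    try:
        n_wave = config.n_wave_samples
        subset = records if n_wave is None else records[:n_wave]
        points_by_sample: dict[str, list[DispersionPoint]] = {}
        fits = {}
        for rec in subset:
            log.info("stage %s: sample %s", stage, rec.sample_id)
            series = synthesize_wave_series(
                rec.springpot, acq,
                amplitude=config.acquisition.amplitude_m,
                noise_sd=config.acquisition.noise_sd_rad,
                seed=rng,
                encoding_gain=config.acquisition.encoding_gain_rad_per_m,
            )
            if write_hdf5:
                write_wave_series(run_dir / f"waves_{rec.sample_id}.h5", series)
            points = invert_series(
                series,
                c_range=config.inversion.c_range_mps,
                a_range=config.inversion.a_range_mps,
                n_grid=config.inversion.n_grid,
                bin_width=config.inversion.bin_width_m,
                weight_by_npx=config.inversion.weight_by_npx,
            )
            points_by_sample[rec.sample_id] = points
            fit = fit_springpot(points, density=acq.density,
                                bounds=(config.rheology.mu_bounds_pa,
                                        config.rheology.alpha_bounds))
            fits[rec.sample_id] = fit
        dispersion_to_frame(points_by_sample).to_csv(
            run_dir / "dispersion.csv", index=False)
        rdf = rheology_to_frame(fits)
        rdf["label"] = [classify_solid_fluid(fits[s]) for s in rdf["sample_id"]]
        rdf["mu_true_pa"] = [r.springpot.mu for r in subset]
        rdf["alpha_true"] = [r.springpot.alpha for r in subset]
        rdf.to_csv(run_dir / "rheology.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, str(e)) from e

    # --- stage 3: histology --------------------------------------------------
    stage = "histology"
    try:
        log.info("stage %s", stage)
        histo_rows = []
        for group, gp in cohort_cfg.group_params.items():
            tiles = []
            for t in range(config.histology.n_tiles_per_group):
                mask = generate_nucleus_mask(
                    density_target=gp["density"].median,
                    mean_area=gp["area"].median,
                    aspect_ratio=gp["aspect"].median,
                    tile_px=config.histology.tile_px,
                    pixel_size=config.histology.pixel_size_um,
                    seed=rng,
                )
                tiles.append(analyze_mask_tile(mask.labels,
                                               pixel_size=mask.pixel_size))
            summ = summarize_slide(tiles)
            histo_rows.append({"group": group, **asdict(summ)})
        pd.DataFrame(histo_rows).to_csv(run_dir / "morphometry.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, str(e)) from e

    # --- stage 4: statistics --------------------------------------------------
    stage = "stats"
    try:
        log.info("stage %s", stage)
        stats: dict = {}
        stats["proportions"] = {
            cls: {"n": n, "pct": pct}
            for cls, (n, pct) in cohort_proportions(
                [r.histo_response for r in records]).items()
        }
        table = concordance([r.histo_response for r in records],
                            [r.recist for r in records])
        stats["concordance"] = {
            "counts": {"both_absent": table.both_absent,
                       "patho_only": table.patho_only,
                       "radio_only": table.radio_only,
                       "both_present": table.both_present},
            "n": table.n,
            "percentages": table.percentages(),
        }
        for value in ("c", "a"):
            for classifier in ("grade", "response"):
                res = correlate_by_frequency(records, value=value,
                                             classifier=classifier)
                stats[f"spearman_{value}_{classifier}"] = [
                    {"f_hz": r.f, "rho": _nan_to_none(r.coefficient),
                     "p": _nan_to_none(r.p_value), "n": r.n} for r in res
                ]
        alpha_by_group = {
            g: [r.springpot.alpha for r in records if r.histo_response == g]
            for g in ("major", "partial", "none")
        }
        cmp_res = compare_groups(alpha_by_group, fdr=config.stats.fdr)
        stats["alpha_groups"] = {
            "kruskal_p": cmp_res.kruskal_p,
            "groups": {g: asdict(s) for g, s in cmp_res.groups.items()},
            "pairwise": {f"{a}|{b}": p for (a, b), p in cmp_res.pairwise.items()},
        }
        area_auc = auc_cutpoint([r.area_um2 for r in records],
                                [r.histo_response == "major" for r in records])
        stats["auc_nucleus_area_major"] = asdict(area_auc)
        (run_dir / "stats.json").write_text(json.dumps(stats, indent=2))
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, str(e)) from e

    manifest = {
        "cylmre_version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "outputs": sorted(p.name for p in run_dir.iterdir()),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


def _nan_to_none(x: float):
    return None if (x is None or not math.isfinite(x)) else x
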