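"""File formats: HDF5 wave series, CSV tables, TIFF masks.

HDF5 layout for a phase-image series::

    /freq_<Hz>/phase      float64 [offset, y, x], wrapped radians
    /freq_<Hz>           attrs: frequency_hz, overshoot
    /                    attrs: n_offsets, matrix, pixel_size_m,
                          tube_inner_diameter_m, density_kg_m3,
                          encoding_gain_rad_per_m, frequencies_hz
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .inversion import DispersionPoint
from .rheology import SpringpotFit
from .simulate import PhaseImageSeries, WaveAcquisition

DISPERSION_COLUMNS = ["sample_id", "f_hz", "k_re", "k_im", "c_mps", "a_mps",
                      "valid", "reason"]
RHEOLOGY_COLUMNS = ["sample_id", "mu_pa", "alpha", "rss", "n_freq_used",
                    "converged"]


def write_wave_series(path: str | Path, series: PhaseImageSeries) -> None:
    acq = series.acquisition
    with h5py.File(path, "w") as h5:
        h5.attrs["n_offsets"] = acq.n_offsets
        h5.attrs["matrix"] = acq.matrix
        h5.attrs["pixel_size_m"] = acq.pixel_size
        h5.attrs["tube_inner_diameter_m"] = acq.tube_inner_diameter
        h5.attrs["density_kg_m3"] = acq.density
        h5.attrs["encoding_gain_rad_per_m"] = series.encoding_gain
        h5.attrs["frequencies_hz"] = np.array(acq.frequencies)
        for f in series.frequencies():
            grp = h5.create_group(f"freq_{int(f)}")
            grp.attrs["frequency_hz"] = f
            grp.attrs["overshoot"] = bool(series.overshoot.get(f, False))
            grp.create_dataset("phase", data=series.phase[f])


def read_wave_series(path: str | Path) -> PhaseImageSeries:
    with h5py.File(path, "r") as h5:
        acq = WaveAcquisition(
            frequencies=tuple(float(f) for f in h5.attrs["frequencies_hz"]),
            n_offsets=int(h5.attrs["n_offsets"]),
            matrix=int(h5.attrs["matrix"]),
            pixel_size=float(h5.attrs["pixel_size_m"]),
            tube_inner_diameter=float(h5.attrs["tube_inner_diameter_m"]),
            density=float(h5.attrs["density_kg_m3"]),
        )
        gain = float(h5.attrs["encoding_gain_rad_per_m"])
        phase = {}
        overshoot = {}
        for name, grp in h5.items():
            if not name.startswith("freq_"):
                continue
            f = float(grp.attrs["frequency_hz"])
            phase[f] = np.asarray(grp["phase"])
            overshoot[f] = bool(grp.attrs["overshoot"])
    return PhaseImageSeries(acquisition=acq, phase=phase, encoding_gain=gain,
                            overshoot=overshoot)


def dispersion_to_frame(points_by_sample: dict[str, Sequence[DispersionPoint]]) -> pd.DataFrame:
    rows = []
    for sid, points in points_by_sample.items():
        for p in points:
            rows.append({"sample_id": sid, "f_hz": p.f, "k_re": p.k_re,
                         "k_im": p.k_im, "c_mps": p.c, "a_mps": p.a,
                         "valid": p.valid, "reason": p.reason})
    return pd.DataFrame(rows, columns=DISPERSION_COLUMNS)


def frame_to_dispersion(df: pd.DataFrame) -> dict[str, list[DispersionPoint]]:
    out: dict[str, list[DispersionPoint]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample_id"]), []).append(DispersionPoint(
            f=float(row["f_hz"]), k_re=float(row["k_re"]),
            k_im=float(row["k_im"]), c=float(row["c_mps"]),
            a=float(row["a_mps"]), valid=bool(row["valid"]),
            reason=str(row["reason"])))
    return out


def rheology_to_frame(fits_by_sample: dict[str, SpringpotFit]) -> pd.DataFrame:
    rows = [{"sample_id": sid, "mu_pa": fit.mu, "alpha": fit.alpha,
             "rss": fit.rss, "n_freq_used": fit.n_freq_used,
             "converged": fit.converged}
            for sid, fit in fits_by_sample.items()]
    return pd.DataFrame(rows, columns=RHEOLOGY_COLUMNS)


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    """16-bit single-channel TIFF label mask."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit a 16-bit mask")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_rgb_image(path: str | Path, rgb: np.ndarray) -> None:
    tifffile.imwrite(path, rgb)
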