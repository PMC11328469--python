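"""Synthetic H&E-like nucleus label masks and stain renderings.

Nuclei are modelled as non-overlapping ellipses of a prescribed area and
aspect ratio, placed uniformly at random (random sequential adsorption) in a
square tile.  The label mask carries one positive integer per nucleus; the
RGB rendering composes the mask into a hematoxylin/eosin stain image through
the standard optical-density colour model, so the downstream colour
deconvolution recovers the nuclei from the hematoxylin channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.color import hed2rgb
from skimage.draw import ellipse as _draw_ellipse

from .errors import InvalidInputError, PlacementError

#: Default pixel size of histology tiles, micrometres per pixel, from the
#: tile geometry 1105 um over 5000 px.
HISTO_PIXEL_SIZE = 1105.0 / 5000.0

#: Hematoxylin optical density assigned to nucleus pixels in renderings.
_H_NUCLEUS = 0.65
#: Eosin optical density of the background tissue (pale pink).
_E_TISSUE = 0.10


@dataclass(frozen=True)
class NucleusMaskResult:
    """Label mask plus ground-truth placement bookkeeping."""

    labels: np.ndarray          # int32 label image, 0 = background
    n_placed: int
    pixel_size: float           # um/px
    mean_area_target: float     # um^2

    @property
    def tile_area_um2(self) -> float:
        return self.labels.size * self.pixel_size**2


def generate_nucleus_mask(
    density_target: float,
    mean_area: float,
    aspect_ratio: float,
    tile_px: int,
    pixel_size: float = HISTO_PIXEL_SIZE,
    seed: int | np.random.Generator | None = 0,
    max_tries_per_nucleus: int = 200,
) -> NucleusMaskResult:
    """Place non-overlapping ellipses to a target count density.

    Parameters
    ----------
    density_target : float
        Nuclei per um^2 of tile.  The implied area fraction
        ``density_target * mean_area`` must stay below 0.5 (hard packing
        bound for sequential random placement).
    mean_area : float
        Area of each nucleus, um^2 (constant across nuclei; the spread of
        *measured* areas then reflects rasterization only).
    aspect_ratio : float
        Major/minor axis ratio, >= 1.
    tile_px : int
        Tile edge length in pixels.
    """
    if tile_px <= 0:
        raise InvalidInputError("tile_px must be > 0")
    if density_target < 0 or mean_area <= 0 or aspect_ratio < 1:
        raise InvalidInputError("invalid density/area/aspect parameters")
    frac = density_target * mean_area
    if frac >= 0.5:
        raise InvalidInputError(
            f"requested area fraction {frac:.2f} exceeds the 0.5 packing bound")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    labels = np.zeros((tile_px, tile_px), dtype=np.int32)
    tile_area = tile_px**2 * pixel_size**2
    n_target = int(round(density_target * tile_area))
    if n_target == 0:
        return NucleusMaskResult(labels=labels, n_placed=0,
                                 pixel_size=pixel_size, mean_area_target=mean_area)

    # Semi-axes in pixels: area = pi * a_maj * a_min, a_maj = AR * a_min.
    a_min_px = math.sqrt(mean_area / (math.pi * aspect_ratio)) / pixel_size
    a_maj_px = aspect_ratio * a_min_px
    margin = a_maj_px + 1.0

    placed = 0
    for lab in range(1, n_target + 1):
        ok = False
        for _ in range(max_tries_per_nucleus):
            cy = rng.uniform(margin, tile_px - margin)
            cx = rng.uniform(margin, tile_px - margin)
            theta = rng.uniform(0.0, math.pi)
            rr, cc = _draw_ellipse(cy, cx, a_maj_px, a_min_px,
                                   rotation=theta, shape=labels.shape)
            if rr.size == 0:
                continue
            if np.any(labels[rr, cc] != 0):
                continue
            # one-pixel clearance so touching nuclei stay separable
            if _touches_neighbour(labels, rr, cc):
                continue
            labels[rr, cc] = lab
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place nucleus {lab}/{n_target} after "
                f"{max_tries_per_nucleus} tries (area fraction {frac:.2f})")
        placed += 1
    return NucleusMaskResult(labels=labels, n_placed=placed,
                             pixel_size=pixel_size, mean_area_target=mean_area)


def _touches_neighbour(labels: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> bool:
    """True if any 4-neighbour of the candidate pixels is already occupied."""
    n = labels.shape[0]
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        r2 = np.clip(rr + dy, 0, n - 1)
        c2 = np.clip(cc + dx, 0, n - 1)
        if np.any(labels[r2, c2] != 0):
            return True
    return False


def render_he_image(labels: np.ndarray,
                    seed: int | np.random.Generator | None = 0,
                    stain_noise: float = 0.02) -> np.ndarray:
    """Render a label mask as an H&E-like RGB uint8 image.

    Nuclei receive hematoxylin optical density (blue-purple), the rest of the
    tile a light eosin density (pale pink tissue), plus small multiplicative
    stain noise; composition to RGB uses the standard HED stain matrix.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nuc = labels > 0
    hed = np.zeros(labels.shape + (3,), dtype=float)
    hed[..., 0] = np.where(nuc, _H_NUCLEUS, 0.0)
    hed[..., 1] = _E_TISSUE
    if stain_noise > 0:
        hed *= 1.0 + rng.normal(0.0, stain_noise, size=hed.shape)
        hed = np.clip(hed, 0.0, None)
    rgb = hed2rgb(hed)
    return (np.clip(rgb, 0.0, 1.0) * 255).astype(np.uint8)
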