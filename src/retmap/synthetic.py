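"""Parametric ground-truth phase maps for testing the analysis chain.

Generates collicular phase-map rasters with known structure — a single
ordered projection, a partial double map with a prescribed visual field
duplication, or a fully double map — plus an ambiguous band between the two
projection areas whose pixels flip at random between the two competing field
positions (the unstable averaging behaviour the reliability filter targets),
and additive Gaussian phase noise.  Every pixel comes with ground-truth
labels, so filtering, lattice construction and the map metrics can be
validated against known answers without running the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .imaging import ImagingParams, PhaseMap, fluctuation_stat
from .substrate import HEMI_ELLIPSE

__all__ = ["SyntheticLabels", "generate_phase_map"]

OUTSIDE, ROSTRAL, CAUDAL, BAND = 0, 1, 2, 3


@dataclass
class SyntheticLabels:
    """Ground truth per pixel: region code and true field position."""

    region: np.ndarray        # 0 outside, 1 rostral, 2 caudal, 3 ambiguous band
    true_azimuth: np.ndarray  # deg (NaN in band/outside)
    true_elevation: np.ndarray


def generate_phase_map(
    kind: str = "single",
    vfd_target: float = 0.0,
    noise_sd: float = 2.0,
    ambiguous_band_width: int = 4,
    seed: int = 0,
    ip: Optional[ImagingParams] = None,
    split: float = 0.55,
) -> tuple[PhaseMap, SyntheticLabels]:
    """Build a synthetic PhaseMap with known single/double structure.

    ``kind``: ``single`` (one ordered projection covering the colliculus),
    ``partial_double`` (rostral area maps the whole field, caudal area maps
    the fraction ``vfd_target`` of it) or ``full_double`` (both areas map the
    entire field).  ``noise_sd`` is Gaussian phase noise in degrees;
    ``ambiguous_band_width`` (pixels) is the strip between the two areas
    whose pixels flip between the competing field positions; ``split`` is
    the rostrocaudal position of the band centre (fraction of the raster).
    """
    ip = ip or ImagingParams()
    if kind == "single":
        if vfd_target not in (0, 0.0):
            raise ValueError("kind='single' requires vfd_target=0")
        frac = 0.0
    elif kind == "full_double":
        frac = 1.0
        if vfd_target not in (0.0, 1.0):
            raise ValueError("kind='full_double' fixes vfd_target=1")
    elif kind == "partial_double":
        if not 0.0 < vfd_target <= 1.0:
            raise ValueError("kind='partial_double' requires vfd_target in (0, 1]")
        frac = float(vfd_target)
    else:
        raise ValueError(f"unknown kind {kind!r}")

    rng = np.random.default_rng(seed)
    h, w = ip.pixel_grid
    # normalized pixel-centre coordinates over the collicular bounding box
    xs = (np.arange(w) + 0.5) / w
    ys = (np.arange(h) + 0.5) / h * 0.6
    X, Y = np.meshgrid(xs, ys)
    inside = HEMI_ELLIPSE.contains(np.column_stack([X.ravel(), Y.ravel()])).reshape(h, w)

    az = np.full((h, w), np.nan)
    el = np.full((h, w), np.nan)
    region = np.full((h, w), OUTSIDE, dtype=np.uint8)
    span = ip.azimuth_span_deg
    bw = ambiguous_band_width / w  # band width, normalized
    if kind == "single":
        x_r0, x_r1 = 0.0, 1.0
        region[inside] = ROSTRAL
        az[inside] = span * (1.0 - X[inside])  # temporal retina rostrally
    else:
        x_r1 = split - bw / 2.0
        x_c0 = split + bw / 2.0
        ros = inside & (X < x_r1)
        cau = inside & (X > x_c0)
        band = inside & ~ros & ~cau
        region[ros] = ROSTRAL
        region[cau] = CAUDAL
        region[band] = BAND
        # rostral area maps the full field, caudal area the nasal-retina
        # fraction `frac` (the temporal-field part of a double map)
        az[ros] = span * (1.0 - X[ros] / x_r1)
        az[cau] = span * frac * (1.0 - (X[cau] - x_c0) / (1.0 - x_c0))
        # band: the unstable average flips between the two competing
        # positions (end of the rostral ramp vs start of the caudal ramp)
        flip = rng.random((h, w)) < 0.5
        az[band] = np.where(flip[band], 0.0, span * frac)
    # elevation is normalized by the local height of the hemi-ellipse: every
    # rostrocaudal level represents the full dorsoventral extent of the field,
    # so iso-elevation lines follow the curved outline (as in real maps)
    ymax = 0.6 * np.sqrt(np.clip(1.0 - ((X - 0.5) / 0.5) ** 2, 1e-9, None))
    el[inside] = ip.elevation_span_deg * (Y[inside] / ymax[inside])

    true_az = az.copy()
    true_el = el.copy()
    true_az[region == BAND] = np.nan

    az = az + rng.normal(0.0, noise_sd, az.shape)
    el = el + rng.normal(0.0, noise_sd, el.shape)
    az[~inside] = np.nan
    el[~inside] = np.nan

    amp = np.where(inside, 1.0 + 0.1 * rng.standard_normal((h, w)), 0.0)
    amp = np.clip(amp, 0.0, None)
    fluct = fluctuation_stat(az, el)
    pmap = PhaseMap(
        azimuth=az, elevation=el, amplitude=amp, fluctuation=fluct,
        pixel_size_um=ip.pixel_size_um,
        azimuth_span_deg=ip.azimuth_span_deg,
        elevation_span_deg=ip.elevation_span_deg,
        meta={"kind": kind, "vfd_target": frac, "noise_sd": noise_sd,
              "ambiguous_band_width": ambiguous_band_width, "seed": seed,
              "split": split},
    )
    return pmap, SyntheticLabels(region, true_az, true_el)
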