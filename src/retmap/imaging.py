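"""Emulation of Fourier-based intrinsic imaging of a simulated projection.

A thin bar is swept periodically across the retina in one of two orthogonal
directions (azimuth = nasotemporal, elevation = dorsoventral).  Retinal cells
fire Poisson spikes at a raised rate while under the bar; collicular drive is
the contact-weighted sum of retinal spikes passed through a
difference-of-Gaussians centre-surround kernel (local excitation and
inhibition); responses are accumulated on a pixel raster.  The Fourier
coefficient of each pixel's time course at the sweep repetition frequency
yields the preferred field position (phase) and response strength
(amplitude), exactly as in the experimental method.

The bar sweeps during the first ``duty`` fraction of each cycle and is off
screen for the remainder, so that phase maps one-to-one onto field position
(no wrap-around ambiguity between the two ends of the field).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse import csr_matrix

from .substrate import CellSheet
from .tk import ContactSet

__all__ = [
    "ImagingParams",
    "PhaseMap",
    "simulate_scan",
    "extract_phase",
    "image_projection",
    "fluctuation_stat",
]


@dataclass
class ImagingParams:
    """Scan geometry, spiking rates and collicular interaction scales."""

    bar_width: float = 0.02          # fraction of the retinal linear extent
    n_cycles: int = 5                # sweep repetitions
    frames_per_cycle: int = 72
    duty: float = 0.8                # fraction of the cycle the bar is on screen
    base_rate: float = 0.2           # Poisson spikes/frame off the bar
    drive_rate: float = 30.0         # Poisson spikes/frame under the bar
    excitation_length: float = 0.05  # collicular excitation scale (normalized)
    inhibition_length: float = 0.15  # collicular inhibition scale
    inhibition_gain: float = 3.0  # relative to the time-mean surround drive
    pixel_grid: tuple[int, int] = (60, 100)   # (rows, cols) over the bounding box
    pixel_size_um: float = 80.0 / 6.0         # 6 pixel-widths = 80 um
    azimuth_span_deg: float = 100.0
    elevation_span_deg: float = 80.0

    def __post_init__(self) -> None:
        if not 0.0 < self.bar_width < 1.0:
            raise ValueError("bar_width must lie in (0, 1)")
        if self.n_cycles < 2:
            raise ValueError("need at least two scan cycles")

    @property
    def n_frames(self) -> int:
        return self.n_cycles * self.frames_per_cycle

    def span(self, direction: str) -> float:
        return self.azimuth_span_deg if direction == "azimuth" else self.elevation_span_deg


@dataclass
class PhaseMap:
    """Per-pixel field position, response amplitude and fluctuation statistic.

    ``azimuth``/``elevation`` are in degrees of visual field; ``amplitude`` is
    the modulus of the elevational-scan Fourier coefficient (arbitrary units);
    ``fluctuation`` is the pooled standard deviation of reported field
    position over the 3x3 pixel neighbourhood (degrees), the statistic the
    reliability filter thresholds.  Pixels with no response carry NaN phases.
    Raster convention: 0-based row-major; pixel centres at half-integer pixel
    coordinates; row 0 is the lateral edge, column 0 the rostral edge.
    """

    azimuth: np.ndarray
    elevation: np.ndarray
    amplitude: np.ndarray
    fluctuation: np.ndarray
    pixel_size_um: float
    azimuth_span_deg: float = 100.0
    elevation_span_deg: float = 80.0
    amp_azimuth: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.azimuth.shape

    def pixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of pixel centres, in micrometres."""
        h, w = self.shape
        xs = (np.arange(w) + 0.5) * self.pixel_size_um
        ys = (np.arange(h) + 0.5) * self.pixel_size_um
        return np.meshgrid(xs, ys)

    _CHANNELS = ("azimuth", "elevation", "amplitude", "fluctuation")

    def save(self, prefix: str | Path) -> None:
        """Write four delimited-text grids and a JSON metadata sidecar."""
        prefix = Path(prefix)
        for name in self._CHANNELS:
            np.savetxt(f"{prefix}_{name}.txt", getattr(self, name), fmt="%.6g")
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "azimuth_span_deg": self.azimuth_span_deg,
            "elevation_span_deg": self.elevation_span_deg,
            "shape": list(self.shape),
            **self.meta,
        }
        Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1, default=float))

    @classmethod
    def load(cls, prefix: str | Path) -> "PhaseMap":
        prefix = Path(prefix)
        meta = json.loads(Path(f"{prefix}_meta.json").read_text())
        chans = {n: np.loadtxt(f"{prefix}_{n}.txt", ndmin=2) for n in cls._CHANNELS}
        return cls(
            pixel_size_um=meta.pop("pixel_size_um"),
            azimuth_span_deg=meta.pop("azimuth_span_deg"),
            elevation_span_deg=meta.pop("elevation_span_deg"),
            meta={k: v for k, v in meta.items() if k != "shape"},
            **chans,
        )

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        stack = np.stack([np.asarray(getattr(self, n), dtype=np.float32)
                          for n in self._CHANNELS])
        tifffile.imwrite(
            str(path), stack,
            metadata={"axes": "CYX", "channels": list(self._CHANNELS),
                      "pixel_size_um": self.pixel_size_um,
                      "azimuth_span_deg": self.azimuth_span_deg,
                      "elevation_span_deg": self.elevation_span_deg},
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "PhaseMap":
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            stack = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        chans = dict(zip(meta.get("channels", cls._CHANNELS), np.asarray(stack, dtype=float)))
        return cls(
            pixel_size_um=float(meta.get("pixel_size_um", 80.0 / 6.0)),
            azimuth_span_deg=float(meta.get("azimuth_span_deg", 100.0)),
            elevation_span_deg=float(meta.get("elevation_span_deg", 80.0)),
            **{n: chans[n] for n in cls._CHANNELS},
        )


def _pixel_index(colliculus: CellSheet, grid: tuple[int, int]) -> np.ndarray:
    h, w = grid
    x0, x1, y0, y1 = colliculus.region.bbox
    ix = np.clip(((colliculus.x - x0) / (x1 - x0) * w).astype(int), 0, w - 1)
    iy = np.clip(((colliculus.y - y0) / (y1 - y0) * h).astype(int), 0, h - 1)
    return iy * w + ix


def simulate_scan(
    contacts: ContactSet,
    retina: CellSheet,
    colliculus: CellSheet,
    ip: Optional[ImagingParams] = None,
    direction: str = "azimuth",
    seed: int = 0,
    subpopulation: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-pixel response time series (n_frames, rows, cols) for one scan.

    ``subpopulation`` (boolean mask over retinal cells) restricts the scan to
    that population: cells outside it stay silent.
    """
    ip = ip or ImagingParams()
    h, w = ip.pixel_grid
    if contacts.n_contacts == 0:
        warnings.warn("imaging an empty contact set: all-zero series", stacklevel=2)
        return np.zeros((ip.n_frames, h, w))
    rng = np.random.default_rng(seed)
    coord = retina.x if direction == "azimuth" else retina.y

    t = np.arange(ip.n_frames)
    bar_pos = (t % ip.frames_per_cycle) / ip.frames_per_cycle / ip.duty  # in [0, 1/duty)
    under = np.abs(coord[None, :] - bar_pos[:, None]) < ip.bar_width / 2.0
    rates = np.where(under, ip.drive_rate, ip.base_rate)
    if subpopulation is not None:
        rates = rates * np.asarray(subpopulation, dtype=bool)[None, :]
    spikes = rng.poisson(rates).astype(np.float64)

    rr, cc, k = contacts.aggregated()
    W = csr_matrix((k.astype(np.float64), (rr, cc)), shape=(retina.n, colliculus.n))
    drive = spikes @ W  # (frames, n_coll)

    pix = _pixel_index(colliculus, ip.pixel_grid)
    P = csr_matrix((np.ones(colliculus.n), (np.arange(colliculus.n), pix)),
                   shape=(colliculus.n, h * w))
    series = np.asarray(drive @ P).reshape(ip.n_frames, h, w)

    # centre-surround interaction: difference of Gaussians on the raster.
    # The surround is temporally integrating (inhibition tracks the scan-mean
    # local drive rather than the instantaneous frame), so it suppresses
    # weakly driven territory without mixing phase information from
    # neighbouring field positions into the response; negative drive is
    # rectified away.
    px_norm = 1.0 / w  # raster spans x in [0, 1]
    s_e = ip.excitation_length / px_norm
    s_i = ip.inhibition_length / px_norm
    exc = gaussian_filter(series, sigma=(0, s_e, s_e))
    inh = gaussian_filter(series.mean(axis=0), sigma=(s_i, s_i))
    return np.clip(exc - ip.inhibition_gain * inh, 0.0, None)


def extract_phase(
    series: np.ndarray,
    ip: Optional[ImagingParams] = None,
    direction: str = "azimuth",
) -> tuple[np.ndarray, np.ndarray]:
    """Field position (degrees) and amplitude from one scan's time series.

    Computes the complex Fourier coefficient of each pixel's time course at
    the sweep repetition frequency; the phase maps linearly onto field
    position, the modulus is the response amplitude.  Pixels with zero
    amplitude get NaN position.
    """
    ip = ip or ImagingParams()
    nt = len(series)
    if nt < 2 * ip.frames_per_cycle:
        raise ValueError("need at least two full cycles of data")
    t = np.arange(nt)
    phasor = np.exp(-2j * np.pi * ip.n_cycles * t / nt)
    coeff = np.tensordot(phasor, series - series.mean(axis=0), axes=(0, 0)) * (2.0 / nt)
    amp = np.abs(coeff)
    cyc_phase = np.mod(-np.angle(coeff) / (2 * np.pi), 1.0)
    pos = cyc_phase / ip.duty  # undo the off-screen part of the cycle
    pos_deg = pos * ip.span(direction)
    pos_deg[amp <= 0] = np.nan
    return pos_deg, amp


def fluctuation_stat(azimuth: np.ndarray, elevation: np.ndarray,
                     size: int = 3) -> np.ndarray:
    """Pooled neighbourhood standard deviation of reported field position.

    For each pixel, the standard deviation of the 2D field position (azimuth
    and elevation channels pooled as a vector: sqrt(var_az + var_el)) over
    the ``size`` x ``size`` neighbourhood, ignoring NaN pixels.  High values
    mark pixels whose reported position fluctuates from pixel to pixel —
    the signature of two field regions mapping to the same collicular area.
    """
    r = size // 2
    shifts = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = np.full(azimuth.shape + (2,), np.nan)
            src_y = slice(max(0, -dy), azimuth.shape[0] - max(0, dy))
            dst_y = slice(max(0, dy), azimuth.shape[0] - max(0, -dy))
            src_x = slice(max(0, -dx), azimuth.shape[1] - max(0, dx))
            dst_x = slice(max(0, dx), azimuth.shape[1] - max(0, -dx))
            shifted[dst_y, dst_x, 0] = azimuth[src_y, src_x]
            shifted[dst_y, dst_x, 1] = elevation[src_y, src_x]
            shifts.append(shifted)
    stack = np.stack(shifts)  # (size^2, H, W, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(stack, axis=0)  # (H, W, 2)
        out = np.sqrt(var[..., 0] + var[..., 1])
    n_valid = np.sum(np.isfinite(stack[..., 0]), axis=0)
    out[n_valid < 3] = np.nan
    return out


def image_projection(
    contacts: ContactSet,
    retina: CellSheet,
    colliculus: CellSheet,
    ip: Optional[ImagingParams] = None,
    seed: int = 0,
    subpopulation: Optional[str | np.ndarray] = None,
) -> PhaseMap:
    """Run both scan directions and assemble a full PhaseMap.

    ``subpopulation`` may be a boolean mask, ``"knockin"`` or ``"wildtype"``
    to restrict the scan to the EphA3+ or EphA3- retinal population.
    """
    ip = ip or ImagingParams()
    if isinstance(subpopulation, str):
        if retina.is_knockin is None:
            raise ValueError("retina has no knock-in assignment")
        subpopulation = retina.is_knockin if subpopulation == "knockin" else ~retina.is_knockin
    s_az, s_el = np.random.SeedSequence(seed).generate_state(2) & 0x7FFFFFFF
    series_az = simulate_scan(contacts, retina, colliculus, ip, "azimuth", int(s_az), subpopulation)
    series_el = simulate_scan(contacts, retina, colliculus, ip, "elevation", int(s_el), subpopulation)
    az, amp_az = extract_phase(series_az, ip, "azimuth")
    el, amp_el = extract_phase(series_el, ip, "elevation")
    fluct = fluctuation_stat(az, el)
    return PhaseMap(
        azimuth=az, elevation=el, amplitude=amp_el, fluctuation=fluct,
        amp_azimuth=amp_az, pixel_size_um=ip.pixel_size_um,
        azimuth_span_deg=ip.azimuth_span_deg, elevation_span_deg=ip.elevation_span_deg,
        meta={"seed": seed},
    )
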