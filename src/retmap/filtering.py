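"""Pixel filtering of raw phase maps.

Three stages reduce a raster to the eligible pixels used for map
construction: (1) keep the most active pixels (by elevational-scan
amplitude); (2) fit an ellipse to the region of strongest elevational
excitation and reject pixels outside it; (3) reject pixels whose reported
field position fluctuates from pixel to pixel by more than ``factor`` times
the wild-type baseline — the signature of two separate field regions driving
the same collicular territory, for which the single reported position is an
unreliable average.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .imaging import PhaseMap, fluctuation_stat

__all__ = [
    "PixelMask",
    "select_top_active",
    "fit_response_ellipse",
    "reject_fluctuating",
    "wt_baseline",
    "filter_phase_map",
    "apply_mask",
]

INACTIVE, ELIGIBLE, REJECTED = 0, 1, 2
FAILED_ACTIVITY, FAILED_ELLIPSE, FAILED_FLUCTUATION = 1, 2, 4


@dataclass
class PixelMask:
    """Per-pixel filter state with provenance flags.

    ``state``: 0 = inactive (never passed the activity cut), 1 = eligible,
    2 = rejected; ``flags`` is a bitmask recording which stage removed the
    pixel (1 activity, 2 ellipse, 4 fluctuation).
    """

    state: np.ndarray
    flags: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def eligible(self) -> np.ndarray:
        return self.state == ELIGIBLE

    @property
    def rejected(self) -> np.ndarray:
        return self.state == REJECTED

    @property
    def active(self) -> np.ndarray:
        return self.state != INACTIVE

    @property
    def shape(self) -> tuple[int, int]:
        return self.state.shape

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".csv"), self.state, fmt="%d", delimiter=",")
        np.savetxt(f"{prefix}_flags.csv", self.flags, fmt="%d", delimiter=",")
        prefix.with_suffix(".json").write_text(json.dumps(self.meta, indent=1, default=float))

    @classmethod
    def load(cls, prefix: str | Path) -> "PixelMask":
        prefix = Path(prefix)
        state = np.loadtxt(prefix.with_suffix(".csv"), dtype=int, delimiter=",", ndmin=2)
        flags = np.loadtxt(f"{prefix}_flags.csv", dtype=int, delimiter=",", ndmin=2)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(state, flags, meta)


def select_top_active(pm: PhaseMap, k: int = 10_000) -> PixelMask:
    """Keep the ``min(k, #nonzero)`` most active pixels (elevational amplitude).

    Ties are broken by raster (row-major) order: among equal amplitudes the
    earlier pixel wins.
    """
    amp = np.nan_to_num(np.asarray(pm.amplitude, dtype=float), nan=0.0)
    flat = amp.ravel()
    nonzero = flat > 0
    k_eff = min(int(k), int(np.count_nonzero(nonzero)))
    state = np.full(flat.shape, INACTIVE, dtype=np.uint8)
    flags = np.full(flat.shape, FAILED_ACTIVITY, dtype=np.uint8)
    if k_eff > 0:
        order = np.argsort(-flat, kind="stable")  # stable: ties in raster order
        keep = order[:k_eff]
        state[keep] = ELIGIBLE
        flags[keep] = 0
    return PixelMask(state.reshape(amp.shape), flags.reshape(amp.shape),
                     meta={"k": int(k), "n_active": k_eff})


def fit_response_ellipse(pm: PhaseMap, mask: PixelMask, quantile: float = 0.975) -> PixelMask:
    """Restrict to an ellipse enclosing the region of strongest elevational excitation.

    The ellipse is an amplitude-weighted second-moment fit over the active
    pixels, scaled so that the given quantile of active elevational amplitude
    falls inside; active pixels outside are marked rejected.  A degenerate
    (collinear or single-pixel) active set falls back to the bounding box
    with a warning.
    """
    act = mask.active & ~mask.rejected
    if not act.any():
        raise ValueError("no active pixels to fit an ellipse to")
    ys, xs = np.nonzero(act)
    prior = pm.meta.get("ellipse")
    if isinstance(prior, dict):
        # the map carries an ROI from an earlier filtering pass: apply it
        # rather than refitting to the already-truncated data (iterative
        # refitting would shrink the ROI indefinitely)
        ctr = np.asarray(prior["center"], dtype=float)
        cinv = np.linalg.inv(np.asarray(prior["cov"], dtype=float))
        d = np.column_stack([xs, ys]).astype(float) - ctr
        m2 = np.einsum("ij,jk,ik->i", d, cinv, d)
        outside = m2 > prior["scale2"] * 1.3
        state = mask.state.copy()
        flags = mask.flags.copy()
        state[ys[outside], xs[outside]] = REJECTED
        flags[ys[outside], xs[outside]] |= FAILED_ELLIPSE
        return PixelMask(state, flags, {**mask.meta, "ellipse": prior})
    wgt = np.nan_to_num(np.asarray(pm.amplitude, dtype=float)[ys, xs], nan=0.0)
    if wgt.sum() <= 0:
        wgt = np.ones_like(wgt)
    else:
        # cap weights at the median amplitude: response strength varies
        # considerably across the colliculus, and uncapped weighting drags
        # the fit toward the strongest corner instead of the responsive region
        wgt = np.minimum(wgt, np.median(wgt[wgt > 0]))
    pts = np.column_stack([xs, ys]).astype(float)
    ctr = np.average(pts, axis=0, weights=wgt)
    d = pts - ctr
    cov = (d * wgt[:, None]).T @ d / wgt.sum()
    state = mask.state.copy()
    flags = mask.flags.copy()
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 1e-9:  # collinear / single pixel: bounding-box fallback
        warnings.warn("degenerate active set; falling back to bounding box", stacklevel=2)
        meta = {**mask.meta, "ellipse": "bbox-fallback"}
        return PixelMask(state, flags, meta)
    cinv = np.linalg.inv(cov)
    m2 = np.einsum("ij,jk,ik->i", d, cinv, d)
    # weighted quantile of squared Mahalanobis radius
    order = np.argsort(m2)
    cw = np.cumsum(wgt[order])
    s2 = m2[order[np.searchsorted(cw, quantile * cw[-1])]] if len(order) > 1 else m2[0]
    # floor at the boundary of a uniformly filled ellipse (m2 = 4), so a
    # compact filled region is kept whole; the inclusion boundary carries a
    # margin so that re-filtering an already-filtered map (whose second
    # moments have shrunk slightly) rejects nothing further
    s2 = max(s2, 4.0)
    outside = m2 > s2 * 1.3
    oy, ox = ys[outside], xs[outside]
    state[oy, ox] = REJECTED
    flags[oy, ox] |= FAILED_ELLIPSE
    lam, vec = np.linalg.eigh(cov)
    meta = {**mask.meta, "ellipse": {
        "center": ctr.tolist(), "cov": cov.tolist(),
        # moment-inverted semi-axes of the fitted (uniform-density) ellipse
        "axes": (2.0 * np.sqrt(lam[::-1])).tolist(),
        "angle_deg": float(np.degrees(np.arctan2(vec[1, -1], vec[0, -1]))),
        "scale2": float(s2), "quantile": quantile}}
    return PixelMask(state, flags, meta)


def wt_baseline(pm: PhaseMap, mask: Optional[PixelMask] = None) -> float:
    """Wild-type fluctuation baseline: median per-pixel statistic of a WT map."""
    fluct = pm.fluctuation
    sel = np.isfinite(fluct)
    if mask is not None:
        sel &= mask.eligible
    if not sel.any():
        raise ValueError("no pixels available to compute a baseline from")
    return float(np.median(fluct[sel]))


def reject_fluctuating(pm: PhaseMap, mask: PixelMask,
                       wt_baseline_sd: float, factor: float = 3.0) -> PixelMask:
    """Reject eligible pixels whose fluctuation exceeds ``factor`` x the WT baseline."""
    if wt_baseline_sd is None or not wt_baseline_sd > 0:
        raise ValueError(
            "a wild-type fluctuation baseline is required: compute one from a "
            "WT phase map (experimental, or simulated at DR=0) with wt_baseline()"
        )
    state = mask.state.copy()
    flags = mask.flags.copy()
    bad = mask.eligible & (np.nan_to_num(pm.fluctuation, nan=0.0) > factor * wt_baseline_sd)
    state[bad] = REJECTED
    flags[bad] |= FAILED_FLUCTUATION
    meta = {**mask.meta, "wt_baseline_sd": float(wt_baseline_sd), "factor": float(factor)}
    return PixelMask(state, flags, meta)


def filter_phase_map(
    pm: PhaseMap,
    k: int = 10_000,
    wt_baseline_sd: Optional[float] = None,
    factor: float = 3.0,
    quantile: float = 0.975,
    self_baseline: bool = False,
) -> PixelMask:
    """Full filtering pipeline: activity cut, ellipse ROI, fluctuation rejection.

    ``self_baseline=True`` computes the baseline from this map itself (only
    appropriate for wild-type maps); otherwise ``wt_baseline_sd`` must be
    supplied from a WT run.
    """
    mask = select_top_active(pm, k)
    mask = fit_response_ellipse(pm, mask, quantile)
    if wt_baseline_sd is None:
        if not self_baseline:
            raise ValueError(
                "a wild-type fluctuation baseline is required: pass wt_baseline_sd "
                "computed from a WT run, or self_baseline=True for a WT map"
            )
        wt_baseline_sd = wt_baseline(pm, mask)
    return reject_fluctuating(pm, mask, wt_baseline_sd, factor)


def apply_mask(pm: PhaseMap, mask: PixelMask) -> PhaseMap:
    """A copy of the phase map with non-eligible pixels blanked (NaN phases, zero amplitude).

    The mask's fitted ROI ellipse travels with the map, so re-filtering the
    masked map reuses it (pipeline idempotence).
    """
    keep = mask.eligible
    out = PhaseMap(
        azimuth=np.where(keep, pm.azimuth, np.nan),
        elevation=np.where(keep, pm.elevation, np.nan),
        amplitude=np.where(keep, pm.amplitude, 0.0),
        fluctuation=np.where(keep, pm.fluctuation, np.nan),
        pixel_size_um=pm.pixel_size_um,
        azimuth_span_deg=pm.azimuth_span_deg,
        elevation_span_deg=pm.elevation_span_deg,
        meta=dict(pm.meta),
    )
    if isinstance(mask.meta.get("ellipse"), dict):
        out.meta["ellipse"] = mask.meta["ellipse"]
    return out
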