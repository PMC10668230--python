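"""The reduced-scale study protocol: develop, image, filter, reconstruct, score.

One call of :func:`reduced_run` performs a complete knock-in experiment at
desk scale: place the two cell sheets, develop the projection by MCMC, image
it with the Fourier emulator, filter the phase map, build the whole-map
lattice and the rostral/caudal partmaps, and report Map Quality, combined
partmap quality, visual-field duplication and the 1%-injection footprint.
Used by the acceptance script and the acceptance test suite; sizes default
to the desk-scale protocol described in docs/methods.md.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .filtering import filter_phase_map
from .imaging import ImagingParams, image_projection
from .lattice import (
    LatticeParams,
    build_paired_lattice,
    largest_ordered_submap,
    partition_and_partmaps,
    place_virtual_electrodes,
)
from .metrics import vfd
from .pipeline import substream
from .substrate import KnockinSpec, assign_gradients, place_cells
from .tk import EnergyParams, run_tk2011, virtual_injection

__all__ = ["reduced_run", "critical_dr"]


def reduced_run(
    dr: float,
    seed: int,
    n: int = 1000,
    iterations: int = 10_000_000,
    baseline: Optional[float] = None,
    partition: str = "auto",
    energy: Optional[EnergyParams] = None,
    imaging: Optional[ImagingParams] = None,
) -> dict:
    """One full simulate->image->filter->lattice->metrics experiment.

    ``baseline`` is the wild-type fluctuation baseline; omit it for DR=0 runs
    (computed from the run's own map).  ``partition``: ``"auto"`` draws the
    dividing line through the rejected band, falling back to an equal-halves
    split when no band separates the eligible region; ``"halves"`` forces the
    equal split (the wild-type convention).
    """
    ret = place_cells(n, "circle", seed=substream(seed, "substrate"))
    col = place_cells(n, "hemi-ellipse", seed=substream(seed, "substrate") + 1)
    assign_gradients(ret, KnockinSpec(DR=dr, seed=substream(seed, "knockin")))
    assign_gradients(col)
    energy = energy or EnergyParams()
    sim = run_tk2011(ret, col, energy, iterations=iterations,
                     seed=substream(seed, "mcmc"))
    pm = image_projection(sim.contacts, ret, col, imaging,
                          seed=substream(seed, "imaging"))
    if baseline is None:
        mask = filter_phase_map(pm, self_baseline=True)
        baseline = mask.meta["wt_baseline_sd"]
    else:
        mask = filter_phase_map(pm, wt_baseline_sd=baseline)
    lp = LatticeParams(seed=substream(seed, "electrodes"))
    elec = place_virtual_electrodes(mask, lp, pm.pixel_size_um)
    whole = build_paired_lattice(elec, pm, mask, lp)
    sub, quality = largest_ordered_submap(whole)
    out = {
        "dr": dr,
        "seed": seed,
        "n": n,
        "baseline": float(baseline),
        "n_nodes": whole.n_nodes,
        "map_quality": quality,
    }
    try:
        part = partition_and_partmaps(
            mask, pm, line="halves" if partition == "halves" else None, lp=lp)
    except ValueError:
        part = partition_and_partmaps(mask, pm, line="halves", lp=lp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        out["vfd"] = vfd(part.rostral_sub, part.caudal_sub)
    out["combined_quality"] = part.combined_map_quality
    out["injection_fraction"] = virtual_injection(
        sim.contacts, col, ret, area_fraction=0.01, method="closing")
    return out


def critical_dr(
    dr_grid=(0.0, 0.05, 0.1, 0.15, 0.2),
    replicates: int = 10,
    seed: int = 0,
    n: int = 500,
    iterations: int = 4_000_000,
    vfd_excess: float = 1.0,
    quality_drop: float = 5.0,
) -> tuple[float, dict]:
    """Smallest augment at which map irregularities emerge.

    Runs the reduced protocol over a DR grid with a constant partition policy
    (equal halves, so the duplication measure is comparable across the
    sweep); irregularity = median VFD more than ``vfd_excess`` points above
    the DR=0 level, or median whole-map quality more than ``quality_drop``
    points below it.  Returns the first such DR (one grid step past the end
    if none triggers) and the per-DR medians.
    """
    seeds = [int(s) for s in
             (np.random.SeedSequence(seed).generate_state(replicates * len(dr_grid))
              & 0x7FFFFFFF)]
    table: dict[float, dict] = {}
    baselines: list[float] = []
    it = iter(seeds)
    for dr in dr_grid:
        vfds, mqs = [], []
        for _ in range(replicates):
            s = next(it)
            bl = float(np.median(baselines)) if (dr > 0 and baselines) else None
            res = reduced_run(dr, s, n=n, iterations=iterations, baseline=bl,
                              partition="halves")
            if dr == 0:
                baselines.append(res["baseline"])
            vfds.append(res["vfd"])
            mqs.append(res["map_quality"])
        table[dr] = {"vfd": float(np.median(vfds)),
                     "map_quality": float(np.median(mqs))}
    q0 = table[dr_grid[0]]["map_quality"]
    v0 = table[dr_grid[0]]["vfd"]
    crit = None
    for dr in dr_grid:
        if dr == 0:
            continue
        if (table[dr]["vfd"] > v0 + vfd_excess
                or table[dr]["map_quality"] < q0 - quality_drop):
            crit = dr
            break
    if crit is None:
        step = dr_grid[-1] - dr_grid[-2] if len(dr_grid) > 1 else 0.05
        crit = dr_grid[-1] + step
    return float(crit), table
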