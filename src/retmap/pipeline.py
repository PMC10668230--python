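"""End-to-end pipeline: simulate -> image -> filter -> lattice -> metrics.

All stages write their artifacts to a results directory with a manifest
recording parameters and seeds, and each stage can be re-run standalone on
the previous stage's outputs.  All randomness flows from a single master
seed through named substreams (substrate, knockin, mcmc, imaging,
electrodes), so the same configuration and seed reproduce byte-identical
metric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .substrate import CellSheet, KnockinSpec, assign_gradients, place_cells, DR_HET, DR_HOM
from .tk import ContactSet, EnergyParams, run_tk2006, run_tk2011, virtual_injection
from .imaging import ImagingParams, PhaseMap, image_projection
from .filtering import PixelMask, filter_phase_map, wt_baseline
from .lattice import (
    LatticeParams,
    build_paired_lattice,
    largest_ordered_submap,
    partition_and_partmaps,
    place_virtual_electrodes,
)
from .metrics import MapMetrics, magnification, map_quality, polarity, vfd

__all__ = ["PipelineConfig", "run_pipeline", "analyze_phase_map", "sweep", "substream"]

_SUBSTREAMS = ("substrate", "knockin", "mcmc", "imaging", "electrodes")


def substream(master_seed: int, name: str) -> int:
    """Deterministic named substream seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from a YAML or JSON mapping."""

    n_retina: int = 1000
    n_colliculus: int = 1000
    model: str = "tk2011"           # or "tk2006"
    DR: Optional[float] = 0.0       # overrides genotype if set
    genotype: Optional[str] = None  # "wt" | "het" | "hom"
    knockin_fraction: float = 0.5
    iterations: int = 10_000_000
    seed: int = 0
    energy: EnergyParams = dataclasses.field(default_factory=EnergyParams)
    imaging: ImagingParams = dataclasses.field(default_factory=ImagingParams)
    lattice: LatticeParams = dataclasses.field(default_factory=LatticeParams)
    filter_k: int = 10_000
    wt_baseline_sd: Optional[float] = None  # None => compute from this map (WT only)
    fluctuation_factor: float = 3.0
    partition: Optional[str] = "auto"  # "auto" | "halves" | None (skip partmaps)
    out_dir: str = "results/run"

    @property
    def dr_value(self) -> float:
        if self.genotype is not None:
            return {"wt": 0.0, "het": DR_HET, "hom": DR_HOM}[self.genotype]
        return float(self.DR or 0.0)

    @classmethod
    def from_mapping(cls, m: dict) -> "PipelineConfig":
        m = dict(m)
        kwargs = {}
        for sub, klass in (("energy", EnergyParams), ("imaging", ImagingParams),
                           ("lattice", LatticeParams)):
            if sub in m:
                sect = m.pop(sub)
                try:
                    kwargs[sub] = klass(**sect)
                except TypeError as err:
                    raise ValueError(f"config section '{sub}': {err}") from None
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(m) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        if "imaging" in kwargs and isinstance(kwargs["imaging"].pixel_grid, list):
            kwargs["imaging"].pixel_grid = tuple(kwargs["imaging"].pixel_grid)
        return cls(**m, **kwargs)

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _build_sheets(cfg: PipelineConfig) -> tuple[CellSheet, CellSheet]:
    s = cfg.seed
    ret = place_cells(cfg.n_retina, "circle", seed=substream(s, "substrate"))
    col = place_cells(cfg.n_colliculus, "hemi-ellipse", seed=substream(s, "substrate") + 1)
    ki = KnockinSpec(DR=cfg.dr_value, fraction=cfg.knockin_fraction,
                     seed=substream(s, "knockin"))
    assign_gradients(ret, ki)
    assign_gradients(col)
    return ret, col


def analyze_phase_map(
    pm: PhaseMap,
    cfg: PipelineConfig,
    out: Optional[Path] = None,
) -> dict:
    """Filter a phase map, build lattices/partmaps and compute all metrics.

    The shared analysis path for simulated and experimentally supplied maps.
    """
    mask = filter_phase_map(pm, k=cfg.filter_k, wt_baseline_sd=cfg.wt_baseline_sd,
                            factor=cfg.fluctuation_factor,
                            self_baseline=cfg.wt_baseline_sd is None)
    lp = dataclasses.replace(cfg.lattice, seed=substream(cfg.seed, "electrodes"))
    elec = place_virtual_electrodes(mask, lp, pm.pixel_size_um)
    whole = build_paired_lattice(elec, pm, mask, lp)
    sub, quality = largest_ordered_submap(whole)
    metrics = MapMetrics(
        n_nodes_whole=whole.n_nodes,
        n_nodes_submap=sub.n_nodes,
        map_quality=quality,
        rc_polarity=polarity(sub, "RC"),
        ml_polarity=polarity(sub, "ML"),
        azimuthal_magnification=magnification(sub, "azimuthal", delta_um=lp.delta_um),
        elevational_magnification=magnification(sub, "elevational", delta_um=lp.delta_um),
    )
    result = {"whole": whole, "submap": sub, "mask": mask, "metrics": metrics,
              "wt_baseline_sd": mask.meta.get("wt_baseline_sd")}
    if cfg.partition:
        try:
            part = partition_and_partmaps(
                mask, pm, line=None if cfg.partition == "auto" else cfg.partition, lp=lp)
            metrics.vfd = vfd(part.rostral_sub, part.caudal_sub)
            result["partmaps"] = part
            result["combined_map_quality"] = part.combined_map_quality
        except ValueError as err:
            warnings.warn(f"partitioning skipped: {err}", stacklevel=2)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        mask.save(out / "pixel_mask")
        whole.save(out / "lattice_whole.json")
        sub.save(out / "lattice_submap.json")
        whole.plot(out / "lattice_whole.png")
        sub.plot(out / "lattice_submap.png")
        rows = metrics.as_dict()
        if "combined_map_quality" in result:
            rows["combined_map_quality"] = result["combined_map_quality"]
        pd.DataFrame([rows]).to_csv(out / "metrics.csv", index=False)
    return result


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Full run: develop the projection, image it, analyze, write artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ret, col = _build_sheets(cfg)
    ret.save(out / "retina")
    col.save(out / "colliculus")
    runner = run_tk2011 if cfg.model == "tk2011" else run_tk2006
    sim = runner(ret, col, cfg.energy, iterations=cfg.iterations,
                 seed=substream(cfg.seed, "mcmc"))
    sim.contacts.save(out / "contacts", metadata={
        "iterations": cfg.iterations, "seed": cfg.seed,
        "energy_final": sim.energy_final,
    })
    np.savetxt(out / "energy_trace.txt", sim.energy_trace)
    pm = image_projection(sim.contacts, ret, col, cfg.imaging,
                          seed=substream(cfg.seed, "imaging"))
    pm.save(out / "phase_map")
    pm.to_tiff(out / "phase_map.tiff")
    result = analyze_phase_map(pm, cfg, out)
    result["contacts"] = sim.contacts
    result["phase_map"] = pm
    result["injection_fraction"] = virtual_injection(
        sim.contacts, col, ret, method="closing") if cfg.model == "tk2011" else None
    manifest = {
        "version": __version__,
        "config": cfg.to_mapping(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_mapping(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "substreams": {name: substream(cfg.seed, name) for name in _SUBSTREAMS},
        "metrics": {k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v)
                    for k, v in result["metrics"].as_dict().items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return result


def sweep(
    dr_values,
    replicates: int = 5,
    base: Optional[PipelineConfig] = None,
    wt_baseline_from_dr0: bool = True,
) -> pd.DataFrame:
    """DR sweep with replicates: long-format table of per-run map statistics.

    The wild-type fluctuation baseline is computed from the DR=0 arm (median
    over its replicates) and applied to every knock-in run.
    """
    base = base or PipelineConfig()
    rows = []
    baseline = base.wt_baseline_sd
    if wt_baseline_from_dr0 and baseline is None:
        bls = []
        for rep in range(replicates):
            cfg = dataclasses.replace(base, DR=0.0, genotype=None, seed=base.seed + 1000 + rep,
                                      wt_baseline_sd=None, partition=None)
            ret, col = _build_sheets(cfg)
            sim = run_tk2011(ret, col, cfg.energy, iterations=cfg.iterations,
                             seed=substream(cfg.seed, "mcmc"))
            pm = image_projection(sim.contacts, ret, col, cfg.imaging,
                                  seed=substream(cfg.seed, "imaging"))
            mask = filter_phase_map(pm, k=cfg.filter_k, self_baseline=True)
            bls.append(mask.meta["wt_baseline_sd"])
        baseline = float(np.median(bls))
    for dr in dr_values:
        for rep in range(replicates):
            cfg = dataclasses.replace(
                base, DR=float(dr), genotype=None, seed=base.seed + rep,
                wt_baseline_sd=baseline,
                out_dir=str(Path(base.out_dir) / f"dr{dr:g}_rep{rep}"),
            )
            ret, col = _build_sheets(cfg)
            sim = run_tk2011(ret, col, cfg.energy, iterations=cfg.iterations,
                             seed=substream(cfg.seed, "mcmc"))
            pm = image_projection(sim.contacts, ret, col, cfg.imaging,
                                  seed=substream(cfg.seed, "imaging"))
            res = analyze_phase_map(pm, cfg)
            row = {
                "DR": float(dr),
                "replicate": rep,
                "seed": cfg.seed,
                "vfd": res["metrics"].vfd,
                "map_quality": res["metrics"].map_quality,
                "combined_map_quality": res.get("combined_map_quality", np.nan),
                "n_nodes": res["metrics"].n_nodes_whole,
            }
            rows.append(row)
    return pd.DataFrame(rows)
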