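"""Cell sheets for retina and colliculus: positions and guidance-molecule gradients.

The retina is a unit-diameter disc (nasotemporal axis = x, ventrodorsal = y)
carrying EphA (``R_A``, rising nasal->temporal) and EphB (``R_B``, rising
ventral->dorsal).  The colliculus is a hemi-ellipse (rostrocaudal = x,
lateromedial = y) carrying ephrinA (``C_A``, rising rostral->caudal, so that
high EphA matches low ephrinA) and ephrinB (``C_B``, rising lateral->medial).

The EphA3 knock-in adds a fixed augment ``DR`` to a random ~50% subset of
retinal cells (the Islet2 class), modelling the salt-and-pepper expression of
the knocked-in receptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional

import numpy as np

__all__ = [
    "Region",
    "CIRCLE",
    "HEMI_ELLIPSE",
    "CellSheet",
    "KnockinSpec",
    "PackingError",
    "place_cells",
    "assign_gradients",
    "epha_profile",
    "default_spacing",
    "DR_HET",
    "DR_HOM",
]

#: EphA augments for the heterozygous / homozygous knock-in, expressed as a
#: fraction of the wild-type EphA span (the homozygote carries twice the dose).
DR_HET = 0.37
DR_HOM = 0.74

#: default exponential-ramp steepness of the retinal EphA and collicular
#: ephrinA gradients (see epha_profile and assign_gradients)
EPHA_K = 2.0
EPHRIN_K = 4.0


@dataclass(frozen=True)
class Region:
    """A 2D region cells can occupy, with containment test and sampling."""

    name: str
    # bounding box (x0, x1, y0, y1)
    bbox: tuple[float, float, float, float]

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        if self.name == "circle":
            # unit-diameter disc centred at (0.5, 0.5)
            return (xy[:, 0] - 0.5) ** 2 + (xy[:, 1] - 0.5) ** 2 <= 0.25
        if self.name == "hemi-ellipse":
            # upper half of an ellipse centred (0.5, 0) with semi-axes (0.5, 0.6)
            inside = ((xy[:, 0] - 0.5) / 0.5) ** 2 + (xy[:, 1] / 0.6) ** 2 <= 1.0
            return inside & (xy[:, 1] >= 0.0)
        raise ValueError(f"unknown region {self.name!r}")

    @property
    def area(self) -> float:
        if self.name == "circle":
            return float(np.pi * 0.25)
        if self.name == "hemi-ellipse":
            return float(np.pi * 0.5 * 0.6 / 2.0)
        raise ValueError(self.name)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform rejection sampling of ``n`` points inside the region."""
        out = np.empty((n, 2))
        filled = 0
        x0, x1, y0, y1 = self.bbox
        while filled < n:
            m = max(2 * (n - filled), 16)
            cand = rng.uniform((x0, y0), (x1, y1), size=(m, 2))
            cand = cand[self.contains(cand)]
            take = min(len(cand), n - filled)
            out[filled : filled + take] = cand[:take]
            filled += take
        return out


CIRCLE = Region("circle", (0.0, 1.0, 0.0, 1.0))
HEMI_ELLIPSE = Region("hemi-ellipse", (0.0, 1.0, 0.0, 0.6))

_REGIONS = {"circle": CIRCLE, "hemi-ellipse": HEMI_ELLIPSE}


class PackingError(RuntimeError):
    """Raised when the requested min spacing cannot be achieved for n cells."""


@dataclass
class KnockinSpec:
    """EphA3 knock-in: augment ``DR`` added to a random fraction of retinal cells."""

    DR: float = 0.0
    fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.DR < 0:
            raise ValueError("DR must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")

    @classmethod
    def het(cls, seed: int = 0) -> "KnockinSpec":
        return cls(DR=DR_HET, seed=seed)

    @classmethod
    def hom(cls, seed: int = 0) -> "KnockinSpec":
        return cls(DR=DR_HOM, seed=seed)


@dataclass
class CellSheet:
    """One cell population (retina or colliculus) with positions and labels.

    ``label_a``/``label_b`` hold EphA/EphB for a retina and ephrinA/ephrinB for
    a colliculus, all on the normalized (wild-type span = [0, 1]) scale.
    """

    structure: Literal["retina", "colliculus"]
    positions: np.ndarray  # (n, 2)
    region: Region
    min_spacing: float
    seed: int
    label_a: Optional[np.ndarray] = None
    label_b: Optional[np.ndarray] = None
    is_knockin: Optional[np.ndarray] = None
    knockin: Optional[KnockinSpec] = None

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    # -- IO ---------------------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.csv`` (one row per cell) and ``<prefix>.json`` header."""
        prefix = Path(prefix)
        n = self.n
        cols = {"x": self.x, "y": self.y}
        if self.label_a is not None:
            a, b = ("R_A", "R_B") if self.structure == "retina" else ("C_A", "C_B")
            cols[a] = self.label_a
            cols[b] = self.label_b
        if self.is_knockin is not None:
            cols["is_knockin"] = self.is_knockin.astype(int)
        header = ",".join(cols)
        data = np.column_stack([np.asarray(v, dtype=float) for v in cols.values()])
        np.savetxt(prefix.with_suffix(".csv"), data, delimiter=",", header=header, comments="")
        meta = {
            "structure": self.structure,
            "region": self.region.name,
            "min_spacing": self.min_spacing,
            "seed": self.seed,
            "n": n,
        }
        if self.knockin is not None:
            meta["knockin"] = {
                "DR": self.knockin.DR,
                "fraction": self.knockin.fraction,
                "seed": self.knockin.seed,
            }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "CellSheet":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        with open(prefix.with_suffix(".csv")) as fh:
            names = fh.readline().strip().split(",")
        data = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1, ndmin=2)
        cols = {name: data[:, i] for i, name in enumerate(names)}
        ki = meta.get("knockin")
        sheet = cls(
            structure=meta["structure"],
            positions=np.column_stack([cols["x"], cols["y"]]),
            region=_REGIONS[meta["region"]],
            min_spacing=meta["min_spacing"],
            seed=meta["seed"],
            label_a=cols.get("R_A", cols.get("C_A")),
            label_b=cols.get("R_B", cols.get("C_B")),
            is_knockin=cols["is_knockin"].astype(bool) if "is_knockin" in cols else None,
            knockin=KnockinSpec(**ki) if ki else None,
        )
        return sheet


def default_spacing(n: int, region: Region) -> float:
    """A comfortably feasible min spacing for ``n`` cells in ``region``."""
    return 0.5 * float(np.sqrt(region.area / n))


def place_cells(
    n: int,
    region: Region | str,
    min_spacing: Optional[float] = None,
    seed: int = 0,
    max_failures: int = 10_000,
) -> CellSheet:
    """Distribute ``n`` cells uniformly in ``region`` with a hard spacing floor.

    Rejection sampling against a spatial hash; after ``max_failures``
    consecutive rejected candidates the packing is declared infeasible.
    """
    if isinstance(region, str):
        region = _REGIONS[region]
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_spacing is None:
        min_spacing = default_spacing(n, region)
    rng = np.random.default_rng(seed)
    s = float(min_spacing)
    x0, x1, y0, y1 = region.bbox
    # grid cell = spacing, so conflicts live in the 3x3 neighbourhood
    nx = max(1, int(np.ceil((x1 - x0) / s)))
    ny = max(1, int(np.ceil((y1 - y0) / s)))
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    placed = 0
    failures = 0
    while placed < n:
        p = rng.uniform((x0, y0), (x1, y1))
        if not region.contains(p[None, :])[0]:
            continue  # outside the region does not count toward packing failure
        gx = min(int((p[0] - x0) / s), nx - 1)
        gy = min(int((p[1] - y0) / s), ny - 1)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), ()):
                    d2 = (pts[j, 0] - p[0]) ** 2 + (pts[j, 1] - p[1]) ** 2
                    if d2 < s * s:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid.setdefault((gx, gy), []).append(placed)
            placed += 1
            failures = 0
        else:
            failures += 1
            if failures >= max_failures:
                raise PackingError(
                    f"could not place cell {placed + 1}/{n} at spacing {s:g} "
                    f"after {max_failures} consecutive failures"
                )
    return CellSheet(
        structure="retina" if region.name == "circle" else "colliculus",
        positions=pts,
        region=region,
        min_spacing=s,
        seed=seed,
    )


def epha_profile(k: float = 2.0) -> Callable[[np.ndarray], np.ndarray]:
    """Normalized exponential EphA/ephrinA ramp ``(e^{kx}-1)/(e^k-1)``.

    A parametric stand-in for the measured receptor profiles; the quantified
    profile values are not reproduced here, so the shape is pluggable — any
    callable mapping normalized axis position to [0, 1], or a tabulated profile
    via :func:`tabulated_profile`, may be passed to :func:`assign_gradients`.
    """

    denom = np.expm1(k)

    def profile(x: np.ndarray) -> np.ndarray:
        return np.expm1(k * np.asarray(x)) / denom

    return profile


def tabulated_profile(x_tab: np.ndarray, v_tab: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Profile interpolated from a table of (axis position, level) samples."""
    x_tab = np.asarray(x_tab, dtype=float)
    v_tab = np.asarray(v_tab, dtype=float)

    def profile(x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x), x_tab, v_tab)

    return profile


def assign_gradients(
    cells: CellSheet,
    knockin: Optional[KnockinSpec] = None,
    profile_a: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    ephrin_offset: float = 0.0,
) -> CellSheet:
    """Attach molecular labels to a placed sheet.

    Retina: ``R_A = profile(x)`` (wild type spans [0, 1]) plus ``DR`` on the
    EphA3+ subset drawn Bernoulli(``fraction``); ``R_B`` linear in y.
    Colliculus: ``C_A = offset + (1-offset)·profile(x)`` rising
    rostral->caudal (high EphA maps to low ephrinA); ``C_B`` linear in the
    mediolateral coordinate.  The default ephrinA ramp is steeper (k=4) than
    the EphA ramp (k=2): its rostral flatness lets correlated activity hold
    EphA3+ and EphA3- fibres of common retinal origin in register rostrally,
    while its steep caudal slope enforces chemoaffinity sorting (separation)
    caudally — the combination that shapes partial double maps.  The
    duplication extent itself is governed by the retinal EphA ramp alone.
    """
    if profile_a is None:
        profile_a = epha_profile(EPHRIN_K if cells.structure == "colliculus" else EPHA_K)
    if cells.structure == "retina":
        if knockin is None:
            knockin = KnockinSpec(DR=0.0)
        base = profile_a(cells.x)
        rng = np.random.default_rng(knockin.seed)
        is_ki = rng.random(cells.n) < knockin.fraction
        cells.label_a = base + knockin.DR * is_ki
        cells.label_b = cells.y.copy()
        cells.is_knockin = is_ki
        cells.knockin = knockin
    else:
        cells.label_a = ephrin_offset + (1.0 - ephrin_offset) * profile_a(cells.x)
        y0, y1 = 0.0, 0.6
        cells.label_b = (cells.y - y0) / (y1 - y0)
        cells.is_knockin = None
    return cells
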