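"""Energy-minimization MCMC development of the retinocollicular projection.

Two variants of the chemoaffinity/activity/competition model are provided:

* :func:`run_tk2011` — multi-contact model.  Contacts between retinal and
  collicular cells are created and deleted by a Markov chain; the energy of a
  configuration is

  ``E = α Σ R_A·C_A − β Σ R_B·C_B − (γ/2) Σ_pairs K_ret(d_ret)·K_coll(d_coll)
  + (w/2)[Σ_i (m_i−1)² + Σ_j (n_j−1)²]``

  with ``K_ret(d) = exp(−d/a)``, ``K_coll(d) = exp(−d/b)``.  The chemoaffinity
  product favours high-EphA cells pairing with low-ephrinA territory (and high
  EphB with high ephrinB), the activity term favours contacts from retinal
  neighbourhoods onto collicular neighbourhoods, and the quadratic competition
  term keeps per-cell contact loads near one on both sides, implementing
  competition for space.

* :func:`run_tk2006` — one-contact-per-cell variant.  The state is a bijection
  between equal-sized sheets, moves exchange the retinal partners of two
  collicular cells, and no competition term is needed.

Both chains accept a move with probability ``1/(1 + exp(ΔE/T))``, so they
converge to a Gibbs distribution over configurations rather than to a single
minimum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import _kernels
from .substrate import CellSheet, KnockinSpec, assign_gradients

__all__ = [
    "EnergyParams",
    "ContactSet",
    "SimResult",
    "energy_total",
    "accept_probability",
    "mcmc_step",
    "run_tk2011",
    "run_tk2006",
    "virtual_injection",
    "calibrate_activity_weight",
    "mean_nn_spacing",
]

#: Calibrated activity-magnitude multiplier.  The base weight γ=0.00625 refers
#: to the reference model's internal correlation functions; with the
#: exponential kernels used here the activity magnitude is rescaled so that a
#: wild-type virtual injection of 1% of the retinal area innervates ~1% of the
#: colliculus (see calibrate_activity_weight and docs/methods.md).
ACTIVITY_SCALE_DEFAULT = 40.0


@dataclass
class EnergyParams:
    """Weights and length scales of the map-development energy."""

    alpha: float = 90.0          # chemoaffinity-A weight
    beta: float = 135.0          # chemoaffinity-B weight
    a: float = 0.03              # retinal correlation length (normalized units)
    b: float = 0.11              # collicular interaction length
    gamma: float = 0.00625       # base activity weight
    activity_scale: float = ACTIVITY_SCALE_DEFAULT
    comp_weight: float = 5.0     # competition (per-cell quadratic) weight
    temperature: float = 1.0     # MCMC acceptance scale
    cutoff_factor: float = 4.0   # retinal pair-sum truncation, units of `a`
    activity_ramp: float = 0.5   # fraction of the run over which the activity
                                 # weight grows from 0 to full (developmental
                                 # sequence: chemoaffinity first, then
                                 # activity-dependent refinement)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("interaction lengths must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    @property
    def gamma_eff(self) -> float:
        return self.gamma * self.activity_scale

    @property
    def cutoff(self) -> float:
        return self.cutoff_factor * self.a


@dataclass
class ContactSet:
    """Sparse retina->colliculus contact map.

    Stored as parallel instance arrays (one entry per contact instance, so a
    multiply-contacted pair appears several times); ``aggregated`` collapses
    them to (retina_id, colliculus_id, count) triples.
    """

    ret_ids: np.ndarray
    coll_ids: np.ndarray
    n_retina: int
    n_colliculus: int
    mode: str = "multi"  # "multi" (TK2011) or "bijection" (TK2006)

    def __post_init__(self) -> None:
        self.ret_ids = np.asarray(self.ret_ids, dtype=np.int32)
        self.coll_ids = np.asarray(self.coll_ids, dtype=np.int32)
        if self.ret_ids.size and (
            self.ret_ids.max() >= self.n_retina or self.coll_ids.max() >= self.n_colliculus
            or self.ret_ids.min() < 0 or self.coll_ids.min() < 0
        ):
            raise ValueError("contact references a cell id outside either sheet")
        if self.mode == "bijection":
            if len(self.coll_ids) != self.n_colliculus or len(np.unique(self.coll_ids)) != self.n_colliculus:
                raise ValueError("bijection mode requires exactly one contact per collicular cell")
            if len(np.unique(self.ret_ids)) != len(self.ret_ids):
                raise ValueError("bijection mode requires distinct retinal partners")

    @property
    def n_contacts(self) -> int:
        return len(self.ret_ids)

    def aggregated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        key = self.ret_ids.astype(np.int64) * self.n_colliculus + self.coll_ids
        uniq, counts = np.unique(key, return_counts=True)
        return (uniq // self.n_colliculus).astype(np.int32), (uniq % self.n_colliculus).astype(np.int32), counts

    def counts_per_retina(self) -> np.ndarray:
        return np.bincount(self.ret_ids, minlength=self.n_retina)

    def counts_per_colliculus(self) -> np.ndarray:
        return np.bincount(self.coll_ids, minlength=self.n_colliculus)

    def save(self, prefix: str | Path, metadata: Optional[dict] = None) -> None:
        prefix = Path(prefix)
        r, c, k = self.aggregated()
        np.savetxt(
            prefix.with_suffix(".csv"),
            np.column_stack([r, c, k]),
            fmt="%d",
            delimiter=",",
            header="retina_id,colliculus_id,count",
            comments="",
        )
        meta = {
            "mode": self.mode,
            "n_retina": self.n_retina,
            "n_colliculus": self.n_colliculus,
        }
        if metadata:
            meta.update(metadata)
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=float))

    @classmethod
    def load(cls, prefix: str | Path) -> "ContactSet":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        data = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1, dtype=np.int64, ndmin=2)
        ret = np.repeat(data[:, 0], data[:, 2])
        col = np.repeat(data[:, 1], data[:, 2])
        return cls(ret, col, meta["n_retina"], meta["n_colliculus"], meta["mode"])


@dataclass
class SimResult:
    contacts: ContactSet
    energy_trace: np.ndarray
    energy_final: float
    energy_check: float  # full recomputation at the end of the run
    iterations: int
    seed: int
    params: EnergyParams


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def _require_labels(retina: CellSheet, colliculus: CellSheet) -> None:
    if retina.label_a is None or colliculus.label_a is None:
        raise ValueError("sheets must have gradients assigned (assign_gradients)")


def _pair_kernels(contacts: ContactSet, retina: CellSheet, colliculus: CellSheet,
                  p: EnergyParams) -> np.ndarray:
    """Dense pairwise activity kernel between contact instances (test scale)."""
    rp = retina.positions[contacts.ret_ids]
    cp = colliculus.positions[contacts.coll_ids]
    dr = cdist(rp, rp)
    dc = cdist(cp, cp)
    kr = np.exp(-dr / p.a)
    kr[dr > p.cutoff] = 0.0
    return kr * np.exp(-dc / p.b)


def energy_total(contacts: ContactSet, retina: CellSheet, colliculus: CellSheet,
                 p: EnergyParams) -> float:
    """Total configuration energy (chemoaffinity + activity + competition).

    Dense O(n²) evaluation over contact instances — intended for verification
    and small systems; the run kernels keep their own incremental energy.
    """
    _require_labels(retina, colliculus)
    r = contacts.ret_ids
    c = contacts.coll_ids
    e_chem = float(
        p.alpha * np.sum(retina.label_a[r] * colliculus.label_a[c])
        - p.beta * np.sum(retina.label_b[r] * colliculus.label_b[c])
    )
    if contacts.n_contacts:
        K = _pair_kernels(contacts, retina, colliculus, p)
        np.fill_diagonal(K, 0.0)
        e_act = -0.5 * p.gamma_eff * float(K.sum())
    else:
        e_act = 0.0
    if contacts.mode == "bijection":
        e_comp = 0.0
    else:
        m = contacts.counts_per_retina()
        nc = contacts.counts_per_colliculus()
        e_comp = 0.5 * p.comp_weight * float(np.sum((m - 1.0) ** 2) + np.sum((nc - 1.0) ** 2))
    return e_chem + e_act + e_comp


def accept_probability(delta_e: float, temperature: float = 1.0) -> float:
    """Logistic acceptance rule: 1/2 at ΔE=0, ->1 as ΔE->-inf."""
    return float(1.0 / (1.0 + np.exp(np.clip(delta_e / temperature, -500, 500))))


def _delta_create(contacts: ContactSet, retina: CellSheet, colliculus: CellSheet,
                  p: EnergyParams, r: int, c: int) -> float:
    s = 0.0
    if contacts.n_contacts:
        dr = np.linalg.norm(retina.positions[contacts.ret_ids] - retina.positions[r], axis=1)
        kr = np.where(dr <= p.cutoff, np.exp(-dr / p.a), 0.0)
        dc = np.linalg.norm(colliculus.positions[contacts.coll_ids] - colliculus.positions[c], axis=1)
        s = float(np.sum(kr * np.exp(-dc / p.b)))
    m_r = int(np.count_nonzero(contacts.ret_ids == r))
    n_c = int(np.count_nonzero(contacts.coll_ids == c))
    return (p.alpha * retina.label_a[r] * colliculus.label_a[c]
            - p.beta * retina.label_b[r] * colliculus.label_b[c]
            - p.gamma_eff * s
            + p.comp_weight * ((m_r - 0.5) + (n_c - 0.5)))


def _delta_delete(contacts: ContactSet, retina: CellSheet, colliculus: CellSheet,
                  p: EnergyParams, g: int) -> float:
    r = int(contacts.ret_ids[g])
    c = int(contacts.coll_ids[g])
    keep = np.ones(contacts.n_contacts, dtype=bool)
    keep[g] = False
    dr = np.linalg.norm(retina.positions[contacts.ret_ids[keep]] - retina.positions[r], axis=1)
    kr = np.where(dr <= p.cutoff, np.exp(-dr / p.a), 0.0)
    dc = np.linalg.norm(colliculus.positions[contacts.coll_ids[keep]] - colliculus.positions[c], axis=1)
    s = float(np.sum(kr * np.exp(-dc / p.b)))
    m_r = int(np.count_nonzero(contacts.ret_ids == r))
    n_c = int(np.count_nonzero(contacts.coll_ids == c))
    return (-(p.alpha * retina.label_a[r] * colliculus.label_a[c]
              - p.beta * retina.label_b[r] * colliculus.label_b[c])
            + p.gamma_eff * s
            + p.comp_weight * ((1.5 - m_r) + (1.5 - n_c)))


def mcmc_step(contacts: ContactSet, retina: CellSheet, colliculus: CellSheet,
              p: EnergyParams, rng: np.random.Generator) -> ContactSet:
    """One creation/deletion step of the TK2011 chain (reference implementation).

    Mirrors the compiled run kernel move-for-move; a deletion proposed on an
    empty contact set is a no-op.  Intended for small systems and for checking
    the chain's stationary distribution against exact enumeration.
    """
    _require_labels(retina, colliculus)
    if rng.random() < 0.5:
        r = int(rng.integers(retina.n))
        c = int(rng.integers(colliculus.n))
        de = _delta_create(contacts, retina, colliculus, p, r, c)
        if rng.random() < accept_probability(de, p.temperature):
            return ContactSet(
                np.append(contacts.ret_ids, r), np.append(contacts.coll_ids, c),
                contacts.n_retina, contacts.n_colliculus, contacts.mode,
            )
    else:
        if contacts.n_contacts == 0:
            return contacts
        g = int(rng.integers(contacts.n_contacts))
        de = _delta_delete(contacts, retina, colliculus, p, g)
        if rng.random() < accept_probability(de, p.temperature):
            return ContactSet(
                np.delete(contacts.ret_ids, g), np.delete(contacts.coll_ids, g),
                contacts.n_retina, contacts.n_colliculus, contacts.mode,
            )
    return contacts


# ---------------------------------------------------------------------------
# run drivers
# ---------------------------------------------------------------------------

def _neighbor_csr(positions: np.ndarray, cutoff: float, a: float):
    tree = cKDTree(positions)
    nbrs = tree.query_ball_point(positions, cutoff)
    n = len(positions)
    ptr = np.zeros(n + 1, dtype=np.int64)
    for i, lst in enumerate(nbrs):
        ptr[i + 1] = ptr[i] + len(lst)
    idx = np.empty(ptr[-1], dtype=np.int32)
    w = np.empty(ptr[-1], dtype=np.float64)
    for i, lst in enumerate(nbrs):
        lst = np.asarray(lst, dtype=np.int32)
        idx[ptr[i]:ptr[i + 1]] = lst
        d = np.linalg.norm(positions[lst] - positions[i], axis=1)
        w[ptr[i]:ptr[i + 1]] = np.exp(-d / a)
    return ptr, idx, w


def _prepare(retina: CellSheet, colliculus: CellSheet, p: EnergyParams):
    _require_labels(retina, colliculus)
    ra = np.ascontiguousarray(retina.label_a, dtype=np.float64)
    rb = np.ascontiguousarray(retina.label_b, dtype=np.float64)
    ca = np.ascontiguousarray(colliculus.label_a, dtype=np.float64)
    cb = np.ascontiguousarray(colliculus.label_b, dtype=np.float64)
    ptr, idx, w = _neighbor_csr(retina.positions, p.cutoff, p.a)
    KC = np.exp(-cdist(colliculus.positions, colliculus.positions) / p.b)
    return ra, rb, ca, cb, ptr, idx, w, KC


def _kernel_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def run_tk2011(
    retina: CellSheet,
    colliculus: CellSheet,
    p: Optional[EnergyParams] = None,
    knockin: Optional[KnockinSpec] = None,
    iterations: int = 2_000_000,
    seed: int = 0,
    trace_stride: Optional[int] = None,
) -> SimResult:
    """Develop a multi-contact map by creation/deletion MCMC.

    ``knockin`` (if given) reassigns the retinal gradients with the requested
    EphA augment before the run; otherwise the sheet's existing labels are
    used.  The initial state is ``n_colliculus`` uniformly random contacts.
    """
    p = p or EnergyParams()
    if knockin is not None or retina.label_a is None:
        assign_gradients(retina, knockin)
    if colliculus.label_a is None:
        assign_gradients(colliculus)
    ra, rb, ca, cb, ptr, idx, w, KC = _prepare(retina, colliculus, p)
    rng = np.random.default_rng(seed)
    init_ret = rng.integers(retina.n, size=colliculus.n).astype(np.int32)
    init_col = rng.integers(colliculus.n, size=colliculus.n).astype(np.int32)
    stride = trace_stride or max(1, iterations // 200)
    gret, gcol, trace, e, e_check = _kernels.run_mcmc(
        ra, rb, ca, cb, ptr, idx, w, KC, init_ret, init_col,
        int(iterations), _kernel_seed(seed),
        p.alpha, p.beta, p.gamma_eff, p.comp_weight, p.temperature, int(stride),
        p.activity_ramp,
    )
    contacts = ContactSet(gret, gcol, retina.n, colliculus.n, "multi")
    return SimResult(contacts, trace, float(e), float(e_check), int(iterations), seed, p)


def run_tk2006(
    retina: CellSheet,
    colliculus: CellSheet,
    p: Optional[EnergyParams] = None,
    knockin: Optional[KnockinSpec] = None,
    iterations: int = 2_000_000,
    seed: int = 0,
    trace_stride: Optional[int] = None,
) -> SimResult:
    """Develop a one-contact-per-cell map by partner-exchange MCMC."""
    if retina.n != colliculus.n:
        raise ValueError("the one-contact variant requires equal cell counts")
    p = p or EnergyParams()
    if knockin is not None or retina.label_a is None:
        assign_gradients(retina, knockin)
    if colliculus.label_a is None:
        assign_gradients(colliculus)
    ra, rb, ca, cb, ptr, idx, w, KC = _prepare(retina, colliculus, p)
    rng = np.random.default_rng(seed)
    init_perm = rng.permutation(retina.n).astype(np.int32)
    stride = trace_stride or max(1, iterations // 200)
    perm, trace, e = _kernels.run_exchange(
        ra, rb, ca, cb, ptr, idx, w, KC, init_perm,
        int(iterations), _kernel_seed(seed),
        p.alpha, p.beta, p.gamma_eff, p.temperature, int(stride),
    )
    contacts = ContactSet(perm, np.arange(colliculus.n, dtype=np.int32),
                          retina.n, colliculus.n, "bijection")
    return SimResult(contacts, trace, float(e), float(e), int(iterations), seed, p)


# ---------------------------------------------------------------------------
# virtual injections
# ---------------------------------------------------------------------------

def mean_nn_spacing(positions: np.ndarray) -> float:
    tree = cKDTree(positions)
    d, _ = tree.query(positions, k=2)
    return float(np.mean(d[:, 1]))


def _footprint_area(points: np.ndarray, r_nn: float, bbox, px: float,
                    method: str = "union") -> float:
    """Area of the footprint of a point set built from discs of radius ``r_nn``.

    ``method="union"``: plain union of the discs.  ``method="closing"``:
    morphological closing (dilation then erosion) — the union's boundary
    inflation, which at coarse cell spacing overstates the area of a compact
    innervated region by ~(1 + r_nn/R)², is removed again.
    """
    from scipy.ndimage import binary_dilation, binary_erosion
    from skimage.morphology import disk

    x0, x1, y0, y1 = bbox
    W = int(np.ceil((x1 - x0) / px))
    H = int(np.ceil((y1 - y0) / px))
    rad = max(1, int(round(r_nn / px)))
    pad = rad + 2
    img = np.zeros((H + 2 * pad, W + 2 * pad), dtype=bool)
    ix = np.clip(((points[:, 0] - x0) / px).astype(int), 0, W - 1) + pad
    iy = np.clip(((points[:, 1] - y0) / px).astype(int), 0, H - 1) + pad
    img[iy, ix] = True
    out = binary_dilation(img, disk(rad))
    if method == "closing":
        out = binary_erosion(out, disk(rad))
    return float(np.count_nonzero(out)) * px * px


def virtual_injection(
    contacts: ContactSet,
    colliculus: CellSheet,
    retina: CellSheet,
    center: tuple[float, float] = (0.5, 0.5),
    area_fraction: float = 0.01,
    method: str = "union",
) -> float:
    """Collicular area fraction innervated by a small retinal injection.

    Retinal cells inside a disc covering ``area_fraction`` of the retina are
    selected; the returned value is the area of their contact footprint on the
    colliculus divided by the area of the full innervated collicular extent.
    A footprint is the union of discs around the contacted collicular cells,
    with radius equal to the mean collicular nearest-neighbour spacing.
    """
    if contacts.n_contacts == 0:
        warnings.warn("virtual injection on an empty contact set", stacklevel=2)
        return 0.0
    r_inj = np.sqrt(area_fraction * retina.region.area / np.pi)
    sel = np.linalg.norm(retina.positions - np.asarray(center), axis=1) <= r_inj
    hit = sel[contacts.ret_ids]
    targets = np.unique(contacts.coll_ids[hit])
    if targets.size == 0:
        warnings.warn("no contacts from the injected region", stacklevel=2)
        return 0.0
    all_targets = np.unique(contacts.coll_ids)
    r_nn = mean_nn_spacing(colliculus.positions)
    px = r_nn / 3.0
    bbox = colliculus.region.bbox
    num = _footprint_area(colliculus.positions[targets], r_nn, bbox, px, method)
    den = _footprint_area(colliculus.positions[all_targets], r_nn, bbox, px, method)
    return num / den if den > 0 else 0.0


def calibrate_activity_weight(
    retina: CellSheet,
    colliculus: CellSheet,
    p: Optional[EnergyParams] = None,
    scales: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    target: float = 0.01,
    iterations: int = 1_000_000,
    seeds: tuple[int, ...] = (0, 1, 2),
    area_fraction: float = 0.01,
) -> tuple[float, dict[float, float]]:
    """Scale the activity magnitude so a 1% retinal injection innervates ~1%.

    Runs short wild-type simulations over a grid of ``activity_scale`` values
    and returns the scale whose median footprint is closest to ``target``,
    together with the measured footprints.
    """
    p = p or EnergyParams()
    results: dict[float, float] = {}
    for s in scales:
        ps = replace(p, activity_scale=s)
        vals = []
        for sd in seeds:
            res = run_tk2011(retina, colliculus, ps, iterations=iterations, seed=sd)
            vals.append(virtual_injection(res.contacts, colliculus, retina,
                                          area_fraction=area_fraction))
        results[s] = float(np.median(vals))
    best = min(results, key=lambda s: abs(results[s] - target))
    return best, results
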