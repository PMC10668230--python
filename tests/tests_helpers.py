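"""Shared oracles and constructions for the test suite."""

import itertools
from collections import Counter

import numpy as np
from scipy.spatial import Delaunay

from retmap.lattice import LatticeMap, crossing_pairs, find_crossing_edges
from retmap.substrate import CIRCLE, HEMI_ELLIPSE, CellSheet
from retmap.tk import ContactSet, EnergyParams, energy_total, mcmc_step


def delaunay_lattice(coll, vis):
    coll = np.asarray(coll, dtype=float)
    tri = Delaunay(coll)
    e = np.vstack([tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]],
                   tri.simplices[:, [0, 2]]])
    edges = np.unique(np.sort(e, axis=1), axis=0)
    lm = LatticeMap(coll, np.asarray(vis, dtype=float), edges,
                    np.zeros(len(edges), bool), np.arange(len(coll)))
    lm.crossing = find_crossing_edges(lm)
    return lm


def linear_lattice(n=6, mirror=False):
    xs, ys = np.meshgrid(np.linspace(0, 1000.0, n), np.linspace(0, 800.0, n))
    coll = np.column_stack([xs.ravel(), ys.ravel()])
    az = (1000.0 - coll[:, 0]) * 0.1
    el = coll[:, 1] * 0.08
    if mirror:
        az = az.max() - az
    return delaunay_lattice(coll, np.column_stack([az, el]))


def grid_lattice_with_swap(seed, n=4):
    xs, ys = np.meshgrid(np.arange(float(n)), np.arange(float(n)))
    coll = np.column_stack([xs.ravel(), ys.ravel()]) * 100
    rng = np.random.default_rng(seed)
    vis = coll * 0.1 + rng.normal(0, 0.5, coll.shape)
    i, j = rng.choice(n * n, 2, replace=False)
    vis[[i, j]] = vis[[j, i]]
    return delaunay_lattice(coll, vis)


def exhaustive_min_removal(lm):
    """Smallest node set whose removal eliminates all crossing pairs."""
    pairs = crossing_pairs(lm)
    involved = sorted({node for p in pairs for e in p for node in lm.edges[e]})
    for size in range(len(involved) + 1):
        for combo in itertools.combinations(involved, size):
            dead = set(combo)
            if all(set(lm.edges[p[0]]) & dead or set(lm.edges[p[1]]) & dead
                   for p in pairs):
                return size
    return len(involved)


def toy_system():
    ret = CellSheet("retina", np.array([[0.3, 0.5], [0.7, 0.5]]), CIRCLE, 0.01, 0,
                    label_a=np.array([0.2, 0.6]), label_b=np.array([0.1, 0.3]))
    col = CellSheet("colliculus", np.array([[0.3, 0.2], [0.7, 0.2]]), HEMI_ELLIPSE,
                    0.01, 0,
                    label_a=np.array([0.3, 0.7]), label_b=np.array([0.2, 0.4]))
    p = EnergyParams(alpha=3.0, beta=2.0, gamma=0.5, activity_scale=1.0,
                     comp_weight=1.0, temperature=1.0, activity_ramp=0.0)
    return ret, col, p


def toy_chain_conditional_law(steps=100_000, seed=42):
    """Empirical vs exact Gibbs law of the toy chain, conditioned on two
    distinct contacts (within a fixed count the creation/deletion proposal
    factors are common, so the conditional stationary law is exp(-E/T)/Z)."""
    ret, col, p = toy_system()
    state = ContactSet(np.empty(0, int), np.empty(0, int), 2, 2)
    rng = np.random.default_rng(seed)
    counts = Counter()
    for _ in range(steps):
        state = mcmc_step(state, ret, col, p, rng)
        if state.n_contacts == 2:
            key = tuple(sorted(zip(state.ret_ids.tolist(), state.coll_ids.tolist())))
            if len(set(key)) == 2:
                counts[key] += 1
    pairs = list(itertools.product(range(2), range(2)))
    energies = {}
    for combo in itertools.combinations(pairs, 2):
        cs = ContactSet(np.array([c[0] for c in combo]),
                        np.array([c[1] for c in combo]), 2, 2)
        energies[tuple(sorted(combo))] = energy_total(cs, ret, col, p)
    total = sum(counts[c] for c in energies)
    z = sum(np.exp(-e / p.temperature) for e in energies.values())
    observed = {c: counts[c] / total for c in energies}
    expected = {c: float(np.exp(-e / p.temperature) / z) for c, e in energies.items()}
    return observed, expected
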