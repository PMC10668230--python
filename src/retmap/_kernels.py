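"""Numba kernels for the energy-minimization MCMC.

State layout (TK2011, multi-contact):
  - per-retinal-cell slot lists ``cols_by_ret[i, s]`` (collicular id of the
    s-th contact of retinal cell i) with counts ``m[i]``;
  - a compact global instance list ``gret/gcol`` for uniform deletion
    sampling, cross-linked to the slot lists for O(1) removal;
  - per-collicular-cell contact counts ``ncc[j]`` for the competition term.

The activity pair sum for a contact (r, c) is truncated at the retinal
correlation cutoff: only contacts whose retinal cell lies in the precomputed
neighbour list of r contribute (CSR arrays ``nbr_ptr/nbr_idx/nbr_w`` with
``nbr_w = exp(-d_ret/a)``, self included with weight 1).  The collicular
kernel ``KC[c, c'] = exp(-d_coll/b)`` is a precomputed dense table, so a step
performs only table lookups.
"""

import numpy as np
from numba import njit

MAX_SLOTS = 64  # per-retinal-cell contact capacity (competition bounds the counts)


@njit(cache=True, inline="always")
def _act_sum(r, c, nbr_ptr, nbr_idx, nbr_w, KC, cols_by_ret, m):
    """Sum of K_ret(d_ret) * K_coll(d_coll) between (r, c) and all contacts
    whose retinal cell is within the retinal cutoff of r (includes contacts of
    r itself, and — when (r, c) exists — the contact's own self term KC[c,c]=1).
    """
    s = 0.0
    for t in range(nbr_ptr[r], nbr_ptr[r + 1]):
        i = nbr_idx[t]
        w = nbr_w[t]
        mi = m[i]
        for k in range(mi):
            s += w * KC[c, cols_by_ret[i, k]]
    return s


@njit(cache=True)
def _insert(r, c, cols_by_ret, g_by_slot, m, gret, gcol, gslot, ncc, n):
    slot = m[r]
    cols_by_ret[r, slot] = c
    g_by_slot[r, slot] = n
    gret[n] = r
    gcol[n] = c
    gslot[n] = slot
    m[r] += 1
    ncc[c] += 1
    return n + 1


@njit(cache=True)
def _remove(g, cols_by_ret, g_by_slot, m, gret, gcol, gslot, ncc, n):
    r = gret[g]
    c = gcol[g]
    slot = gslot[g]
    # per-retina list: move last slot into the hole
    last = m[r] - 1
    if slot != last:
        cols_by_ret[r, slot] = cols_by_ret[r, last]
        gm = g_by_slot[r, last]
        g_by_slot[r, slot] = gm
        gslot[gm] = slot
    m[r] = last
    ncc[c] -= 1
    # global list: move last entry into the hole
    lastg = n - 1
    if g != lastg:
        gret[g] = gret[lastg]
        gcol[g] = gcol[lastg]
        gslot[g] = gslot[lastg]
        g_by_slot[gret[g], gslot[g]] = g
    return lastg


@njit(cache=True)
def energy_full(ra, rb, ca, cb, nbr_ptr, nbr_idx, nbr_w, KC,
                cols_by_ret, g_by_slot, m, gret, gcol, gslot, ncc, n,
                alpha, beta, gamma_eff, comp_w):
    """Full energy of the current state (same truncation as the step kernel)."""
    e_chem = 0.0
    for g in range(n):
        e_chem += alpha * ra[gret[g]] * ca[gcol[g]] - beta * rb[gret[g]] * cb[gcol[g]]
    e_act = 0.0
    for g in range(n):
        r = gret[g]
        c = gcol[g]
        # pair sum including self term (subtracted below), halved for double count
        e_act += _act_sum(r, c, nbr_ptr, nbr_idx, nbr_w, KC, cols_by_ret, m) - 1.0
    e_act *= -0.5 * gamma_eff
    e_comp = 0.0
    for i in range(len(ra)):
        e_comp += (m[i] - 1.0) ** 2
    for j in range(len(ca)):
        e_comp += (ncc[j] - 1.0) ** 2
    e_comp *= 0.5 * comp_w
    return e_chem + e_act + e_comp


@njit(cache=True)
def run_mcmc(ra, rb, ca, cb, nbr_ptr, nbr_idx, nbr_w, KC,
             init_ret, init_col, iterations, seed,
             alpha, beta, gamma_eff, comp_w, temperature, trace_stride,
             activity_ramp):
    """TK2011 creation/deletion MCMC.

    Proposes creation (uniform over all cell pairs) or deletion (uniform over
    existing contact instances) with probability 1/2 each; accepts with the
    logistic rule 1/(1 + exp(dE/T)).  The activity weight grows linearly from
    zero to ``gamma_eff`` over the first ``activity_ramp`` fraction of the
    run (chemoaffinity establishes the coarse map before activity-dependent
    refinement sets in); the energy trace is reported under the full final
    weight.  Returns the final instance arrays, the running-energy trace and
    the final running energy.
    """
    nret = len(ra)
    ncoll = len(ca)
    cap = 24 * ncoll + len(init_ret)
    cols_by_ret = np.zeros((nret, MAX_SLOTS), dtype=np.int32)
    g_by_slot = np.zeros((nret, MAX_SLOTS), dtype=np.int32)
    m = np.zeros(nret, dtype=np.int32)
    ncc = np.zeros(ncoll, dtype=np.int32)
    gret = np.zeros(cap, dtype=np.int32)
    gcol = np.zeros(cap, dtype=np.int32)
    gslot = np.zeros(cap, dtype=np.int32)
    n = 0
    for k in range(len(init_ret)):
        if m[init_ret[k]] < MAX_SLOTS:
            n = _insert(init_ret[k], init_col[k], cols_by_ret, g_by_slot, m,
                        gret, gcol, gslot, ncc, n)

    e = energy_full(ra, rb, ca, cb, nbr_ptr, nbr_idx, nbr_w, KC,
                    cols_by_ret, g_by_slot, m, gret, gcol, gslot, ncc, n,
                    alpha, beta, gamma_eff, comp_w)
    np.random.seed(seed)
    ntrace = iterations // trace_stride + 1
    trace = np.empty(ntrace, dtype=np.float64)
    trace[0] = e
    tpos = 1
    ramp_end = max(1.0, activity_ramp * iterations)
    gamma_t = 0.0 if activity_ramp > 0 else gamma_eff
    for it in range(iterations):
        if activity_ramp > 0 and it < ramp_end:
            gamma_t = gamma_eff * it / ramp_end
        else:
            gamma_t = gamma_eff
        if np.random.random() < 0.5:
            # creation
            r = np.random.randint(nret)
            c = np.random.randint(ncoll)
            if m[r] < MAX_SLOTS and n < cap:
                s = _act_sum(r, c, nbr_ptr, nbr_idx, nbr_w, KC, cols_by_ret, m)
                de = (alpha * ra[r] * ca[c] - beta * rb[r] * cb[c]
                      - gamma_t * s
                      + comp_w * ((m[r] - 0.5) + (ncc[c] - 0.5)))
                if np.random.random() < 1.0 / (1.0 + np.exp(de / temperature)):
                    n = _insert(r, c, cols_by_ret, g_by_slot, m,
                                gret, gcol, gslot, ncc, n)
                    e += de
        else:
            # deletion (no-op on an empty contact set)
            if n > 0:
                g = np.random.randint(n)
                r = gret[g]
                c = gcol[g]
                s = _act_sum(r, c, nbr_ptr, nbr_idx, nbr_w, KC, cols_by_ret, m) - 1.0
                de = (-(alpha * ra[r] * ca[c] - beta * rb[r] * cb[c])
                      + gamma_t * s
                      + comp_w * ((1.5 - m[r]) + (1.5 - ncc[c])))
                if np.random.random() < 1.0 / (1.0 + np.exp(de / temperature)):
                    n = _remove(g, cols_by_ret, g_by_slot, m,
                                gret, gcol, gslot, ncc, n)
                    e += de
        if (it + 1) % trace_stride == 0 and tpos < ntrace:
            if activity_ramp > 0:
                # under a time-varying weight the incremental sum is not an
                # energy; log the exact energy at the full final weight
                trace[tpos] = energy_full(ra, rb, ca, cb, nbr_ptr, nbr_idx, nbr_w,
                                          KC, cols_by_ret, g_by_slot, m, gret,
                                          gcol, gslot, ncc, n,
                                          alpha, beta, gamma_eff, comp_w)
            else:
                trace[tpos] = e
            tpos += 1
    e_check = energy_full(ra, rb, ca, cb, nbr_ptr, nbr_idx, nbr_w, KC,
                          cols_by_ret, g_by_slot, m, gret, gcol, gslot, ncc, n,
                          alpha, beta, gamma_eff, comp_w)
    return gret[:n].copy(), gcol[:n].copy(), trace[:tpos], e, e_check


@njit(cache=True)
def run_exchange(ra, rb, ca, cb, nbr_ptr, nbr_idx, nbr_w, KC,
                 init_perm, iterations, seed,
                 alpha, beta, gamma_eff, temperature, trace_stride):
    """One-contact-per-cell MCMC (TK2006 variant).

    The state is a bijection ``perm[j] = retinal partner of collicular cell j``;
    moves exchange the retinal partners of two random collicular cells and are
    accepted with the same logistic rule.  No competition term is needed.
    """
    ncoll = len(ca)
    perm = init_perm.copy()
    inv = np.empty(ncoll, dtype=np.int32)  # retina -> colliculus
    for j in range(ncoll):
        inv[perm[j]] = j

    # full energy of the bijection
    e = 0.0
    for j in range(ncoll):
        i = perm[j]
        e += alpha * ra[i] * ca[j] - beta * rb[i] * cb[j]
    e_act = 0.0
    for j in range(ncoll):
        i = perm[j]
        for t in range(nbr_ptr[i], nbr_ptr[i + 1]):
            k = nbr_idx[t]
            if k != i:
                e_act += nbr_w[t] * KC[j, inv[k]]
    e += -0.5 * gamma_eff * e_act

    np.random.seed(seed)
    ntrace = iterations // trace_stride + 1
    trace = np.empty(ntrace, dtype=np.float64)
    trace[0] = e
    tpos = 1
    for it in range(iterations):
        j1 = np.random.randint(ncoll)
        j2 = np.random.randint(ncoll)
        if j1 == j2:
            continue
        i1 = perm[j1]
        i2 = perm[j2]
        de = (alpha * (ra[i1] - ra[i2]) * (ca[j2] - ca[j1])
              - beta * (rb[i1] - rb[i2]) * (cb[j2] - cb[j1]))
        s = 0.0
        for t in range(nbr_ptr[i1], nbr_ptr[i1 + 1]):
            k = nbr_idx[t]
            if k != i1 and k != i2:
                s += nbr_w[t] * (KC[j2, inv[k]] - KC[j1, inv[k]])
        for t in range(nbr_ptr[i2], nbr_ptr[i2 + 1]):
            k = nbr_idx[t]
            if k != i1 and k != i2:
                s += nbr_w[t] * (KC[j1, inv[k]] - KC[j2, inv[k]])
        de += -gamma_eff * s
        if np.random.random() < 1.0 / (1.0 + np.exp(de / temperature)):
            perm[j1] = i2
            perm[j2] = i1
            inv[i1] = j2
            inv[i2] = j1
            e += de
        if (it + 1) % trace_stride == 0 and tpos < ntrace:
            trace[tpos] = e
            tpos += 1
    return perm, trace[:tpos], e
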