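"""Numba inner loops for the lattice simulation.

The scheduler is an operator-split fixed-step scheme: the cell step is
chosen so the total per-cell event probability stays below PROB_CAP, each
cell draws at most one event per step (division / death / migration,
mutually exclusive), cells are processed in uniformly random order, and the
growth-factor field is advanced with explicit sub-steps in between.

Cells created or already acted upon within a step are stamped in ``acted``
so nothing moves or divides twice per step.
"""

import numpy as np
from numba import njit

PROB_CAP = 0.02

LONG = 0
SHORT = 1


@njit(cache=True)
def _gf_substeps(g, occ, D, rho, delta, spacing, dt):
    """Advance the field by dt with stable explicit sub-steps (mirror BC)."""
    n = g.shape[0]
    # joint diffusion+decay bound (checkerboard mode stays contractive)
    rate = 4.0 * D / (spacing * spacing) + delta
    bound = 1.0 / rate if rate > 0.0 else 1e300
    nsub = 1
    if bound < dt:
        nsub = int(np.ceil(dt / bound))
    sub = dt / nsub
    work = np.empty_like(g)
    inv_h2 = 1.0 / (spacing * spacing)
    for _ in range(nsub):
        for i in range(n):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n - 1 else n - 1
            for j in range(n):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < n - 1 else n - 1
                lap = (g[im, j] + g[ip, j] + g[i, jm] + g[i, jp] - 4.0 * g[i, j]) * inv_h2
                val = g[i, j] + sub * (D * lap + rho * occ[i, j] - delta * g[i, j])
                work[i, j] = val if val > 0.0 else 0.0
        g[:, :] = work[:, :]
    return g


@njit(cache=True)
def run_sim(
    occ,
    g,
    alpha,
    mu,
    nu,
    rho,
    delta,
    D,
    spacing,
    dispersal,
    T,
    record_every,
    seed,
    prob_cap,
):
    """Evolve the coupled cell/field system; returns (times, densities).

    occ : int8 N x N (modified in place), g : float64 N x N (in place).
    """
    np.random.seed(seed)
    N = occ.shape[0]
    total_sites = N * N

    n_cells = 0
    for i in range(N):
        for j in range(N):
            if occ[i, j] == 1:
                n_cells += 1

    # cell step from the capped per-cell event probability
    gmax = rho / delta if (delta > 0.0 and rho > 0.0) else 0.0
    max_rate = alpha * (1.0 + gmax) + mu + nu
    if max_rate > 0.0:
        dt = prob_cap / max_rate
    else:
        dt = T
    if dt > record_every:
        dt = record_every
    if dt > T:
        dt = T

    n_rec = int(np.floor(T / record_every + 1e-9)) + 1
    times = np.empty(n_rec)
    dens = np.empty(n_rec)
    times[0] = 0.0
    dens[0] = n_cells / total_sites
    rec = 1

    xs = np.empty(total_sites, dtype=np.int64)
    ys = np.empty(total_sites, dtype=np.int64)
    acted = np.full((N, N), -1, dtype=np.int64)

    t = 0.0
    step = 0
    while t < T - 1e-9:
        step += 1
        dt_eff = dt
        if t + dt_eff > T:
            dt_eff = T - t

        # snapshot occupied sites
        m = 0
        for i in range(N):
            for j in range(N):
                if occ[i, j] == 1:
                    xs[m] = i
                    ys[m] = j
                    m += 1
        # Fisher-Yates shuffle of the processing order
        for k in range(m - 1, 0, -1):
            r = np.random.randint(0, k + 1)
            xs[k], xs[r] = xs[r], xs[k]
            ys[k], ys[r] = ys[r], ys[k]

        for k in range(m):
            x = xs[k]
            y = ys[k]
            if occ[x, y] == 0 or acted[x, y] == step:
                continue  # died/moved already handled, or newborn/mover
            acted[x, y] = step
            p_div = alpha * (1.0 + g[x, y]) * dt_eff
            p_die = mu * dt_eff
            p_mig = nu * dt_eff
            u = np.random.random()
            if u < p_div:
                if dispersal == LONG:
                    tx = np.random.randint(0, N)
                    ty = np.random.randint(0, N)
                else:
                    direction = np.random.randint(0, 4)
                    tx = x
                    ty = y
                    if direction == 0:
                        tx = x - 1
                    elif direction == 1:
                        tx = x + 1
                    elif direction == 2:
                        ty = y - 1
                    else:
                        ty = y + 1
                if 0 <= tx < N and 0 <= ty < N and occ[tx, ty] == 0:
                    occ[tx, ty] = 1
                    acted[tx, ty] = step
                    n_cells += 1
            elif u < p_div + p_die:
                occ[x, y] = 0
                n_cells -= 1
            elif u < p_div + p_die + p_mig:
                direction = np.random.randint(0, 4)
                tx = x
                ty = y
                if direction == 0:
                    tx = x - 1
                elif direction == 1:
                    tx = x + 1
                elif direction == 2:
                    ty = y - 1
                else:
                    ty = y + 1
                if 0 <= tx < N and 0 <= ty < N and occ[tx, ty] == 0:
                    occ[x, y] = 0
                    occ[tx, ty] = 1
                    acted[tx, ty] = step
            # else: no event this step

        if rho > 0.0 or delta > 0.0 or D > 0.0:
            _gf_substeps(g, occ, D, rho, delta, spacing, dt_eff)

        t += dt_eff
        while rec < n_rec and t + 1e-9 >= times[0] + rec * record_every:
            times[rec] = rec * record_every
            dens[rec] = n_cells / total_sites
            rec += 1

    return times[:rec], dens[:rec]


@njit(cache=True)
def random_walk_msd(nu, spacing, n_walkers, T, n_record, seed):
    """MSD of isolated lattice random walkers hopping at total rate nu.

    Returns (times, msd) at n_record evenly spaced times; used to verify the
    nu = 4*D_c/spacing^2 correspondence.
    """
    np.random.seed(seed)
    dt = PROB_CAP / nu
    n_steps = int(np.ceil(T / dt))
    dt = T / n_steps
    p_hop = nu * dt
    rec_stride = max(1, n_steps // n_record)
    n_out = n_steps // rec_stride
    times = np.empty(n_out)
    msd = np.zeros(n_out)
    for w in range(n_walkers):
        x = 0.0
        y = 0.0
        idx = 0
        for s in range(1, n_steps + 1):
            if np.random.random() < p_hop:
                direction = np.random.randint(0, 4)
                if direction == 0:
                    x -= spacing
                elif direction == 1:
                    x += spacing
                elif direction == 2:
                    y -= spacing
                else:
                    y += spacing
            if s % rec_stride == 0 and idx < n_out:
                msd[idx] += x * x + y * y
                if w == 0:
                    times[idx] = s * dt
                idx += 1
    for i in range(n_out):
        msd[i] /= n_walkers
    return times, msd
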