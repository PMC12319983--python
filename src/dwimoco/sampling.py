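"""Multi-shell gradient scheme design.

Directions are placed by minimizing an antipodally symmetric Coulomb
(electrostatic-repulsion) energy that balances the angular uniformity of
each shell against that of the pooled direction set, and are then ordered
in time so that (i) unweighted volumes are interleaved evenly, (ii) every
temporal prefix respects the shell ratio to within one volume, and
(iii) consecutive same-shell directions are angularly far apart.  Any
temporal prefix of such an acquisition is therefore itself a usable,
approximately uniform multi-shell sample — the property that makes the
scheme motion-tolerant.
"""

from __future__ import annotations

import numpy as np

from .gradients import GradientScheme

__all__ = [
    "electrostatic_energy",
    "design_scheme",
    "order_incrementally",
    "DEGENERATE_ENERGY",
]

#: Energy reported for coincident/antipodal pairs instead of infinity, so
#: that local refinement can still escape degenerate configurations.
DEGENERATE_ENERGY = np.finfo(float).max

_EPS = 1e-12


def _pair_energy(dirs: np.ndarray) -> float:
    """Antipodal Coulomb energy sum_{i<j} 1/|u_i-u_j| + 1/|u_i+u_j|."""
    n = dirs.shape[0]
    if n < 2:
        return 0.0
    diff = np.linalg.norm(dirs[:, None, :] - dirs[None, :, :], axis=-1)
    summ = np.linalg.norm(dirs[:, None, :] + dirs[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    d, s = diff[iu], summ[iu]
    if np.any(d < _EPS) or np.any(s < _EPS):
        return DEGENERATE_ENERGY
    return float(np.sum(1.0 / d) + np.sum(1.0 / s))


def electrostatic_energy(directions_by_shell, global_weight: float = 0.5) -> float:
    """Convex combination of pooled and per-shell Coulomb energies.

    ``global_weight * E(pooled) + (1 - global_weight) * mean_shells E(shell)``
    with ``E(S) = sum_{i<j} 1/|u_i - u_j| + 1/|u_i + u_j|``.

    Parameters
    ----------
    directions_by_shell : sequence of (n_s, 3) arrays
        Unit directions, one array per shell.
    global_weight : float in [0, 1]
        Weight of the pooled-set term.

    Returns
    -------
    float
        Non-negative energy; :data:`DEGENERATE_ENERGY` if any pair is
        coincident or antipodal.
    """
    if not 0.0 <= global_weight <= 1.0:
        raise ValueError("global_weight must be in [0, 1]")
    shells = [np.asarray(s, dtype=float).reshape(-1, 3)
              for s in directions_by_shell]
    pooled = np.concatenate(shells, axis=0) if shells else np.empty((0, 3))
    e_glob = _pair_energy(pooled)
    e_shell = float(np.mean([_pair_energy(s) for s in shells])) if shells else 0.0
    if e_glob >= DEGENERATE_ENERGY or e_shell >= DEGENERATE_ENERGY:
        return DEGENERATE_ENERGY
    return global_weight * e_glob + (1.0 - global_weight) * e_shell


def _energy_gradient(shells: list[np.ndarray], global_weight: float) -> list[np.ndarray]:
    """Euclidean gradient of the combined energy w.r.t. each direction."""
    n_shells = len(shells)
    sizes = [s.shape[0] for s in shells]
    pooled = np.concatenate(shells, axis=0)

    def grad_set(dirs):
        diff = dirs[:, None, :] - dirs[None, :, :]
        summ = dirs[:, None, :] + dirs[None, :, :]
        dn = np.linalg.norm(diff, axis=-1)
        sn = np.linalg.norm(summ, axis=-1)
        np.fill_diagonal(dn, 1.0)
        dn = np.maximum(dn, 1e-9)
        sn = np.maximum(sn, 1e-9)
        g = -(diff / dn[..., None] ** 3).sum(axis=1) \
            - (summ / sn[..., None] ** 3).sum(axis=1)
        # self-pair (i==i): diff term zeroed by fill; summ term 2u/|2u|^3
        u = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        g += (2 * u) / 8.0  # remove the i==j antipodal self-interaction
        return g

    g_pool = grad_set(pooled)
    grads = []
    off = 0
    for k in range(n_shells):
        g = global_weight * g_pool[off:off + sizes[k]]
        if shells[k].shape[0] >= 2:
            g = g + (1.0 - global_weight) / n_shells * grad_set(shells[k])
        grads.append(g)
        off += sizes[k]
    return grads


def _refine(shells: list[np.ndarray], global_weight: float,
            n_iter: int = 200) -> list[np.ndarray]:
    """Projected gradient descent on the product of spheres."""
    shells = [s.copy() for s in shells]
    step = 1e-3
    e = electrostatic_energy(shells, global_weight)
    for _ in range(n_iter):
        grads = _energy_gradient(shells, global_weight)
        trial = []
        for s, g in zip(shells, grads):
            tang = g - (np.sum(g * s, axis=1, keepdims=True)) * s
            t = s - step * tang
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            trial.append(t)
        e_new = electrostatic_energy(trial, global_weight)
        if e_new < e:
            shells, e = trial, e_new
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-10:
                break
    return shells


def _random_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def design_scheme(n_b0: int, shells, global_weight: float = 0.5,
                  seed: int = 0, n_restarts: int = 20,
                  n_iter: int = 200) -> GradientScheme:
    """Design a multi-shell scheme by multi-start electrostatic refinement.

    Parameters
    ----------
    n_b0 : int
        Number of unweighted volumes, interleaved evenly in time.
    shells : list of (b, n_dirs)
        Shell b-values (s/mm^2) and direction counts.
    global_weight : float
        Pooled-vs-per-shell balance of the repulsion cost.
    seed : int
        Seed for the random restarts; the result is bit-reproducible.

    Returns
    -------
    GradientScheme
        ``n_b0 + sum(n_dirs)`` volumes with incremental temporal order
        (see :func:`order_incrementally`).
    """
    shells = [(float(b), int(n)) for b, n in shells]
    if n_b0 == 0 and not shells:
        raise ValueError("scheme must contain at least one volume")
    if any(n < 1 for _, n in shells):
        raise ValueError("each shell needs at least one direction")

    rng = np.random.default_rng(seed)
    best, best_e = None, np.inf
    counts = [n for _, n in shells]
    for _ in range(max(1, n_restarts)):
        init = [_random_sphere(n, rng) for n in counts]
        ref = _refine(init, global_weight, n_iter=n_iter) if counts else []
        e = electrostatic_energy(ref, global_weight) if counts else 0.0
        if e < best_e:
            best, best_e = ref, e
    b_values = [0.0] * n_b0
    directions = [np.zeros(3)] * n_b0
    for (b, _), dirs in zip(shells, best or []):
        for u in dirs:
            b_values.append(b)
            directions.append(u)
    scheme = GradientScheme(np.array(b_values), np.array(directions))
    return order_incrementally(scheme)


def _antipodal_angle(u: np.ndarray, vs: np.ndarray) -> np.ndarray:
    """Angle (radians) between u and each row of vs, folding antipodes."""
    c = np.clip(np.abs(vs @ u), -1.0, 1.0)
    return np.arccos(c)


def order_incrementally(scheme: GradientScheme) -> GradientScheme:
    """Assign a motion-tolerant temporal order to a designed scheme.

    b=0 volumes are spread evenly across the acquisition; diffusion-weighted
    slots alternate between shells so every prefix holds the shell ratio to
    within one volume, and within each shell the next direction is the one
    farthest (antipodal metric) from all directions of that shell already
    placed (greedy farthest-point).
    """
    n = len(scheme)
    if n == 1:
        return scheme
    b0_idx = np.flatnonzero(scheme.b0_mask)
    dw_idx = np.flatnonzero(~scheme.b0_mask)
    n_b0, n_dw = len(b0_idx), len(dw_idx)

    b0_slots = set(int(np.floor(k * n / n_b0)) for k in range(n_b0)) \
        if n_b0 else set()
    # floor collisions can merge slots for large n_b0/n; spread leftovers
    while len(b0_slots) < n_b0:
        for s in range(n):
            if s not in b0_slots:
                b0_slots.add(s)
                break

    shell_bs = scheme.shells
    shell_members = {b: list(np.flatnonzero(scheme.shell_mask(b) & ~scheme.b0_mask))
                     for b in shell_bs}
    shell_total = {b: len(shell_members[b]) for b in shell_bs}
    placed_count = {b: 0 for b in shell_bs}
    placed_dirs: dict[float, list[np.ndarray]] = {b: [] for b in shell_bs}
    remaining = {b: list(shell_members[b]) for b in shell_bs}

    order = []
    b0_iter = iter(b0_idx)
    t_dw = 0
    for slot in range(n):
        if slot in b0_slots:
            order.append(int(next(b0_iter)))
            continue
        # shell with the largest deficit against the running target ratio
        def deficit(b):
            target = (t_dw + 1) * shell_total[b] / n_dw
            return target - placed_count[b]
        avail = [b for b in shell_bs if remaining[b]]
        shell = max(avail, key=lambda b: (deficit(b), shell_total[b]))
        cand = remaining[shell]
        if placed_dirs[shell]:
            prev = np.array(placed_dirs[shell])
            scores = [
                _antipodal_angle(scheme.directions[i], prev).min()
                for i in cand
            ]
            pick = cand[int(np.argmax(scores))]
        else:
            pick = cand[0]
        cand.remove(pick)
        placed_dirs[shell].append(scheme.directions[pick])
        placed_count[shell] += 1
        order.append(int(pick))
        t_dw += 1
    return GradientScheme(
        scheme.b_values, scheme.directions, np.array(order), scheme.pe_axis
    )
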