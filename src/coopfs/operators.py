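"""Per-subpopulation search operators.

Three heterogeneous update rules act on disjoint slices of the population:

* exploration — differential donor steps plus Lévy flights and dimension-wise
  uniform mutation, for long-range moves;
* exploitation — contraction toward the global and subpopulation bests, with
  occasional Gaussian perturbation;
* balance — an equal blend of an exploratory increment and a best-directed
  increment, with moderate Gaussian noise.

All three share an elite pull ``lambda * (x_pbest - x)`` toward a member of
the top ``p_best`` fraction of the whole population, and all are followed by
clipping to the search box.  A bi-adaptive scale couples each group's base
step size to its recent success ratio and to the global progress schedule.

Every operator documents its random-draw order; tests trace them by
replaying an identically seeded generator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SubpopParams",
    "ScheduleState",
    "levy_step",
    "adaptive_scale",
    "explore_update",
    "exploit_update",
    "balance_update",
]

ROLE_DEFAULTS = {
    # role: (base_scale, perturb_prob)
    "exploration": (2.0, 0.3),
    "exploitation": (0.5, 0.1),
    "balance": (1.0, 0.2),
}


@dataclass(frozen=True)
class SubpopParams:
    """Tunable constants of one subpopulation's operator.

    base_scale : base differential weight F_k (2.0 / 0.5 / 1.0 for the
        exploration / exploitation / balance roles).
    perturb_prob : probability of the role's perturbation — dimension-wise
        uniform mutation for exploration (0.3), whole-vector Gaussian noise
        for exploitation (0.1) and balance (0.2).
    noise_scale : Gaussian noise scale sigma relative to the box width (0.05).
    levy_exponent : stability exponent beta of the Lévy steps (1.5).
    elite_pull : strength lambda of the attraction to a p-best elite (0.7).
    pbest_fraction : fraction of the population forming the elite pool (0.2).
    """

    role: str
    base_scale: float
    perturb_prob: float
    noise_scale: float = 0.05
    levy_exponent: float = 1.5
    elite_pull: float = 0.7
    pbest_fraction: float = 0.2

    def __post_init__(self):
        if self.base_scale <= 0:
            raise ValueError("base_scale must be positive")
        if not 0.0 <= self.perturb_prob <= 1.0:
            raise ValueError("perturb_prob must lie in [0, 1]")
        if not 1.0 < self.levy_exponent <= 2.0:
            raise ValueError("levy_exponent must lie in (1, 2]")

    @classmethod
    def for_role(cls, role: str, **overrides) -> "SubpopParams":
        if role not in ROLE_DEFAULTS:
            raise ValueError(f"unknown subpopulation role {role!r}")
        base, prob = ROLE_DEFAULTS[role]
        kw = dict(role=role, base_scale=base, perturb_prob=prob)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class ScheduleState:
    """Iteration-dependent control quantities.

    progress p = 1 - t/T_max decays linearly; the restart scale delta keeps a
    floor of 0.05 so late restarts still perturb; the local-search radius
    shrinks to zero as evolution completes.
    """

    iteration: int
    max_iterations: int
    local_radius_base: float = 0.12

    @property
    def progress(self) -> float:
        return 1.0 - self.iteration / self.max_iterations

    @property
    def restart_scale(self) -> float:
        return max(0.05, self.progress)

    @property
    def local_radius(self) -> float:
        return self.local_radius_base * self.progress


def _mantegna_sigma(beta: float) -> float:
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(n: int, beta: float, rng) -> np.ndarray:
    """Mantegna-style heavy-tailed step vector of length ``n``.

    ``s_j = u_j / |v_j|^(1/beta)`` with ``u_j ~ N(0, sigma_u^2)``,
    ``v_j ~ N(0, 1)`` and ``sigma_u`` the standard Mantegna scale for the
    stability exponent ``beta``.  Draw order: u (n normals), then v.
    """
    sigma_u = _mantegna_sigma(beta)
    u = rng.normal(0.0, sigma_u, n)
    v = rng.normal(0.0, 1.0, n)
    return u / np.abs(v) ** (1.0 / beta)


def adaptive_scale(base: float, success_ratio: float, t: int, t_max: int) -> float:
    """Bi-adaptive differential weight.

    ``F = base * (0.5 + 0.5 R) * (0.4 + 0.6 p)`` with ``p = 1 - t/T_max``:
    monotone increasing in the success ratio R and decreasing in t, bounded
    within [0.2 * base, base].
    """
    p = 1.0 - t / t_max
    return base * (0.5 + 0.5 * success_ratio) * (0.4 + 0.6 * p)


def _pick_donors(i: int, size: int, rng) -> tuple[int, int]:
    """Two donor indices from a subpopulation of ``size``, both != i and
    mutually distinct; if the group is too small, drawn with replacement."""
    others = [j for j in range(size) if j != i]
    if len(others) >= 2:
        r1, r2 = rng.choice(len(others), size=2, replace=False)
        return others[r1], others[r2]
    logger.debug("subpopulation of size %d: donors drawn with replacement", size)
    r1, r2 = rng.integers(0, size, size=2)
    return int(r1), int(r2)


def _pick_pbest(pbest_pool: np.ndarray, rng) -> np.ndarray:
    return pbest_pool[rng.integers(pbest_pool.shape[0])]


def explore_update(
    i: int,
    subpop: np.ndarray,
    pbest_pool: np.ndarray,
    scale: float,
    params: SubpopParams,
    lower: np.ndarray,
    upper: np.ndarray,
    rng,
    use_levy: bool = True,
) -> np.ndarray:
    """Exploration trial vector for member ``i`` of ``subpop``.

    ``v = x + F r (x_r1 - x_r2) + 0.5 F Levy(n) (x - x_pbest)
    + lambda (x_pbest - x)``, then each coordinate is reset to U(L_j, U_j)
    with probability ``perturb_prob``, then clipped.  The Lévy step is
    scaled element-wise by the displacement from the sampled elite (the
    usual Lévy-flight convention in this algorithm family), so jumps are
    landscape-scaled: large while the population is spread out, fine once
    it has contracted.  Draw order: donors, r, p-best index, Lévy (if on),
    mutation mask, replacement uniforms.
    """
    x = subpop[i]
    n = x.size
    j1, j2 = _pick_donors(i, subpop.shape[0], rng)
    r = rng.random(n)
    v = x + scale * r * (subpop[j1] - subpop[j2])
    pbest = _pick_pbest(pbest_pool, rng)
    if use_levy:
        v = v + 0.5 * scale * levy_step(n, params.levy_exponent, rng) * (x - pbest)
    v = v + params.elite_pull * (pbest - x)
    mut = rng.random(n) < params.perturb_prob
    if mut.any():
        v = v.copy()
        v[mut] = lower[mut] + rng.random(int(mut.sum())) * (upper[mut] - lower[mut])
    return np.clip(v, lower, upper)


def exploit_update(
    x: np.ndarray,
    x_best: np.ndarray,
    x_sub_best: np.ndarray,
    pbest_pool: np.ndarray,
    scale: float,
    params: SubpopParams,
    lower: np.ndarray,
    upper: np.ndarray,
    rng,
) -> np.ndarray:
    """Exploitation trial vector.

    ``v = x + F r (x_best - x) + 0.5 F (x_sub,best - x) + lambda (x_pbest - x)``;
    with probability ``perturb_prob`` a Gaussian ``N(0, sigma (U - L))`` is
    added per dimension; then clipping.  Draw order: r, p-best index,
    perturbation coin, noise vector.
    """
    n = x.size
    r = rng.random(n)
    pbest = _pick_pbest(pbest_pool, rng)
    v = (
        x
        + scale * r * (x_best - x)
        + 0.5 * scale * (x_sub_best - x)
        + params.elite_pull * (pbest - x)
    )
    if rng.random() < params.perturb_prob:
        v = v + rng.normal(0.0, params.noise_scale * (upper - lower))
    return np.clip(v, lower, upper)


def balance_update(
    i: int,
    subpop: np.ndarray,
    x_best: np.ndarray,
    pbest_pool: np.ndarray,
    scale: float,
    params: SubpopParams,
    lower: np.ndarray,
    upper: np.ndarray,
    rng,
    use_levy: bool = True,
) -> np.ndarray:
    """Balance trial vector: equal blend of an exploratory increment
    ``E = F r (x_r1 - x_r2) + F Levy(n) (x - x_pbest)`` and a best-directed
    increment ``D = F r' (x_best - x)``:

    ``v = x + E/2 + D/2 + lambda (x_pbest - x)``,

    followed by Gaussian noise with probability ``perturb_prob`` and
    clipping.  The Lévy step is elite-displacement-scaled as in
    :func:`explore_update`.  Draw order: donors, r (for E), p-best index,
    Lévy (if on), r' (for D), perturbation coin, noise vector.
    """
    x = subpop[i]
    n = x.size
    j1, j2 = _pick_donors(i, subpop.shape[0], rng)
    r_e = rng.random(n)
    e_inc = scale * r_e * (subpop[j1] - subpop[j2])
    pbest = _pick_pbest(pbest_pool, rng)
    if use_levy:
        e_inc = e_inc + scale * levy_step(n, params.levy_exponent, rng) * (x - pbest)
    r_d = rng.random(n)
    d_inc = scale * r_d * (x_best - x)
    v = x + 0.5 * e_inc + 0.5 * d_inc + params.elite_pull * (pbest - x)
    if rng.random() < params.perturb_prob:
        v = v + rng.normal(0.0, params.noise_scale * (upper - lower))
    return np.clip(v, lower, upper)
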