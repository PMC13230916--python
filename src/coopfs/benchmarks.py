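"""Shifted–rotated analytic benchmark functions for continuous-mode
validation.

Each objective has the form ``f(x) = base(M (x - o)) + bias`` with a random
orthogonal rotation ``M`` (QR of a seeded Gaussian matrix), a uniform shift
``o`` in [-80, 80]^D inside the [-100, 100] search box, and an additive
bias, so the optimum value ``f(o) = bias`` is known exactly.  The base
functions are sphere, Zakharov, Rosenbrock (optimum moved to the origin),
Rastrigin, and the expanded Schaffer F7 composed pairwise-cyclically over
consecutive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BenchmarkFunction", "make_function", "BASE_FUNCTIONS"]


def sphere(z):
    return float(np.sum(z * z))

def zakharov(z):
    s = 0.5 * np.arange(1, z.size + 1) * z
    t = float(np.sum(s))
    return float(np.sum(z * z)) + t**2 + t**4

def rosenbrock(z):
    # shifted so the optimum sits at z = 0
    z = z + 1.0
    return float(np.sum(100.0 * (z[:-1] ** 2 - z[1:]) ** 2 + (z[:-1] - 1.0) ** 2))

def rastrigin(z):
    return float(np.sum(z * z - 10.0 * np.cos(2.0 * np.pi * z) + 10.0))

def expanded_schaffer_f7(z):
    # cyclic pairs (z_i, z_{i+1}), wrapping the last to the first
    s = np.sqrt(z**2 + np.roll(z, -1) ** 2)
    g = np.sqrt(s) + np.sqrt(s) * np.sin(50.0 * s**0.2) ** 2
    return float(np.mean(g) ** 2)


BASE_FUNCTIONS = {
    "sphere": sphere,
    "zakharov": zakharov,
    "rosenbrock": rosenbrock,
    "rastrigin": rastrigin,
    "schaffer_f7_expanded": expanded_schaffer_f7,
}

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class BenchmarkFunction:
    """Callable shifted–rotated objective with known optimum ``bias``."""

    name: str
    base: str
    dimension: int
    shift: np.ndarray = field(repr=False)
    rotation: np.ndarray = field(repr=False)
    bias: float = 0.0
    bounds: tuple = (-100.0, 100.0)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (self.dimension, self.dimension):
            raise ValueError("rotation shape does not match dimension")
        if not np.allclose(R.T @ R, np.eye(self.dimension), atol=_ORTHO_TOL):
            raise ValueError("rotation matrix is not orthogonal")
        if self.base not in BASE_FUNCTIONS:
            raise ValueError(f"unknown base function {self.base!r}")

    def __call__(self, x) -> float:
        z = self.rotation @ (np.asarray(x, dtype=float) - self.shift)
        return BASE_FUNCTIONS[self.base](z) + self.bias


def _random_rotation(dim: int, rng) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(dim, dim)))
    return q * np.sign(np.diag(r))  # unique, det-stable orthogonal factor


def make_function(
    base: str,
    dimension: int,
    rng,
    bias: float = 0.0,
    shift_range: float = 80.0,
    rotate: bool = True,
) -> BenchmarkFunction:
    """Construct a shifted(-rotated) benchmark instance.

    The shift is uniform in [-shift_range, shift_range]^D and the rotation a
    seeded random orthogonal matrix (identity if ``rotate`` is false); the
    instance is fully determined by the generator state.
    """
    if base not in BASE_FUNCTIONS:
        raise ValueError(f"unknown base function {base!r}")
    shift = rng.uniform(-shift_range, shift_range, dimension)
    rotation = _random_rotation(dimension, rng) if rotate else np.eye(dimension)
    return BenchmarkFunction(
        name=f"{base}_{dimension}d",
        base=base,
        dimension=dimension,
        shift=shift,
        rotation=rotation,
        bias=float(bias),
    )
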