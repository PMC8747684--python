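"""Sampling from a multivariate Gaussian truncated to a polytope.

Candidate generation for the constrained optimizer needs draws from
N(mean, cov) restricted to {x : A x <= b}.  Naive rejection collapses on the
dose-capped treatment domain — the feasible fraction of the bounding box
shrinks like 1/d! with dimension — so the workhorse here is the exact
Hamiltonian Monte Carlo method for truncated Gaussians: in whitened
coordinates the potential is harmonic, positions follow
x(t) = x0 cos t + v0 sin t exactly, and each linear constraint is hit at
analytically computable times of a sinusoid.  The trajectory reflects the
velocity off each wall it meets and the position after a fixed travel time
is an exact sample — no discretization, no rejections, cost independent of
the feasible-volume fraction.

The plain rejection sampler is retained as the independent distributional
oracle for low-dimensional validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import linprog

from combopt.domain import FEASIBILITY_TOL, LinearConstraintSet

#: ignore wall-hit roots below this time to avoid re-hitting the wall just left
_HIT_GUARD = 1e-12
#: cap on reflections within one trajectory (defensive; typical counts are < 10)
_MAX_BOUNCES = 100_000


@dataclass(frozen=True)
class TruncatedGaussianSpec:
    """N(mean, covariance) restricted to constraints.A @ x <= constraints.b."""

    mean: NDArray[np.float64]
    covariance: NDArray[np.float64]
    constraints: LinearConstraintSet

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float).reshape(-1)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric (within 1e-10)")
        np.linalg.cholesky(cov)  # raises LinAlgError if not positive-definite
        if self.constraints.dim != mean.size:
            raise ValueError("constraint dimension does not match mean")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)


@dataclass(frozen=True)
class SamplerConfig:
    """Tuning for :func:`sample_truncated`.

    travel_time is the Hamiltonian trajectory length per emitted move
    (pi/2 — a quarter period of the harmonic dynamics — decorrelates well);
    burn_in moves are discarded before the first sample, thin moves are made
    between samples.  max_reject caps total trials for the rejection method.
    """

    method: str = "hmc"
    travel_time: float = math.pi / 2
    burn_in: int = 50
    thin: int = 1
    seed: int | None = None
    max_reject: int = 2_000_000

    def __post_init__(self):
        if self.method not in ("hmc", "rejection"):
            raise ValueError(f"unknown sampler method {self.method!r}")
        if self.travel_time <= 0:
            raise ValueError("travel_time must be positive")
        if self.burn_in < 0 or self.thin < 1:
            raise ValueError("burn_in >= 0 and thin >= 1 required")


def find_interior_point(cons: LinearConstraintSet) -> NDArray[np.float64]:
    """A strictly feasible point: the Chebyshev center of the polytope.

    Maximizes the inradius r subject to A x + r ||a_i|| <= b; raises if the
    region has empty interior (r <= 0) or the LP fails.
    """
    norms = np.linalg.norm(cons.A, axis=1)
    D = cons.dim
    # variables (x, r); maximize r == minimize -r
    A_ub = np.hstack([cons.A, norms[:, None]])
    c = np.zeros(D + 1)
    c[-1] = -1.0
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=cons.b,
        bounds=[(None, None)] * D + [(None, None)],
        method="highs",
    )
    if not res.success:
        raise ValueError(f"could not locate an interior point: {res.message}")
    x, r = res.x[:-1], res.x[-1]
    if r <= FEASIBILITY_TOL:
        raise ValueError("feasible region has no interior (inradius <= 0)")
    return x


def _strictify(
    x: NDArray[np.float64], cons: LinearConstraintSet, slack: float = 1e-10
) -> NDArray[np.float64]:
    """Pull a feasible-but-boundary point slightly toward the Chebyshev
    center so the Hamiltonian trajectory starts strictly inside."""
    if np.all(cons.A @ x <= cons.b - slack):
        return x
    center = find_interior_point(cons)
    for frac in (1e-6, 1e-4, 1e-2, 0.1, 0.5, 1.0):
        cand = (1 - frac) * x + frac * center
        if np.all(cons.A @ cand <= cons.b - slack):
            return cand
    raise ValueError("no strictly feasible start point could be constructed")


def _hmc_move(
    x: NDArray[np.float64],
    G: NDArray[np.float64],
    c: NDArray[np.float64],
    gram: NDArray[np.float64],
    travel_time: float,
    rng: np.random.Generator,
    energy_log: list | None = None,
) -> NDArray[np.float64]:
    """One exact-HMC move in whitened coordinates (standard normal target,
    feasible set G x <= c).  Returns the end position after travel_time."""
    v = rng.standard_normal(x.size)
    remaining = travel_time
    for _ in range(_MAX_BOUNCES):
        gx = G @ x
        gv = G @ v
        u = np.hypot(gx, gv)
        phi = np.arctan2(gv, gx)
        # hit times of u cos(t - phi) = c, smallest positive root per wall
        with np.errstate(invalid="ignore", divide="ignore"):
            acos = np.arccos(np.clip(c / u, -1.0, 1.0))
        reachable = u >= np.abs(c)
        t1 = np.mod(phi + acos, 2 * math.pi)
        t2 = np.mod(phi - acos, 2 * math.pi)
        t1 = np.where(reachable & (t1 > _HIT_GUARD), t1, np.inf)
        t2 = np.where(reachable & (t2 > _HIT_GUARD), t2, np.inf)
        hit_times = np.minimum(t1, t2)
        j = int(np.argmin(hit_times))
        t_hit = hit_times[j]
        if t_hit >= remaining:
            ct, st = math.cos(remaining), math.sin(remaining)
            return x * ct + v * st
        ct, st = math.cos(t_hit), math.sin(t_hit)
        x, v = x * ct + v * st, -x * st + v * ct
        if energy_log is not None:
            h_before = 0.5 * float(x @ x + v @ v)
        g = G[j]
        v = v - (2.0 * (g @ v) / gram[j]) * g
        if energy_log is not None:
            energy_log.append((h_before, 0.5 * float(x @ x + v @ v)))
        remaining -= t_hit
    raise RuntimeError("exceeded maximum reflections in one HMC trajectory")


def sample_truncated(
    spec: TruncatedGaussianSpec,
    n: int,
    cfg: SamplerConfig | None = None,
    start: NDArray[np.float64] | None = None,
    rng: np.random.Generator | None = None,
    diagnostics: dict | None = None,
) -> NDArray[np.float64]:
    """Draw n samples from the truncated Gaussian.

    Parameters
    ----------
    start : optional strictly feasible chain start (original coordinates) for
        the hmc method; defaults to the polytope's Chebyshev center.  The
        Gaussian mean itself need not be feasible.
    rng : optional generator overriding ``cfg.seed`` (used by the optimizer
        to keep one reproducible stream across iterations).
    diagnostics : optional dict; the hmc method records per-bounce
        Hamiltonian energies under ``"energy"`` as an (n_bounces, 2) array.

    Returns an (n, D) matrix; every row satisfies the constraints.
    """
    cfg = cfg or SamplerConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cons = spec.constraints
    if cfg.method == "rejection":
        return _sample_rejection(spec, n, cfg, rng)

    L = cholesky(spec.covariance, lower=True)
    # whitened feasible set: G y <= c_off, y standard normal
    G = cons.A @ L
    c_off = cons.b - cons.A @ spec.mean
    gram = np.einsum("ij,ij->i", G, G)
    if start is None:
        start = find_interior_point(cons)
    start = _strictify(np.asarray(start, dtype=float).reshape(-1), cons)
    y = solve_triangular(L, start - spec.mean, lower=True)
    energy_log: list | None = [] if diagnostics is not None else None

    out = np.empty((n, cons.dim))
    emitted = 0
    moves_until_emit = cfg.burn_in + 1
    while emitted < n:
        y = _hmc_move(y, G, c_off, gram, cfg.travel_time, rng, energy_log)
        moves_until_emit -= 1
        if moves_until_emit == 0:
            out[emitted] = spec.mean + L @ y
            emitted += 1
            moves_until_emit = cfg.thin
    if diagnostics is not None:
        diagnostics["energy"] = np.asarray(energy_log).reshape(-1, 2)
    # exact dynamics keep the chain inside; guard against float drift anyway
    viol = cons.A @ out.T - cons.b[:, None]
    if viol.max(initial=-np.inf) > FEASIBILITY_TOL:
        raise RuntimeError("HMC emitted an infeasible sample beyond tolerance")
    return out


def _sample_rejection(
    spec: TruncatedGaussianSpec,
    n: int,
    cfg: SamplerConfig,
    rng: np.random.Generator,
) -> NDArray[np.float64]:
    cons = spec.constraints
    L = cholesky(spec.covariance, lower=True)
    out = []
    trials = 0
    batch = max(4 * n, 256)
    while sum(len(o) for o in out) < n:
        if trials >= cfg.max_reject:
            raise RuntimeError(
                f"rejection sampler exhausted {cfg.max_reject} trials; the "
                "feasible volume under this Gaussian is too small — use hmc"
            )
        z = rng.standard_normal((batch, cons.dim))
        ys = spec.mean + z @ L.T
        ok = np.all(cons.A @ ys.T <= cons.b[:, None] + FEASIBILITY_TOL, axis=0)
        out.append(ys[ok])
        trials += batch
    return np.concatenate(out)[:n]
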