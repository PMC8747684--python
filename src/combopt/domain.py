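"""Treatment vectors and the dose-capped treatment domain.

A single-step treatment is a vector tau of per-drug concentrations in nM.
The admissible domain is

    T = { tau >= 0 : ||tau||_1 <= alpha },

a box-corner simplex whose total dose is capped at ``alpha`` (default
8000 nM, the maximal total concentration in the calibration data of the
upstream response model).  Sequential plans of ``n_steps`` treatments live
in the Cartesian power T^n, with the cap applied per step.

Internally the optimizer works in normalized coordinates x = tau / alpha, so
every step lives in the unit simplex-capped box and an O(1) step size is
meaningful; results are converted back to nM for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

DEFAULT_ALPHA_NM = 8000.0
DEFAULT_DRUG_NAMES = [
    "PLX-4720",
    "PD0325901",
    "CHIR-265",
    "Erlotinib",
    "Lapatinib",
    "drug6",
    "drug7",
]
FEASIBILITY_TOL = 1e-9


def _default_names(d: int) -> list[str]:
    if d <= len(DEFAULT_DRUG_NAMES):
        return DEFAULT_DRUG_NAMES[:d]
    extra = [f"drug{i + 1}" for i in range(len(DEFAULT_DRUG_NAMES), d)]
    return DEFAULT_DRUG_NAMES + extra


@dataclass(frozen=True)
class TreatmentVector:
    """Per-drug concentrations (nM); the decision variable tau."""

    doses: NDArray[np.float64]

    def __init__(self, doses: ArrayLike):
        arr = np.asarray(doses, dtype=float).reshape(-1)
        if arr.size < 1:
            raise ValueError("a treatment needs at least one drug")
        if np.any(arr < 0):
            raise ValueError("drug concentrations must be nonnegative")
        arr.setflags(write=False)
        object.__setattr__(self, "doses", arr)

    @property
    def d(self) -> int:
        return self.doses.size

    @property
    def total_dose(self) -> float:
        return float(self.doses.sum())

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.doses, dtype=dtype)


@dataclass(frozen=True)
class TreatmentSpace:
    """The dose-capped domain T (and its n-step Cartesian power T^n).

    Parameters
    ----------
    d : number of drugs (default 7).
    alpha : total-dose cap per treatment step, in nM (default 8000).
    n_steps : plan length; 1 for single-step treatments.
    drug_names : labels for the d drugs.
    """

    d: int = 7
    alpha: float = DEFAULT_ALPHA_NM
    n_steps: int = 1
    drug_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not self.drug_names:
            object.__setattr__(self, "drug_names", _default_names(self.d))
        if len(self.drug_names) != self.d:
            raise ValueError(
                f"drug_names has length {len(self.drug_names)}, expected {self.d}"
            )

    @property
    def dim(self) -> int:
        """Flat dimension D = d * n_steps of the search space."""
        return self.d * self.n_steps

    def even_split(self, normalized: bool = False) -> NDArray[np.float64]:
        """The treatment splitting the full cap evenly across the d drugs,
        replicated over all steps (the optimizer's default initial mean)."""
        per_drug = 1.0 / self.d if normalized else self.alpha / self.d
        return np.full(self.dim, per_drug)

    def to_plan(self, x: ArrayLike, normalized: bool = False) -> "SequentialPlan":
        """Reshape a flat coordinate vector into a SequentialPlan (in nM)."""
        arr = np.asarray(x, dtype=float).reshape(self.n_steps, self.d)
        if normalized:
            arr = arr * self.alpha
        return SequentialPlan([TreatmentVector(row) for row in arr])


@dataclass(frozen=True)
class SequentialPlan:
    """An ordered sequence of treatments (tau_1, ..., tau_n) in T^n."""

    steps: list[TreatmentVector]

    def __post_init__(self):
        if not self.steps:
            raise ValueError("a plan needs at least one step")
        d0 = self.steps[0].d
        if any(s.d != d0 for s in self.steps):
            raise ValueError("all steps must have the same drug count")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def d(self) -> int:
        return self.steps[0].d

    def flatten(self) -> NDArray[np.float64]:
        return np.concatenate([s.doses for s in self.steps])

    def total_dose(self) -> float:
        return float(sum(s.total_dose for s in self.steps))


@dataclass(frozen=True)
class LinearConstraintSet:
    """Feasibility as A @ x <= b.

    Rows encode -x_j <= 0 for every coordinate plus one per-step total-dose
    cap, so m = D + n_steps for a d-drug, n-step space.
    """

    A: NDArray[np.float64]
    b: NDArray[np.float64]

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        b = np.asarray(self.b, dtype=float).reshape(-1)
        if A.ndim != 2 or A.shape[0] != b.size:
            raise ValueError("A and b have incompatible shapes")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    @property
    def m(self) -> int:
        return self.b.size

    @property
    def dim(self) -> int:
        return self.A.shape[1]


def build_constraints(
    space: TreatmentSpace, normalized: bool = True
) -> LinearConstraintSet:
    """Linear-inequality representation of T^n.

    With ``normalized`` the coordinates are tau/alpha and every per-step cap
    is 1; otherwise coordinates are nM and caps are alpha.  Returns exactly
    D + n_steps inequalities (D nonnegativity rows, one sum cap per step).
    """
    D = space.dim
    cap = 1.0 if normalized else space.alpha
    A = np.zeros((D + space.n_steps, D))
    A[:D, :] = -np.eye(D)
    for s in range(space.n_steps):
        A[D + s, s * space.d : (s + 1) * space.d] = 1.0
    b = np.concatenate([np.zeros(D), np.full(space.n_steps, cap)])
    return LinearConstraintSet(A, b)


def is_feasible(
    x: ArrayLike, cons: LinearConstraintSet, tol: float = FEASIBILITY_TOL
) -> bool:
    """True iff A @ x <= b + tol elementwise."""
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != cons.dim:
        raise ValueError(f"point has dimension {arr.size}, constraints expect {cons.dim}")
    return bool(np.all(cons.A @ arr <= cons.b + tol))


def feasible_volume_fraction(
    d: int, n_samples: int, seed: int | None = None
) -> float:
    """Monte-Carlo estimate of vol(T) / vol([0, alpha]^d).

    Draws uniform points in the axis-aligned cube and returns the fraction
    whose coordinate sum is below the cap.  The exact value is 1/d! (the
    cap-simplex has volume alpha^d / d!), which is why rejection sampling
    collapses as d grows.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if d == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    # scale-free: work on the unit cube against the unit simplex
    hits = 0
    remaining = n_samples
    while remaining > 0:
        batch = min(remaining, 1_000_000)
        u = rng.random((batch, d))
        hits += int(np.count_nonzero(u.sum(axis=1) <= 1.0))
        remaining -= batch
    return hits / n_samples
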