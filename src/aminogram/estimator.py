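"""Inverse estimation of blood composition from the hydrolysis ratio W.

A single pair of ninhydrin readings (F before hydrolysis, T after) pins
down only the ratio ``W = T / F``.  Normalising to F = 1, the balance
equations leave a two-parameter family of compositions consistent with any
given W:

* ``alpha`` — fraction of dipeptides carrying extra (side-chain) amine
  groups, with the surplus split evenly between the 2- and 3-amine classes
  (``x2 = x3``); bounded by 0.3, the two-amine share of the residue
  alphabet.
* ``beta`` — the same fraction for tripeptides (``y2 = y3 = y4``), also
  bounded by 0.3.
* ``A`` — the free-amino-acid amine-group equivalents, confined to an
  interval [A_lo, A_hi] depending on (alpha, beta, W) by the requirement
  that the dipeptide and tripeptide totals x, y be non-negative.

Absent further information, every composition in this feasible set is
treated as equally probable, and the reported "mean structure" is the
expectation of the before- and after-hydrolysis share triples under the
uniform distribution on the 3-D set.  Two interchangeable integrators are
provided: a deterministic nested quadrature (closed-form inner average
over A, midpoint rule over alpha and beta, cells weighted by the A-interval
length) and a rejection Monte-Carlo sampler, which serves as an
independent cross-check.

W below 1 or above 3 cannot arise from the model (W = 1 is pure free
amino acids; W = 3 the single-amine-tripeptide ceiling), so out-of-range
ratios are clamped under an explicit, flag-raising policy: sub-unity W is
attributed to assay noise, W above 3 signals peptides longer than three
residues, which the model deliberately excludes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .amine_model import AmineReadings, Composition

__all__ = [
    "WPolicy",
    "FeasiblePoint",
    "MeanStructure",
    "ReadingSplit",
    "w_ratio",
    "a_bounds",
    "solve_xy",
    "feasible_point",
    "shares_at_point",
    "mean_structure",
    "decompose_reading",
    "legacy_free_fraction",
    "FLAG_SUB_UNITY_W",
    "FLAG_LONGER_PEPTIDES",
    "FLAG_UNDEFINED_W",
]

FLAG_SUB_UNITY_W = "W<1 clamped to 1 (T below F; assay noise)"
FLAG_LONGER_PEPTIDES = "W>3 clamped to 3 (possible peptides longer than tripeptides)"
FLAG_UNDEFINED_W = "W undefined (F adjusted to 0); point contributes nothing"

ALPHA_MAX_DEFAULT = 0.3
BETA_MAX_DEFAULT = 0.3


@dataclass(frozen=True)
class WPolicy:
    """How to treat hydrolysis ratios outside the model range [1, 3]."""

    w_min: float = 1.0
    w_max: float = 3.0
    below_min_action: str = "clamp"  # "clamp" | "error"
    above_max_action: str = "clamp"  # "clamp" | "error"

    def __post_init__(self) -> None:
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be < w_max")
        for name in ("below_min_action", "above_max_action"):
            if getattr(self, name) not in ("clamp", "error"):
                raise ValueError(f"{name} must be 'clamp' or 'error'")


DEFAULT_POLICY = WPolicy()


def w_ratio(
    readings: AmineReadings, policy: WPolicy = DEFAULT_POLICY
) -> tuple[float, list[str]]:
    """Hydrolysis ratio W = T / F with the range policy applied.

    Returns the (possibly clamped) ratio and the list of flags raised.
    Flags are never dropped: callers must propagate them to output tables.
    """
    if not (math.isfinite(readings.F) and math.isfinite(readings.T)):
        raise ValueError(f"non-finite readings F={readings.F}, T={readings.T}")
    if readings.F <= 0:
        raise ValueError(f"F must be > 0 to form W = T/F, got F={readings.F}")
    W = readings.T / readings.F
    flags: list[str] = []
    if W < policy.w_min:
        if policy.below_min_action == "error":
            raise ValueError(f"W={W:.4g} below model minimum {policy.w_min}")
        W = policy.w_min
        flags.append(FLAG_SUB_UNITY_W)
    elif W > policy.w_max:
        if policy.above_max_action == "error":
            raise ValueError(f"W={W:.4g} above model maximum {policy.w_max}")
        W = policy.w_max
        flags.append(FLAG_LONGER_PEPTIDES)
    return W, flags


def _check_w(W: float) -> None:
    if not (1.0 <= W <= 3.0):
        raise ValueError(
            f"W={W} outside [1, 3]; apply a WPolicy (w_ratio) before estimating"
        )


def a_bounds(alpha, beta, W):
    """Feasible interval [A_lo, A_hi] of the free-amino-acid count.

    A_lo = max(1 − (1 + 1.5·alpha)(W − 1), 0)   (tripeptide total y ≥ 0)
    A_hi = 1 − (1 + 2·beta)(W − 1)/2            (dipeptide total x ≥ 0)

    An (alpha, beta) cell with A_lo > A_hi is infeasible (empty interval).
    Accepts scalars or numpy arrays.
    """
    W_arr = np.asarray(W, dtype=float)
    if np.any(W_arr < 1.0) or np.any(W_arr > 3.0):
        raise ValueError(f"W outside [1, 3]: apply a WPolicy first (got {W})")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    A_lo = np.maximum(1.0 - (1.0 + 1.5 * alpha) * (W_arr - 1.0), 0.0)
    A_hi = 1.0 - (1.0 + 2.0 * beta) * (W_arr - 1.0) / 2.0
    if A_lo.ndim == 0:
        return float(A_lo), float(A_hi)
    return A_lo, A_hi


def solve_xy(A, alpha, beta, W):
    """Dipeptide and tripeptide totals (x, y) for a point of the feasible set.

        x = [1 − A − (1 + 2·beta)(W − 1)/2] / [0.5 + 1.5·alpha − beta]
        y = (W − 1 − x)/2

    The denominator is bounded below by 0.2 on the (alpha, beta) box.
    Values within −1e−12 of zero are clipped to exactly 0.
    """
    scalar = np.isscalar(A) or np.asarray(A).ndim == 0
    A = np.asarray(A, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    W = np.asarray(W, dtype=float)
    A_lo, A_hi = a_bounds(alpha, beta, W)
    tol = 1e-12
    bad_lo = A < np.asarray(A_lo) - tol
    bad_hi = A > np.asarray(A_hi) + tol
    if np.any(bad_lo) or np.any(bad_hi):
        if np.any(bad_hi):
            raise ValueError(
                "A above upper bound 1 - (1+2*beta)(W-1)/2: dipeptide total x "
                "would be negative"
            )
        raise ValueError(
            "A below lower bound max(1-(1+1.5*alpha)(W-1), 0): tripeptide "
            "total y would be negative"
        )
    denom = 0.5 + 1.5 * alpha - beta
    x = (1.0 - A - (1.0 + 2.0 * beta) * (W - 1.0) / 2.0) / denom
    y = (W - 1.0 - x) / 2.0
    x = np.where(np.abs(x) < tol, 0.0, x)
    y = np.where(np.abs(y) < tol, 0.0, y)
    x = np.clip(x, 0.0, None)
    y = np.clip(y, 0.0, None)
    if scalar:
        return float(x), float(y)
    return x, y


@dataclass(frozen=True)
class FeasiblePoint:
    """One composition consistent with a given W, in F = 1 normalised units."""

    W: float
    alpha: float
    beta: float
    A: float
    x: float = field(init=False)
    y: float = field(init=False)

    def __post_init__(self) -> None:
        _check_w(self.W)
        if not (0.0 <= self.alpha <= ALPHA_MAX_DEFAULT):
            raise ValueError(f"alpha={self.alpha} outside [0, {ALPHA_MAX_DEFAULT}]")
        if not (0.0 <= self.beta <= BETA_MAX_DEFAULT):
            raise ValueError(f"beta={self.beta} outside [0, {BETA_MAX_DEFAULT}]")
        x, y = solve_xy(self.A, self.alpha, self.beta, self.W)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def to_composition(self) -> Composition:
        """Expand into explicit class abundances per the even-split convention."""
        return Composition(
            A=self.A,
            x1=(1.0 - self.alpha) * self.x,
            x2=self.alpha * self.x / 2.0,
            x3=self.alpha * self.x / 2.0,
            y1=(1.0 - self.beta) * self.y,
            y2=self.beta * self.y / 3.0,
            y3=self.beta * self.y / 3.0,
            y4=self.beta * self.y / 3.0,
        )


def feasible_point(W: float, alpha: float, beta: float, A: float) -> FeasiblePoint:
    """Construct and validate a point of the feasible set."""
    return FeasiblePoint(W=W, alpha=alpha, beta=beta, A=A)


def shares_at_point(p: FeasiblePoint) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Before- and after-hydrolysis share triples at one feasible point.

    Before (shares of F = 1): dipeptides show x·(1 + 1.5·alpha) intact
    amine groups, tripeptides y·(1 + 2·beta).  After (shares of T = W):
    hydrolysis adds x groups from dipeptides and 2y from tripeptides.
    Both triples sum to 1 by construction.
    """
    before = (p.A, p.x * (1.0 + 1.5 * p.alpha), p.y * (1.0 + 2.0 * p.beta))
    after_raw = (p.A, p.x * (2.0 + 1.5 * p.alpha), p.y * (3.0 + 2.0 * p.beta))
    after = tuple(v / p.W for v in after_raw)
    return before, after


@dataclass(frozen=True)
class MeanStructure:
    """Uniform-average composition shares for a fixed hydrolysis ratio W.

    ``a_star, x_star, y_star`` are the mean shares of the pre-hydrolysis
    signal F attributed to free amino acids, dipeptides and tripeptides;
    ``a_prime, x_prime, y_prime`` the mean shares of the post-hydrolysis
    signal T (free, dipeptide-derived, tripeptide-derived amino acids).
    """

    W: float
    a_star: float
    x_star: float
    y_star: float
    a_prime: float
    x_prime: float
    y_prime: float
    method: str
    n: int
    seed: int | None = None

    @property
    def before(self) -> tuple[float, float, float]:
        return (self.a_star, self.x_star, self.y_star)

    @property
    def after(self) -> tuple[float, float, float]:
        return (self.a_prime, self.x_prime, self.y_prime)


def _shares_arrays(A, alpha, beta, W):
    """Vectorised share triples; returns (before 3-tuple, after 3-tuple) of arrays."""
    x, y = solve_xy(A, alpha, beta, W)
    b = (A, x * (1.0 + 1.5 * alpha), y * (1.0 + 2.0 * beta))
    a = (A / W, x * (2.0 + 1.5 * alpha) / W, y * (3.0 + 2.0 * beta) / W)
    return b, a


def _mean_structure_quadrature(
    W: float, resolution: int, alpha_max: float, beta_max: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Midpoint-rule average over (alpha, beta), closed-form inner mean over A.

    Every share is affine in A at fixed (alpha, beta), so the uniform
    average over [A_lo, A_hi] equals the value at the interval midpoint;
    cells are weighted by the interval length, which is the conditional
    measure of the 3-D set.

    As W approaches 3 the feasible beta range shrinks like (3 - W); the
    beta grid is restricted to that range (zero-weight territory is
    dropped, leaving the uniform measure unchanged) so the quadrature
    stays resolved arbitrarily close to the endpoint.
    """
    beta_hi = beta_max
    if W > 2.0:
        # A_hi >= 0 requires beta <= (2/(W-1) - 1)/2
        beta_hi = min(beta_max, (2.0 / (W - 1.0) - 1.0) / 2.0)
    edges_a = np.linspace(0.0, alpha_max, resolution + 1)
    edges_b = np.linspace(0.0, beta_hi, resolution + 1)
    mid_a = 0.5 * (edges_a[:-1] + edges_a[1:])
    mid_b = 0.5 * (edges_b[:-1] + edges_b[1:])
    alpha, beta = np.meshgrid(mid_a, mid_b, indexing="ij")
    A_lo, A_hi = a_bounds(alpha, beta, W)
    weight = np.clip(A_hi - A_lo, 0.0, None)
    total = weight.sum()
    if total <= 0.0:
        raise RuntimeError(
            f"empty feasible set at W={W}; degenerate endpoints are handled "
            "analytically upstream"
        )
    feas = weight > 0.0
    A_mid = 0.5 * (A_lo + A_hi)
    # restrict to feasible cells to keep solve_xy's bound check happy
    b, a = _shares_arrays(A_mid[feas], alpha[feas], beta[feas], W)
    w = weight[feas] / total
    before = np.array([float(np.sum(c * w)) for c in b])
    after = np.array([float(np.sum(c * w)) for c in a])
    return before, after, int(feas.sum())


def _mean_structure_mc(
    W: float, n_samples: int, seed: int, alpha_max: float, beta_max: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Rejection sampler: uniform proposals on the (alpha, beta, A) box,
    accepted iff A lies in the feasible interval."""
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(0.0, alpha_max, n_samples)
    beta = rng.uniform(0.0, beta_max, n_samples)
    A = rng.uniform(0.0, 1.0, n_samples)
    A_lo, A_hi = a_bounds(alpha, beta, W)
    keep = (A >= A_lo) & (A <= A_hi)
    n_acc = int(keep.sum())
    if n_acc == 0:
        raise RuntimeError(
            f"rejection sampler accepted 0 of {n_samples} proposals at W={W}; "
            "increase n_samples or use quadrature"
        )
    b, a = _shares_arrays(A[keep], alpha[keep], beta[keep], W)
    before = np.array([float(np.mean(c)) for c in b])
    after = np.array([float(np.mean(c)) for c in a])
    return before, after, n_acc


def mean_structure(
    W: float,
    method: str = "quadrature",
    resolution: int = 400,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    alpha_max: float = ALPHA_MAX_DEFAULT,
    beta_max: float = BETA_MAX_DEFAULT,
) -> MeanStructure:
    """Expected before/after-hydrolysis shares under the uniform-on-set prior.

    Parameters
    ----------
    W
        Hydrolysis ratio in [1, 3] (apply :func:`w_ratio` first for raw data).
    method
        ``"quadrature"`` (deterministic, default) or ``"mc"`` (rejection
        sampling; requires an explicit ``seed``).
    resolution
        Quadrature grid size per axis (default 400, giving share error
        well below 0.005).
    n_samples
        Number of Monte-Carlo proposals (default 1e6).
    seed
        Mandatory for ``method="mc"``; ignored by quadrature.

    Notes
    -----
    At the endpoints W = 1 and W = 3 the feasible set degenerates to
    zero 3-D measure (pure free amino acids and pure single-amine
    tripeptides respectively); the exact limit structures are returned.
    """
    _check_w(W)
    if W == 1.0:
        return MeanStructure(W, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, "exact-limit", 0, seed)
    if W == 3.0:
        return MeanStructure(W, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0, "exact-limit", 0, seed)
    if method == "quadrature":
        before, after, n = _mean_structure_quadrature(W, resolution, alpha_max, beta_max)
    elif method == "mc":
        if seed is None:
            raise ValueError("method='mc' requires an explicit seed")
        before, after, n = _mean_structure_mc(W, n_samples, seed, alpha_max, beta_max)
    else:
        raise ValueError(f"unknown method {method!r}; use 'quadrature' or 'mc'")
    return MeanStructure(
        W,
        a_star=before[0], x_star=before[1], y_star=before[2],
        a_prime=after[0], x_prime=after[1], y_prime=after[2],
        method=method, n=n, seed=seed if method == "mc" else None,
    )


@dataclass(frozen=True)
class ReadingSplit:
    """Absolute after-hydrolysis attribution of one reading (units of T)."""

    free: float
    dipeptide_derived: float
    tripeptide_derived: float
    W: float
    flags: tuple[str, ...] = ()

    @property
    def total(self) -> float:
        return self.free + self.dipeptide_derived + self.tripeptide_derived


def decompose_reading(
    readings: AmineReadings,
    policy: WPolicy = DEFAULT_POLICY,
    **estimator_kwargs,
) -> ReadingSplit:
    """Split one (F, T) reading into free / dipeptide- / tripeptide-derived
    amine-group equivalents.

    The after-hydrolysis mean shares at W = T/F are scaled by T, so the
    three components sum to T exactly — the "total amino acids" view that
    stacked postprandial bar charts display.
    """
    W, flags = w_ratio(readings, policy)
    s = mean_structure(W, **estimator_kwargs)
    return ReadingSplit(
        free=readings.T * s.a_prime,
        dipeptide_derived=readings.T * s.x_prime,
        tripeptide_derived=readings.T * s.y_prime,
        W=W,
        flags=tuple(flags),
    )


def legacy_free_fraction(readings: AmineReadings, policy: WPolicy = DEFAULT_POLICY) -> float:
    """Heuristic free-amino-acid equivalent F / W.

    A simpler, earlier convention: divide the pre-hydrolysis signal by the
    hydrolysis ratio.  It is not consistent with the feasible-set averaging
    above and is retained only for comparison; no pipeline uses it.
    """
    W, _ = w_ratio(readings, policy)
    return readings.F / W
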