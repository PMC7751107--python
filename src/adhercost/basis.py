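"""Penalized cubic regression spline basis with mixed-model reparametrization.

The smoother is a natural cubic regression spline parameterized by its values
at ``rank`` knots (placed at quantiles of the observed covariate), with the
integrated squared second derivative as wiggliness penalty.  The penalty has
a two-dimensional null space (constant + linear).  For estimation inside a
mixed model the basis is reparameterized:

* a sum-to-zero constraint over the observed covariate values is absorbed
  (so every fitted smooth is centred by construction);
* the constrained penalty is eigen-decomposed into its null space (one
  linear direction after centring) and range space;
* range-space columns are whitened so the penalty becomes the identity —
  these columns enter the model as a random-effect block, while the single
  null-space (linear) column enters as a fixed effect.

Evaluation outside the knot range extrapolates linearly, as natural splines do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky, eigh, null_space


class DegenerateSmoothWarning(UserWarning):
    """Covariate has too little variation for a spline; downgraded to linear."""


def _knot_positions(values: np.ndarray, rank: int,
                    bounds: tuple[float, float] | None = None) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if bounds is not None:
        v = v[(v >= bounds[0]) & (v <= bounds[1])]
    qs = np.linspace(0, 1, rank)
    knots = np.unique(np.quantile(np.unique(v), qs))
    return knots


def _cr_design(x: np.ndarray, knots: np.ndarray, f_full: np.ndarray) -> np.ndarray:
    """Design matrix of the value-at-knots natural cubic spline at points x.

    ``f_full`` maps knot values to second derivatives at the knots
    (rows for the first and last knot are zero: natural boundary).
    Points beyond the boundary knots are extended linearly.
    """
    k = len(knots)
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = np.diff(knots)
    design = np.zeros((n, k))

    inside = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, inside, side="right") - 1, 0, k - 2)
    hj = h[j]
    xm = knots[j + 1] - inside          # distance to right knot
    xp = inside - knots[j]              # distance to left knot
    am, ap = xm / hj, xp / hj
    cm = (xm ** 3 / hj - hj * xm) / 6.0
    cp = (xp ** 3 / hj - hj * xp) / 6.0
    rows = np.arange(n)
    design[rows, j] += am
    design[rows, j + 1] += ap
    design += cm[:, None] * f_full[j, :]
    design += cp[:, None] * f_full[j + 1, :]

    # linear extrapolation beyond the boundary knots via the boundary slope
    for side, knot_idx, seg in ((x < knots[0], 0, 0), (x > knots[-1], k - 1, k - 2)):
        if not side.any():
            continue
        hs = h[seg]
        # derivative of the basis row at the boundary knot
        d_am, d_ap = -1.0 / hs, 1.0 / hs
        at_left = knot_idx == 0
        xb = knots[0] if at_left else knots[-1]
        xm_b = knots[seg + 1] - xb
        xp_b = xb - knots[seg]
        d_cm = (-3 * xm_b ** 2 / hs + hs) / 6.0
        d_cp = (3 * xp_b ** 2 / hs - hs) / 6.0
        slope_row = np.zeros(k)
        slope_row[seg] += d_am
        slope_row[seg + 1] += d_ap
        slope_row += d_cm * f_full[seg, :] + d_cp * f_full[seg + 1, :]
        value_row = np.zeros(k)
        value_row[knot_idx] = 1.0
        design[side, :] = value_row + np.outer(x[side] - xb, slope_row)
    return design


@dataclass
class SmoothBasis:
    """Reparameterized penalized spline for one smooth term.

    Attributes ending in an underscore are computed artefacts of the
    factorization; ``fixed(x)`` / ``random(x)`` evaluate the centred fixed
    (linear) column and the whitened wiggly columns at new points.
    """

    knots: np.ndarray
    f_full: np.ndarray
    penalty: np.ndarray                 # k x k second-derivative penalty
    constraint: np.ndarray              # row vector c: c @ beta = 0 absorbed
    q_null: np.ndarray                  # k x (k-1) constraint null basis
    null_vec: np.ndarray                # (k-1,) penalty-null direction (linear)
    wiggly: np.ndarray                  # (k-1) x (k-2) whitened range directions
    fixed_scale: float
    random_scale: float
    degenerate: bool = False

    @property
    def rank(self) -> int:
        return len(self.knots)

    @property
    def n_random(self) -> int:
        return 0 if self.degenerate else self.wiggly.shape[1]

    def design(self, x) -> np.ndarray:
        return _cr_design(np.asarray(x, dtype=float), self.knots, self.f_full)

    def fixed(self, x) -> np.ndarray:
        """Centred linear column (n x 1)."""
        if self.degenerate:
            return np.zeros((len(np.asarray(x)), 1))
        return (self.design(x) @ self.q_null @ self.null_vec)[:, None] * self.fixed_scale

    def random(self, x) -> np.ndarray:
        """Whitened wiggly columns (n x (rank-2)); penalty is identity."""
        if self.degenerate:
            return np.zeros((len(np.asarray(x)), 0))
        return self.design(x) @ self.q_null @ self.wiggly * self.random_scale

    def coef_original(self, coef_fixed: float, coef_random: np.ndarray) -> np.ndarray:
        """Map (fixed, random) model coefficients back to knot-value coefficients."""
        return self.q_null @ (
            self.null_vec * (self.fixed_scale * coef_fixed)
            + self.wiggly @ (self.random_scale * np.asarray(coef_random, dtype=float))
        )

    def wiggliness(self, coef_fixed: float, coef_random: np.ndarray) -> float:
        """Penalty beta' S beta of a smooth, via the whitened coordinates.

        The fixed (linear) part is penalty-free and the whitened random part
        has identity penalty, so this is just the scaled squared norm of the
        random coefficients.
        """
        b = np.asarray(coef_random, dtype=float)
        return float(self.random_scale ** 2 * (b @ b))


def build_smooth_basis(
    values,
    rank: int = 10,
    bounds: tuple[float, float] | None = None,
) -> SmoothBasis:
    """Construct the reparameterized penalized spline for observed ``values``.

    Returns a :class:`SmoothBasis` whose ``fixed``/``random`` columns evaluated
    at ``values`` are centred (mean zero) and whose penalty in the random
    coordinates is the identity.  A covariate with fewer than four distinct
    values is downgraded to a (centred) linear term with a warning.
    """
    if rank < 3:
        raise ValueError(f"rank must be >= 3, got {rank}")
    v = np.asarray(values, dtype=float)
    knots = _knot_positions(v, rank, bounds)
    k = len(knots)
    if k < 4:
        warnings.warn(
            f"covariate has only {k} distinct knot positions; smooth downgraded "
            "to a linear term", DegenerateSmoothWarning)
        # degenerate: linear (or constant) term only
        knots = np.array([v.min(), v.max()]) if k < 2 else knots
        basis = SmoothBasis(
            knots=knots, f_full=np.zeros((len(knots), len(knots))),
            penalty=np.zeros((len(knots), len(knots))),
            constraint=np.zeros(len(knots)), q_null=np.eye(len(knots)),
            null_vec=np.zeros(len(knots)), wiggly=np.zeros((len(knots), 0)),
            fixed_scale=1.0, random_scale=1.0, degenerate=True)
        return basis

    h = np.diff(knots)
    # B (k-2 x k-2) tridiagonal, D (k-2 x k): f'' = B^-1 D f  at interior knots
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    Bc = cholesky(B, lower=True)
    f_interior = cho_solve((Bc, True), D)
    f_full = np.zeros((k, k))
    f_full[1:-1, :] = f_interior
    penalty = D.T @ f_interior          # D' B^-1 D, PSD, rank k-2

    design_obs = _cr_design(v, knots, f_full)
    constraint = design_obs.mean(axis=0)
    q_null = null_space(constraint[None, :])        # k x (k-1)

    s_con = q_null.T @ penalty @ q_null
    eigval, eigvec = eigh(s_con)
    # ascending eigenvalues: first is the (centred) linear null direction
    tol = max(eigval.max(), 1.0) * 1e-10
    null_mask = eigval < tol
    if null_mask.sum() != 1:
        raise RuntimeError(
            f"unexpected penalty null-space dimension {int(null_mask.sum())} "
            "after constraint absorption")
    null_vec = eigvec[:, null_mask][:, 0]
    lam = eigval[~null_mask]
    wiggly = eigvec[:, ~null_mask] / np.sqrt(lam)

    # rescale for numerical balance; scales are pure reparametrizations
    fixed_col = design_obs @ q_null @ null_vec
    fixed_scale = 1.0 / max(fixed_col.std(), 1e-12)
    rand_cols = design_obs @ q_null @ wiggly
    random_scale = 1.0 / max(np.sqrt((rand_cols ** 2).mean()), 1e-12)
    return SmoothBasis(
        knots=knots, f_full=f_full, penalty=penalty, constraint=constraint,
        q_null=q_null, null_vec=null_vec, wiggly=wiggly,
        fixed_scale=fixed_scale, random_scale=random_scale)
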