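"""SHORE q-space signal representation.

The diffusion signal E(q) is expanded over the simple-harmonic-oscillator
basis Phi_nlm(q) = X_nl(|q|, zeta) Y_lm(u): generalized-Laguerre radial
functions modulated by a Gaussian decay, times real spherical harmonics of
even degree.  The truncation keeps every radial order l <= n <= N_max for
each even degree l, which yields 72 functions at N_max = 6 (the wider of
the two truncations in circulation; the alternative even-n-only set has
50).  Coefficients are estimated per voxel by weighted, l2-regularized
least squares with separate radial and angular roughness penalties.

q is mapped from the b-value as q = sqrt(b) * u (b in s/mm^2); diffusion
timings are absorbed into the scale parameter zeta, a convention rather
than physics — the default zeta = 700 is calibrated for this mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.special import eval_genlaguerre, gammaln, sph_harm_y

__all__ = [
    "shore_index_set",
    "shore_radial",
    "real_sph_harm",
    "build_basis",
    "ShoreBasis",
    "ShoreCoefficients",
    "RegularizationOperators",
    "regularization_operators",
    "fit_shore",
    "predict_signal",
    "DEFAULT_ORDER",
    "DEFAULT_ZETA",
    "DEFAULT_LAMBDA",
]

DEFAULT_ORDER = 6
DEFAULT_ZETA = 700.0
DEFAULT_LAMBDA = 1e-8


def shore_index_set(order_max: int) -> list[tuple[int, int, int]]:
    """Enumerate the (n, l, m) indices for a given maximal order.

    l runs over even degrees 0..order_max, n over l..order_max and m over
    -l..l, in lexicographic (l, n, m) order.  The count is
    sum_{l even <= N} (N - l + 1)(2l + 1): 1, 8, 29, 72 for N = 0, 2, 4, 6.
    """
    if order_max < 0 or order_max % 2 != 0:
        raise ValueError("order_max must be an even non-negative integer")
    idx = []
    for l in range(0, order_max + 1, 2):
        for n in range(l, order_max + 1):
            for m in range(-l, l + 1):
                idx.append((n, l, m))
    return idx


def shore_radial(n: int, l: int, q: np.ndarray, zeta: float) -> np.ndarray:
    """Radial basis function X_nl(q, zeta).

    X_nl = kappa_nl (q^2/zeta)^(l/2) exp(-q^2/(2 zeta))
           L^{l+1/2}_{n-l}(q^2/zeta),
    with kappa_nl = sqrt(2 (n-l)! / (zeta^{3/2} Gamma(n + 3/2))), which
    makes {X_nl}_n orthonormal under the measure q^2 dq for each l.
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    q = np.asarray(q, dtype=float)
    x = q * q / zeta
    log_kappa = 0.5 * (
        np.log(2.0) + gammaln(n - l + 1) - 1.5 * np.log(zeta)
        - gammaln(n + 1.5)
    )
    with np.errstate(divide="ignore"):
        # x^(l/2) at x=0 handled explicitly: only l=0 is nonzero there
        radial = np.where(
            x > 0, np.exp(0.5 * l * np.log(np.maximum(x, 1e-300))), 0.0
        )
        if l == 0:
            radial = np.ones_like(x)
    return (
        np.exp(log_kappa) * radial * np.exp(-x / 2.0)
        * eval_genlaguerre(n - l, l + 0.5, x)
    )


def real_sph_harm(l: int, m: int, directions: np.ndarray) -> np.ndarray:
    """Real, orthonormal spherical harmonic of degree l, order m.

    m < 0 maps to sqrt(2) Im(Y_l^|m|), m > 0 to sqrt(2) Re(Y_l^m).
    ``directions`` are unit 3-vectors; zero rows evaluate as the pole
    (they only occur at q = 0 where every l > 0 column vanishes anyway).
    """
    d = np.asarray(directions, dtype=float).reshape(-1, 3)
    norms = np.linalg.norm(d, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    u = d / safe[:, None]
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return np.real(y)
    if m > 0:
        return np.sqrt(2.0) * np.real(y)
    return np.sqrt(2.0) * np.imag(y)


@dataclass(frozen=True)
class ShoreBasis:
    """Evaluated SHORE design matrix over a set of q-space points."""

    order_max: int
    zeta: float
    index_set: tuple
    design_matrix: np.ndarray  # (Q, C)

    @property
    def n_coeffs(self) -> int:
        return len(self.index_set)


@dataclass
class ShoreCoefficients:
    """Per-voxel SHORE coefficient vectors bound to their basis.

    ``values`` is (..., C); the leading axes are voxel axes (or absent for
    a single voxel).
    """

    values: np.ndarray
    basis: ShoreBasis

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape[-1] != self.basis.n_coeffs:
            raise ValueError("coefficient length does not match basis")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite coefficients")
        self.values = v


@dataclass(frozen=True)
class RegularizationOperators:
    """Diagonal angular (L) and radial (N) roughness operators.

    diag(L) = l(l+1) and diag(N) = n(n+1) in basis index order, scaled by
    lambda_l and lambda_n in the penalized fit.
    """

    L_diag: np.ndarray
    N_diag: np.ndarray
    lambda_l: float
    lambda_n: float

    @property
    def penalty_diag(self) -> np.ndarray:
        """Diagonal of lambda_l L^2 + lambda_n N^2."""
        return (self.lambda_l * self.L_diag ** 2
                + self.lambda_n * self.N_diag ** 2)


def regularization_operators(index_set, lambda_l: float = DEFAULT_LAMBDA,
                             lambda_n: float = DEFAULT_LAMBDA
                             ) -> RegularizationOperators:
    if lambda_l < 0 or lambda_n < 0:
        raise ValueError("regularization weights must be non-negative")
    L = np.array([l * (l + 1) for (_, l, _) in index_set], dtype=float)
    N = np.array([n * (n + 1) for (n, _, _) in index_set], dtype=float)
    return RegularizationOperators(L, N, float(lambda_l), float(lambda_n))


def build_basis(index_set, q_points: np.ndarray, zeta: float = DEFAULT_ZETA
                ) -> ShoreBasis:
    """Evaluate the design matrix Phi over q-space sample points.

    ``q_points`` are 3-vectors q = sqrt(b) u.  Entry (i, j) is
    X_{n_j l_j}(|q_i|, zeta) * Y_{l_j m_j}(u_i).
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    q = np.asarray(q_points, dtype=float).reshape(-1, 3)
    qnorm = np.linalg.norm(q, axis=1)
    order_max = max((n for n, _, _ in index_set), default=0)
    cols = []
    radial_cache: dict[tuple[int, int], np.ndarray] = {}
    sh_cache: dict[tuple[int, int], np.ndarray] = {}
    for (n, l, m) in index_set:
        if (n, l) not in radial_cache:
            radial_cache[(n, l)] = shore_radial(n, l, qnorm, zeta)
        if (l, m) not in sh_cache:
            sh_cache[(l, m)] = real_sph_harm(l, m, q)
        cols.append(radial_cache[(n, l)] * sh_cache[(l, m)])
    design = np.column_stack(cols) if cols else np.empty((q.shape[0], 0))
    return ShoreBasis(order_max, float(zeta), tuple(index_set), design)


def fit_shore(signal, basis: ShoreBasis, weights=None,
              reg: RegularizationOperators | None = None
              ) -> ShoreCoefficients:
    """Weighted l2-regularized least-squares SHORE fit.

    Solves ``argmin_c ||W(Phi c - E)||^2 + lambda_l ||L c||^2
    + lambda_n ||N c||^2`` through the normal equations
    ``(Phi^T W^2 Phi + lambda_l L^2 + lambda_n N^2) c = Phi^T W^2 E``.

    Parameters
    ----------
    signal : (..., Q) array
        Signal samples; leading axes are voxels and share the weights.
    weights : (Q,) or (..., Q) array in [0, 1], optional
        Diagonal of W.  Defaults to all ones.
    reg : RegularizationOperators, optional
        Defaults to lambda = 0 (unregularized).
    """
    E = np.asarray(signal, dtype=float)
    phi = basis.design_matrix
    Q, C = phi.shape
    if E.shape[-1] != Q:
        raise ValueError("signal length does not match basis rows")
    if weights is None:
        weights = np.ones(Q)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    if reg is None:
        reg = regularization_operators(basis.index_set, 0.0, 0.0)
    pen = reg.penalty_diag

    if w.ndim == 1 and E.ndim >= 1:
        w2 = w * w
        A = (phi.T * w2) @ phi + np.diag(pen)
        b = (phi.T * w2) @ E.reshape(-1, Q).T
        c = _solve_spd(A, b, has_reg=pen.any())
        values = c.T.reshape(E.shape[:-1] + (C,))
    else:
        # per-voxel weights: batched normal equations (BLAS batched GEMM)
        w = np.broadcast_to(w, E.shape)
        flatE = E.reshape(-1, Q)
        flatW2 = (w * w).reshape(-1, Q)
        wphi = flatW2[:, :, None] * phi[None, :, :]      # (V, Q, C)
        A = np.matmul(phi.T[None], wphi) + np.diag(pen)[None]
        b = np.matmul(wphi.transpose(0, 2, 1),
                      flatE[:, :, None])[..., 0]
        c = np.zeros_like(b)
        informative = flatW2.sum(axis=1) > 0  # else A can be singular
        if np.any(informative):
            c[informative] = np.linalg.solve(
                A[informative], b[informative, :, None])[..., 0]
        values = c.reshape(E.shape[:-1] + (C,))
    return ShoreCoefficients(values, basis)


def _solve_spd(A: np.ndarray, b: np.ndarray, has_reg: bool) -> np.ndarray:
    try:
        cf = linalg.cho_factor(A, check_finite=False)
        return linalg.cho_solve(cf, b, check_finite=False)
    except linalg.LinAlgError:
        if not has_reg:
            raise np.linalg.LinAlgError(
                "normal equations are rank deficient with lambda = 0; "
                "add radial/angular regularization"
            )
        return linalg.lstsq(A, b, check_finite=False)[0]


def predict_signal(coeffs: ShoreCoefficients, q_points: np.ndarray
                   ) -> np.ndarray:
    """Evaluate the fitted expansion Phi(q) c at arbitrary q-space points."""
    basis = build_basis(coeffs.basis.index_set, q_points, coeffs.basis.zeta)
    return coeffs.values @ basis.design_matrix.T
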