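"""SVD/GSVD bundles and the spectral curves every criterion consumes.

Regularized Tikhonov solutions and all five parameter-choice criteria are
closed-form expressions in the (generalized) singular value expansion of
the transfer matrix.  This module computes the decompositions once per
system and exposes the curves

    rho(lambda)  = ||A x(lambda) - b||^2        (residual norm)
    eta(lambda)  = ||x(lambda)||^2 or ||L x||^2 (solution (semi)norm)
    xi(lambda)   = Trace[(A A_lambda^+)^2]      (influence trace)

as vectorized functions of lambda.

Conventions follow the standard treatment of discrete ill-posed problems:
ordinary singular values are stored in decreasing order; the GSVD of the
pair {A, L} stores sigma increasing, nu decreasing, so the generalized
singular values gsv_i = sigma_i / nu_i are nondecreasing.  Entries with
nu_i below 1e-14 are treated as infinite generalized singular values whose
filter factor is 1 for every lambda (the Dirichlet-to-Neumann operator has
a constant null vector, so this case is the norm, not the exception).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import qr, svd

__all__ = [
    "SvdBundle",
    "GsvdBundle",
    "compute_svd",
    "compute_gsvd",
    "residual_curve",
    "seminorm_curve",
    "influence_trace",
    "filter_trace",
    "complement_filter_trace",
    "lambda_grid",
]

_NU_ZERO = 1e-14


def _frames(b_or_B: np.ndarray) -> np.ndarray:
    """Return measurements as an (m, T) column-frame matrix."""
    b = np.asarray(b_or_B, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite entries in measurement frames")
    return b


@dataclasses.dataclass
class SvdBundle:
    """Thin SVD of A with per-frame Fourier coefficients.

    ``mu[i, t] = u_i^T b_t`` and ``rperp2[t]`` is the squared residual of
    the least-squares solution for frame t (the part of b outside the
    range of A).
    """

    U: np.ndarray
    sigma: np.ndarray  # decreasing
    V: np.ndarray
    mu: np.ndarray  # (n, T)
    rperp2: np.ndarray  # (T,)
    m: int
    n: int

    @property
    def n_frames(self) -> int:
        return self.mu.shape[1]

    def filters(self, lam: float) -> np.ndarray:
        return self.sigma**2 / (self.sigma**2 + lam**2)


@dataclasses.dataclass
class GsvdBundle:
    """GSVD of the pair {A, L}: A = P C Z^-1, L = Q S Z^-1.

    ``sigma`` (diag C, increasing, <= 1) and ``nu`` (diag S, decreasing)
    satisfy sigma^2 + nu^2 = 1; ``gsv = sigma/nu`` are the generalized
    singular values (np.inf where nu ~ 0).  ``alpha[i, t] = p_i^T b_t``;
    ``extra2[t]`` is the out-of-range residual term sum_{i>n} (p_i^T b)^2,
    computed as ||b||^2 - sum_i alpha_i^2 (P has orthonormal columns).
    """

    P: np.ndarray
    Q: np.ndarray
    Z: np.ndarray  # columns z_i; A z_i = sigma_i p_i, L z_i = nu_i q_i
    sigma: np.ndarray
    nu: np.ndarray
    gsv: np.ndarray
    alpha: np.ndarray  # (n, T)
    extra2: np.ndarray  # (T,)
    m: int
    n: int

    @property
    def n_frames(self) -> int:
        return self.alpha.shape[1]

    @property
    def finite(self) -> np.ndarray:
        return np.isfinite(self.gsv)

    def filters(self, lam: float) -> np.ndarray:
        """Filter factors gsv^2/(gsv^2 + lam^2); 1 on infinite entries."""
        phi = np.ones_like(self.sigma)
        f = self.finite
        phi[f] = self.gsv[f] ** 2 / (self.gsv[f] ** 2 + lam**2)
        return phi


def compute_svd(A: np.ndarray, b_or_B: np.ndarray) -> SvdBundle:
    """Thin SVD of A (m >= n) plus per-frame spectral coefficients."""
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite entries in A")
    m, n = A.shape
    if m < n:
        raise ValueError(f"need m >= n, got {A.shape}")
    B = _frames(b_or_B)
    U, s, Vt = svd(A, full_matrices=False)
    mu = U.T @ B
    live = s > s[0] * 1e-15 if s[0] > 0 else np.zeros_like(s, dtype=bool)
    rperp2 = np.einsum("it,it->t", B, B) - np.einsum("it,it->t", mu[live], mu[live])
    return SvdBundle(U=U, sigma=s, V=Vt.T, mu=mu, rperp2=np.maximum(rperp2, 0.0), m=m, n=n)


def compute_gsvd(A: np.ndarray, L: np.ndarray, b_or_B: np.ndarray) -> GsvdBundle:
    """GSVD of {A, L} via QR of the stacked matrix and a CS decomposition.

    The route: [A; L] = [Q1; Q2] R (thin QR); the SVD Q1 = P C W^T makes
    Q2 W have orthogonal columns of norms nu_i = sqrt(1 - sigma_i^2), so
    Q = (Q2 W) S^+ (orthonormally completed where nu_i = 0) and
    Z^-1 = W^T R.  The contract is the reconstruction invariants, not the
    route.
    """
    A = np.asarray(A, dtype=float)
    L = np.asarray(L, dtype=float)
    m, n = A.shape
    if m < n:
        raise ValueError(f"need m >= n, got {A.shape}")
    if L.shape != (n, n):
        raise ValueError(f"L must be {n} x {n}, got {L.shape}")
    B = _frames(b_or_B)
    stacked = np.vstack([A, L])
    Qfull, R = qr(stacked, mode="economic")
    if np.linalg.matrix_rank(R) < n:
        raise ValueError("rank([A; L]) < n: the regularized problem is ill-posed for every lambda")
    Q1, Q2 = Qfull[:m], Qfull[m:]
    Uc, c, Wt = svd(Q1, full_matrices=False)  # c decreasing in [0, 1]
    order = np.argsort(c, kind="stable")  # sigma increasing per convention
    c = np.clip(c[order], 0.0, 1.0)
    P = Uc[:, order]
    W = Wt.T[:, order]
    nu = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
    Q2W = Q2 @ W
    Q = np.empty((n, n))
    small = nu <= _NU_ZERO
    Q[:, ~small] = Q2W[:, ~small] / nu[~small]
    if np.any(small):
        # complete orthonormally; these columns never carry L-content
        basis = np.linalg.qr(
            np.hstack([Q[:, ~small], np.random.default_rng(0).normal(size=(n, small.sum()))])
        )[0]
        Q[:, small] = basis[:, (~small).sum() :]
    Z = np.linalg.solve(R, W)  # Z^-1 = W^T R
    gsv = np.where(small, np.inf, c / np.where(small, 1.0, nu))
    alpha = P.T @ B
    extra2 = np.maximum(np.einsum("it,it->t", B, B) - np.einsum("it,it->t", alpha, alpha), 0.0)
    return GsvdBundle(
        P=P, Q=Q, Z=Z, sigma=c, nu=nu, gsv=gsv, alpha=alpha, extra2=extra2, m=m, n=n
    )


# ---------------------------------------------------------------------------
# spectral curves (vectorized over a lambda array)
# ---------------------------------------------------------------------------


def _lam_col(lam) -> np.ndarray:
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam < 0):
        raise ValueError("lambda must be nonnegative")
    return lam[:, None]


def _unpack(bundle, frame: int):
    """(spectral values restricted to finite entries, coefficients, floor)."""
    if isinstance(bundle, SvdBundle):
        return bundle.sigma, bundle.mu[:, frame], float(bundle.rperp2[frame]), None
    s = bundle.gsv[bundle.finite]
    a = bundle.alpha[bundle.finite, frame]
    return s, a, float(bundle.extra2[frame]), bundle


def residual_curve(bundle, lam, frame: int = 0) -> np.ndarray:
    """rho(lambda) = ||A x(lambda) - b||^2 by the closed-form spectral sum."""
    s, coef, floor, _ = _unpack(bundle, frame)
    live = s > (s.max() if len(s) else 0.0) * 1e-15
    floor = floor + float(np.sum(coef[~live] ** 2))  # dead directions never fit
    s, coef = s[live], coef[live]
    L = _lam_col(lam)
    out = np.sum((L**2 / (s**2 + L**2)) ** 2 * coef**2, axis=1) + floor
    return out if np.ndim(lam) else float(out[0])


def seminorm_curve(bundle, lam, frame: int = 0) -> np.ndarray:
    """eta(lambda) = ||x||^2 (SVD branch) or ||L x||^2 (GSVD branch)."""
    s, coef, _, _ = _unpack(bundle, frame)
    live = s > (s.max() if len(s) else 0) * 1e-15
    s, coef = s[live], coef[live]
    L = _lam_col(lam)
    out = np.sum((s / (s**2 + L**2)) ** 2 * coef**2, axis=1)
    return out if np.ndim(lam) else float(out[0])


def influence_trace(bundle, lam) -> np.ndarray:
    """xi(lambda) = Trace[(A A_lambda^+)^2] = sum of squared filter factors."""
    if isinstance(bundle, SvdBundle):
        s = bundle.sigma
        n_inf = 0
    else:
        s = bundle.gsv[bundle.finite]
        n_inf = int((~bundle.finite).sum())
    L = _lam_col(lam)
    out = np.sum((s**2 / (s**2 + L**2)) ** 2, axis=1) + n_inf
    return out if np.ndim(lam) else float(out[0])


def filter_trace(bundle, lam) -> np.ndarray:
    """Sum of filter factors: Trace(A A_lambda^+), the GCV denominator term."""
    if isinstance(bundle, SvdBundle):
        s = bundle.sigma
        n_inf = 0
    else:
        s = bundle.gsv[bundle.finite]
        n_inf = int((~bundle.finite).sum())
    L = _lam_col(lam)
    out = np.sum(s**2 / (s**2 + L**2), axis=1) + n_inf
    return out if np.ndim(lam) else float(out[0])


def complement_filter_trace(bundle, lam) -> np.ndarray:
    """m - Trace(A A_lambda^+), computed without cancellation.

    Evaluated as (m - n) + sum_i lam^2/(s_i^2 + lam^2); infinite
    generalized singular values contribute zero.  The naive m - sum(f_i)
    loses all precision at small lambda, where the complement is tiny.
    """
    if isinstance(bundle, SvdBundle):
        s = bundle.sigma
        extra = bundle.m - bundle.n
    else:
        s = bundle.gsv[bundle.finite]
        extra = bundle.m - bundle.n
    L = _lam_col(lam)
    out = np.sum(L**2 / (s**2 + L**2), axis=1) + extra
    return out if np.ndim(lam) else float(out[0])


def lambda_grid(bundle, num: int = 300, lo_rel: float = 1e-8, hi_rel: float = 10.0) -> np.ndarray:
    """Shared geometric lambda grid from lo_rel*s_max to hi_rel*s_max.

    ``s_max`` is the largest finite (generalized) singular value, so all
    criteria scan the same grid and branch comparisons are fair.
    """
    if isinstance(bundle, SvdBundle):
        smax = float(bundle.sigma[0])
    else:
        fin = bundle.gsv[bundle.finite]
        smax = float(fin.max()) if len(fin) else 1.0
    if smax <= 0:
        raise ValueError("no positive spectral values; cannot build a lambda grid")
    return np.geomspace(lo_rel * smax, hi_rel * smax, num)
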