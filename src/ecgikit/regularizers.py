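"""Inverse solvers: zero-order Tikhonov and L1 current-density regularization.

Three reconstruction schemes are supported:

* MFS-ZOT / FEM-ZOT -- zero-order Tikhonov, solved in the SVD basis of the
  transfer matrix:  x(lambda) = sum_i sigma_i^2/(sigma_i^2 + lambda^2)
  (u_i^T b / sigma_i) v_i.
* FEM-L1 -- the L1 norm of the current density (the normal derivative D x
  of the potential through the epicardium) is smoothly approximated by
  sum_i sqrt(|[Dx]_i|^2 + beta), which linearizes to a first-order
  Tikhonov problem with operator D_tilde = W^{1/2} D, where W is a
  diagonal weight matrix evaluated at the zero-order Tikhonov seed
  solution.  The linearized problem is solved in the GSVD basis of
  {A, D_tilde}; there is no reweighting iteration by default (a single
  linearization at the ZOT seed), though an iterative mode exists for
  study.

The half-quadratic weight convention: the normal equations penalize
lambda^2 D^T W D, so the effective first-order operator is W^{1/2} D.  A
``weight_power`` switch selects the alternative W D convention (penalty
D^T W^2 D) for comparison.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .spectral import GsvdBundle, SvdBundle, compute_gsvd, compute_svd

__all__ = [
    "Reconstruction",
    "L1Config",
    "solve_zot",
    "solve_first_order",
    "build_weight_matrix",
    "solve_l1_current_density",
    "l1_operator",
]


@dataclasses.dataclass
class Reconstruction:
    """A regularized solution x(lambda) with its provenance."""

    x: np.ndarray
    lam: float
    method: str = ""
    criterion: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite reconstruction")


@dataclasses.dataclass
class L1Config:
    """Configuration of the L1 current-density scheme.

    beta is the smoothing constant of the L1 approximation (fixed default
    1e-5); ``weight_power`` = 0.5 applies W^{1/2} D (the
    half-quadratic normal-equation form, default) and 1.0 applies W D.
    ``max_iter`` > 1 enables iterative reweighting to a fixed point
    (off by default: a single linearization at the ZOT seed).
    """

    beta: float = 1e-5
    weight_power: float = 0.5
    max_iter: int = 1
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.weight_power not in (0.5, 1.0):
            raise ValueError("weight_power must be 0.5 or 1.0")


def _coef(bundle: SvdBundle | GsvdBundle, b) -> np.ndarray:
    basis = bundle.U if isinstance(bundle, SvdBundle) else bundle.P
    b = np.asarray(b, dtype=float)
    if b.ndim == 1 and len(b) == bundle.m:
        return basis.T @ b
    if np.isscalar(b) or b.ndim == 0:
        raise ValueError("b must be a vector or a frame index")
    raise ValueError(f"frame length {len(b)} does not match m = {bundle.m}")


def solve_zot(bundle: SvdBundle, b: np.ndarray | int, lam: float) -> Reconstruction:
    """Zero-order Tikhonov solution in the SVD basis.

    ``b`` may be a measurement vector or the index of a frame already
    attached to the bundle.  At lambda = 0 this is the (pseudo-inverse)
    least-squares solution; a zero singular value then raises.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    mu = bundle.mu[:, b] if isinstance(b, (int, np.integer)) else _coef(bundle, b)
    s = bundle.sigma
    if lam == 0 and np.any(s <= s[0] * 1e-15):
        raise ZeroDivisionError("lambda = 0 with a zero singular value")
    filt = s**2 / (s**2 + lam**2)
    x = bundle.V @ (filt * mu / s)
    return Reconstruction(x=x, lam=float(lam), method="ZOT")


def solve_first_order(bundle: GsvdBundle, b: np.ndarray | int, lam: float) -> Reconstruction:
    """First-order Tikhonov solution in the GSVD basis of {A, L}.

    x = sum_i phi_i (p_i^T b / sigma_i) z_i with filter factors
    phi_i = gsv_i^2/(gsv_i^2 + lambda^2); directions with nu_i = 0
    (infinite generalized singular value) pass unfiltered.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    alpha = bundle.alpha[:, b] if isinstance(b, (int, np.integer)) else _coef(bundle, b)
    sig, nu = bundle.sigma, bundle.nu
    if np.any(sig <= 1e-15):
        raise ZeroDivisionError("zero sigma_i in GSVD: A has a null direction not damped by L")
    # phi/sigma = sigma/(sigma^2 + lam^2 nu^2), finite also when nu = 0
    coef = sig / (sig**2 + lam**2 * nu**2) * alpha
    x = bundle.Z @ coef
    return Reconstruction(x=x, lam=float(lam), method="first-order")


def build_weight_matrix(D: np.ndarray, x0: np.ndarray, beta: float) -> np.ndarray:
    """Diagonal of the half-quadratic weight matrix W_beta(x0).

    W_ii = 1 / (2 sqrt(|[D x0]_i|^2 + beta)): small local current density
    gives a large weight (more smoothing); a large current density relaxes
    the penalty there, which is what lets the scheme keep sharp potential
    fronts.  Entries lie in (0, 1/(2 sqrt(beta))].
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    dx = np.asarray(D, dtype=float) @ np.asarray(x0, dtype=float)
    return 1.0 / (2.0 * np.sqrt(dx**2 + beta))


def solve_l1_current_density(
    A: np.ndarray,
    b: np.ndarray,
    D: np.ndarray,
    lam: float,
    config: L1Config | None = None,
    zot_seed_lam: float | None = None,
    svd_bundle: SvdBundle | None = None,
    gsvd_bundle: GsvdBundle | None = None,
) -> Reconstruction:
    """L1 current-density reconstruction via one-shot half-quadratic
    linearization.

    Computes the ZOT seed x0 = x_ZOT(zot_seed_lam), forms
    D_tilde = W_beta(x0)^p D and solves the first-order Tikhonov problem on
    the GSVD of {A, D_tilde} at ``lam``.  Pass ``gsvd_bundle`` to reuse a
    decomposition (the seed is then implicit in it).
    """
    config = config or L1Config()
    if gsvd_bundle is None:
        if svd_bundle is None:
            svd_bundle = compute_svd(A, b)
        seed_lam = lam if zot_seed_lam is None else zot_seed_lam
        x_prev = solve_zot(svd_bundle, b, seed_lam).x
        for _ in range(max(config.max_iter, 1)):
            w = build_weight_matrix(D, x_prev, config.beta)
            Dt = (w**config.weight_power)[:, None] * D
            gsvd_bundle = compute_gsvd(A, Dt, b)
            rec = solve_first_order(gsvd_bundle, b, lam)
            if np.linalg.norm(rec.x - x_prev) <= config.tol * np.linalg.norm(rec.x):
                break
            x_prev = rec.x
    else:
        rec = solve_first_order(gsvd_bundle, b, lam)
    return Reconstruction(x=rec.x, lam=float(lam), method="L1")


def l1_operator(D: np.ndarray, x0: np.ndarray, config: L1Config | None = None) -> np.ndarray:
    """Effective first-order operator D_tilde = W_beta(x0)^p D at a seed."""
    config = config or L1Config()
    w = build_weight_matrix(D, x0, config.beta)
    return (w**config.weight_power)[:, None] * np.asarray(D, dtype=float)
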