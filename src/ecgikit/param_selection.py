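"""Regularization-parameter choice criteria: GCV, RGCV, CRESO, U-curve, ADPC.

All five criteria operate on a spectral bundle (SVD for zero-order
Tikhonov, GSVD for first-order / L1 current density) and scan a shared
geometric lambda grid, so comparisons between numerical-method branches
are fair and reproducible.  Ties are broken toward larger lambda (more
regularization), a conservative default given GCV's known tendency to
under-regularize on discrete ill-posed problems.

The GCV flat-curve warning implements the classic failure mode on FEM
transfer matrices: for square, mildly noisy systems G(lambda) approaches a
constant plateau as lambda -> 0, so the minimizer sits on a flat shelf and
is numerically meaningless.  The warning fires either when the whole curve
is flat to 1e-12 relative, or when the near-minimal set
{lambda : G <= (1 + 1e-6) G_min} spans at least one decade.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .spectral import (
    GsvdBundle,
    SvdBundle,
    complement_filter_trace,
    influence_trace,
    lambda_grid,
    residual_curve,
    seminorm_curve,
)

__all__ = [
    "SelectionResult",
    "SelectionCurve",
    "gcv_lambda",
    "rgcv_lambda",
    "creso_lambda",
    "ucurve_lambda",
    "adpc_lambda",
    "gcv_curve",
    "rgcv_curve",
    "creso_curve",
    "ucurve_curve",
    "selection_curve",
    "CRITERIA",
]


@dataclasses.dataclass
class SelectionResult:
    """A chosen regularization parameter and how it was found."""

    lam: float
    index: int
    criterion: str
    flags: tuple[str, ...] = ()

    @property
    def flat(self) -> bool:
        return "flat-curve" in self.flags


@dataclasses.dataclass
class SelectionCurve:
    """All criterion curves on one lambda grid, for export/inspection."""

    grid: np.ndarray
    rho: np.ndarray
    eta: np.ndarray
    G: np.ndarray
    R: np.ndarray
    xi: np.ndarray
    C: np.ndarray
    ucurve: np.ndarray
    gamma: float
    chosen: dict[str, SelectionResult]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lambda": self.grid,
                "rho": self.rho,
                "eta": self.eta,
                "G": self.G,
                "R": self.R,
                "xi": self.xi,
                "C": self.C,
                "ucurve": self.ucurve,
            }
        )


def _grid(bundle, grid):
    return lambda_grid(bundle) if grid is None else np.asarray(grid, dtype=float)


def _argmin_prefer_large(values: np.ndarray) -> int:
    """Index of the minimum; exact ties resolved toward larger lambda."""
    rev = len(values) - 1 - int(np.argmin(values[::-1]))
    return rev


def _best_interior_minimum(values: np.ndarray) -> int | None:
    """First prominent interior local minimum (scanning lambda upward).

    GCV-family curves on the prescribed wide grid can decay monotonically
    toward the grid top (xi -> 0 as lambda -> infinity drives R -> 0), so a
    bare global argmin degenerates to the largest grid point; the
    meaningful minimizer is the interior dip.  Minima are filtered by a
    prominence of 1e-3 of the curve range: the small-lambda plateau is
    analytically constant but wiggles at round-off-amplified levels, and
    shallow dips on the large-lambda tail are artifacts of the flattening
    influence trace.
    """
    from scipy.signal import find_peaks

    rng = float(np.max(values) - np.min(values))
    if rng <= 0:
        return None
    peaks, _ = find_peaks(-values, prominence=1e-3 * rng)
    if len(peaks) == 0:
        return None
    return int(peaks[0])


def _capped_argmin(grid: np.ndarray, values: np.ndarray, bundle) -> int:
    """Fallback when no interior minimum exists: argmin restricted to
    lambda <= s_max.  Beyond the largest spectral value every filter factor
    is below 1/2 and the solution is essentially annihilated, so the
    monotone tail out there carries no usable minimizer."""
    smax = _spectral_max(bundle)
    mask = grid <= smax
    if not np.any(mask):
        return _argmin_prefer_large(values)
    sub = np.nonzero(mask)[0]
    return int(sub[_argmin_prefer_large(values[sub])])


_PLATEAU_RTOL = 1e-2  # "within 1 % of the minimum" counts as flat
_PLATEAU_DECADES = 1.0


def _flat_flags(grid: np.ndarray, values: np.ndarray) -> tuple[str, ...]:
    """Flat-curve warning: globally constant, or a near-minimal shelf
    spanning at least a decade of lambda (a 1 % variation over a decade is
    unpickable in practice)."""
    vmax, vmin = float(np.max(values)), float(np.min(values))
    if vmax - vmin < 1e-12 * abs(vmax):
        return ("flat-curve",)
    near = (
        values <= vmin * (1.0 + _PLATEAU_RTOL)
        if vmin > 0
        else values <= vmin + _PLATEAU_RTOL * abs(vmax)
    )
    lams = grid[near]
    if len(lams) > 1 and lams.max() / lams.min() >= 10.0**_PLATEAU_DECADES:
        return ("flat-curve",)
    return ()


def _spectral_max(bundle) -> float:
    if isinstance(bundle, SvdBundle):
        return float(bundle.sigma[0])
    fin = bundle.gsv[bundle.finite]
    return float(fin.max()) if len(fin) else float("inf")


# ---------------------------------------------------------------------------
# GCV / RGCV
# ---------------------------------------------------------------------------


def gcv_curve(bundle, frame: int = 0, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """G(lambda) = rho(lambda) / (m - Trace(A A_lambda^+))^2 on the grid."""
    grid = _grid(bundle, grid)
    rho = residual_curve(bundle, grid, frame)
    denom = complement_filter_trace(bundle, grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        return grid, rho / denom**2


def gcv_lambda(bundle, frame: int = 0, grid=None) -> SelectionResult:
    """Minimizer of the generalized cross-validation function."""
    grid, G = gcv_curve(bundle, frame, grid)
    flags = _flat_flags(grid, G)
    if "flat-curve" in flags:
        near = G <= np.min(G) * (1.0 + _PLATEAU_RTOL)
        idx = int(np.max(np.nonzero(near)[0]))  # largest grid point on the shelf
    else:
        interior = _best_interior_minimum(G)
        idx = interior if interior is not None else _capped_argmin(grid, G, bundle)
    return SelectionResult(lam=float(grid[idx]), index=idx, criterion="GCV", flags=flags)


def rgcv_curve(bundle, frame: int = 0, gamma: float = 0.0, grid=None):
    """R(lambda) = [gamma + (1 - gamma) xi(lambda)] G(lambda)."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    grid, G = gcv_curve(bundle, frame, grid)
    xi = influence_trace(bundle, grid)
    return grid, (gamma + (1.0 - gamma) * xi) * G


def rgcv_lambda(bundle, frame: int = 0, gamma: float = 0.0, grid=None) -> SelectionResult:
    """Minimizer of robust GCV; gamma = 0 is the robust default, gamma = 1
    reduces identically to GCV."""
    grid, R = rgcv_curve(bundle, frame, gamma, grid)
    flags = _flat_flags(grid, R)
    if "flat-curve" in flags:
        near = R <= np.min(R) * (1.0 + _PLATEAU_RTOL)
        idx = int(np.max(np.nonzero(near)[0]))
    else:
        interior = _best_interior_minimum(R)
        idx = interior if interior is not None else _capped_argmin(grid, R, bundle)
    return SelectionResult(lam=float(grid[idx]), index=idx, criterion="RGCV", flags=flags)


# ---------------------------------------------------------------------------
# CRESO
# ---------------------------------------------------------------------------


def creso_curve(bundle, frame: int = 0, grid=None):
    """C(lambda) = d/d(lambda^2) [lambda^2 eta(lambda) - rho(lambda)].

    Closed spectral form: sum_i s_i^2 c_i^2 (s_i^2 - 3 lambda^2) /
    (s_i^2 + lambda^2)^3 over finite spectral values s_i with coefficients
    c_i (the out-of-range residual term is constant in lambda and drops).
    """
    grid = _grid(bundle, grid)
    if isinstance(bundle, SvdBundle):
        s, c = bundle.sigma, bundle.mu[:, frame]
    else:
        s, c = bundle.gsv[bundle.finite], bundle.alpha[bundle.finite, frame]
    L = grid[:, None]
    C = np.sum(s**2 * c**2 * (s**2 - 3 * L**2) / (s**2 + L**2) ** 3, axis=1)
    return grid, C


def creso_lambda(bundle, frame: int = 0, grid=None) -> SelectionResult:
    """First interior strict local maximum of C, scanning lambda upward."""
    from scipy.signal import find_peaks

    grid, C = creso_curve(bundle, frame, grid)
    rng = float(np.max(C) - np.min(C))
    peaks, _ = find_peaks(C, prominence=1e-9 * rng) if rng > 0 else (np.array([], int), None)
    if len(peaks):
        idx = int(peaks[0])  # first local maximum scanning lambda upward
        flags: tuple[str, ...] = ()
    else:
        idx = int(np.argmax(C))
        flags = ("no-local-maximum",)
    return SelectionResult(lam=float(grid[idx]), index=idx, criterion="CRESO", flags=flags)


# ---------------------------------------------------------------------------
# U-curve
# ---------------------------------------------------------------------------


def ucurve_curve(bundle, frame: int = 0, grid=None):
    """U(lambda) = 1/rho(lambda) + 1/eta(lambda)."""
    grid = _grid(bundle, grid)
    rho = residual_curve(bundle, grid, frame)
    eta = seminorm_curve(bundle, grid, frame)
    with np.errstate(divide="ignore"):
        return grid, 1.0 / rho + 1.0 / eta


def ucurve_lambda(bundle, frame: int = 0, grid=None) -> SelectionResult:
    """U-curve minimizer restricted to [delta_n^(2/3), delta_1^(2/3)].

    delta_1 / delta_n are the largest / smallest nonzero finite
    (generalized) singular values; the U-curve is strictly decreasing left
    of the interval and increasing right of it, so the minimum is interior.
    Grid points with rho = 0 (noise-free square systems) are excluded.
    """
    grid, U = ucurve_curve(bundle, frame, grid)
    if isinstance(bundle, SvdBundle):
        s = bundle.sigma
    else:
        s = bundle.gsv[bundle.finite]
    s = s[s > (s.max() if len(s) else 0) * 1e-15]
    if len(s) == 0:
        raise ValueError("no nonzero spectral values: U-curve undefined")
    lo, hi = float(np.min(s)) ** (2.0 / 3.0), float(np.max(s)) ** (2.0 / 3.0)
    inside = (grid >= lo) & (grid <= hi) & np.isfinite(U)
    if not np.any(inside):
        # interval narrower than the grid spacing: take the nearest point
        mid = np.sqrt(lo * hi)
        inside = np.zeros_like(inside)
        inside[int(np.argmin(np.abs(np.log(grid / mid))))] = True
    if not np.any(np.isfinite(U[inside])):
        raise ValueError("rho or eta vanishes on the whole U-curve search interval")
    cand = np.nonzero(inside)[0]
    idx = int(cand[_argmin_prefer_large(U[cand])])
    return SelectionResult(lam=float(grid[idx]), index=idx, criterion="UCurve")


# ---------------------------------------------------------------------------
# ADPC
# ---------------------------------------------------------------------------


def adpc_lambda(bundle, degree: int = 5, grid=None) -> SelectionResult:
    """Automatic discrete-Picard-condition choice over all attached frames.

    Per frame, the log moduli of the spectral coefficients |u_i^T b_t| (or
    |p_i^T b_t|) are fitted with a low-degree polynomial p_t(i) in the
    decreasing-spectral-value indexing; the Picard break is the last index
    k such that log s_i >= p_t(i) for all i <= k, and alpha_t = s_k.  The
    chosen lambda is the median of the alpha_t.

    Both curves are normalized to their leading values (s_i / s_0 and
    |c_i| / max|c_i|) before comparison: the discrete Picard condition is
    a statement about relative decay rates, and the raw curves carry
    incommensurate units (singular values of A versus millivolt-scale
    data), so the unnormalized comparison would depend on the arbitrary
    scale of b.
    """
    if degree not in (5, 6, 7):
        raise ValueError("polynomial degree must be 5, 6 or 7")
    if isinstance(bundle, SvdBundle):
        s = bundle.sigma
        coefs = bundle.mu
    else:
        fin = bundle.finite
        # relabel so spectral values decrease with index, as for the SVD
        order = np.argsort(-bundle.gsv[fin], kind="stable")
        s = bundle.gsv[fin][order]
        coefs = bundle.alpha[fin][order]
    live = s > s[0] * 1e-15
    s = s[live]
    coefs = coefs[live]
    if coefs.shape[1] < 1:
        raise ValueError("ADPC needs at least one frame")
    alphas = []
    flags: list[str] = []
    idxs = np.arange(len(s), dtype=float)
    logs = np.log10(s / s[0])
    for t in range(coefs.shape[1]):
        c = np.abs(coefs[:, t])
        usable = c > 1e-300
        if not np.any(usable):
            flags.append(f"frame-{t}-skipped")
            continue
        if usable.sum() <= degree:
            flags.append(f"frame-{t}-skipped")
            continue
        c = c / c[usable].max()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            poly = np.polynomial.Polynomial.fit(idxs[usable], np.log10(c[usable]), degree)
        ok = logs >= poly(idxs)
        if not ok[0]:
            alphas.append(float(s[0]))
            flags.append(f"frame-{t}-no-picard-range")
            continue
        first_bad = np.argmin(ok) if not ok.all() else len(ok)
        alphas.append(float(s[first_bad - 1]))
    if not alphas:
        raise ValueError("ADPC: every frame was skipped (all-zero coefficients)")
    lam = float(np.median(alphas))
    return SelectionResult(lam=lam, index=-1, criterion="ADPC", flags=tuple(flags))


CRITERIA = ("GCV", "RGCV", "CRESO", "UCurve", "ADPC")


def selection_curve(
    bundle, frame: int = 0, gamma: float = 0.0, degree: int = 5, grid=None
) -> SelectionCurve:
    """Evaluate every criterion on one shared grid and record the choices."""
    grid = _grid(bundle, grid)
    rho = residual_curve(bundle, grid, frame)
    eta = seminorm_curve(bundle, grid, frame)
    _, G = gcv_curve(bundle, frame, grid)
    xi = influence_trace(bundle, grid)
    _, R = rgcv_curve(bundle, frame, gamma, grid)
    _, C = creso_curve(bundle, frame, grid)
    with np.errstate(divide="ignore"):
        U = 1.0 / rho + 1.0 / eta
    chosen = {
        "GCV": gcv_lambda(bundle, frame, grid),
        "RGCV": rgcv_lambda(bundle, frame, gamma, grid),
        "CRESO": creso_lambda(bundle, frame, grid),
        "UCurve": ucurve_lambda(bundle, frame, grid),
        "ADPC": adpc_lambda(bundle, grid=grid),
    }
    return SelectionCurve(
        grid=grid, rho=rho, eta=eta, G=G, R=R, xi=xi, C=C, ucurve=U, gamma=gamma, chosen=chosen
    )
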