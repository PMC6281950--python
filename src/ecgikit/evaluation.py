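"""Metrics, preprocessing and pacing-site localization.

Reconstruction quality is summarized by the relative error
RE = ||x_c - x_e|| / ||x_e|| and the Pearson correlation coefficient CC
between computed (x_c) and known (x_e) potentials, evaluated spatially
(per frame, over epicardial vertices) and temporally (per vertex, over
frames).  Transfer-matrix fidelity is summarized by
RE_d = ||A x_exact - b|| / ||b||.

Preprocessing mirrors what tank recordings need before inversion:
electrodes pressed into the epicardium produce ischemic, monophasic
signals and are discarded by a plateau-amplitude threshold; missing
electrode values are filled by discrete-harmonic (graph Laplacian)
interpolation over the mesh.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse import coo_matrix, identity
from scipy.sparse.linalg import spsolve

from .geometry import SurfaceMesh, geodesic_distance

__all__ = [
    "EvaluationReport",
    "relative_error",
    "correlation_coefficient",
    "transfer_residual",
    "threshold_ischemic_electrodes",
    "interpolate_missing",
    "detect_pacing_site",
    "localization_error",
    "evaluate_frames",
]


def relative_error(x_c: np.ndarray, x_e: np.ndarray) -> float:
    """RE = ||x_c - x_e|| / ||x_e||."""
    x_c = np.asarray(x_c, dtype=float)
    x_e = np.asarray(x_e, dtype=float)
    if x_c.shape != x_e.shape or x_c.ndim != 1 or len(x_c) < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    denom = np.linalg.norm(x_e)
    if denom == 0:
        raise ValueError("reference vector has zero norm")
    return float(np.linalg.norm(x_c - x_e) / denom)


def correlation_coefficient(x_c: np.ndarray, x_e: np.ndarray) -> float:
    """Centered cosine (Pearson) correlation between the two patterns."""
    x_c = np.asarray(x_c, dtype=float)
    x_e = np.asarray(x_e, dtype=float)
    if x_c.shape != x_e.shape or x_c.ndim != 1 or len(x_c) < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    a = x_c - x_c.mean()
    b = x_e - x_e.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance input")
    return float(a @ b / (na * nb))


def transfer_residual(A: np.ndarray, x_exact: np.ndarray, b: np.ndarray) -> float:
    """RE_d = ||A x_exact - b|| / ||b||, the forward-model data mismatch."""
    b = np.asarray(b, dtype=float)
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("zero measurement vector")
    return float(np.linalg.norm(np.asarray(A) @ np.asarray(x_exact, dtype=float) - b) / nb)


def threshold_ischemic_electrodes(
    signals: np.ndarray,
    pacing_time: int,
    plateau_offset: int,
    fraction: float = 0.5,
) -> np.ndarray:
    """Drop electrodes whose plateau amplitude exceeds half the maximum.

    ``signals`` is electrodes x time; the plateau sample is
    ``pacing_time + plateau_offset`` (offset in samples, e.g. 250 ms worth).
    Electrodes with |signal| strictly above fraction * max(|signal|) at that
    sample are excluded; the kept indices are returned in order.
    """
    signals = np.asarray(signals, dtype=float)
    t = pacing_time + plateau_offset
    if not 0 <= t < signals.shape[1]:
        raise IndexError("plateau sample outside the recording")
    amp = np.abs(signals[:, t])
    cutoff = fraction * amp.max()
    kept = np.nonzero(~(amp > cutoff))[0] if cutoff > 0 else np.arange(len(amp))
    if len(kept) == 0:
        raise ValueError("thresholding removed every electrode")
    return kept


def _cotangent_laplacian(mesh: SurfaceMesh):
    """Cotangent-weight graph Laplacian; uniform weights on degenerate
    triangles."""
    n = mesh.n_vertices
    tris = mesh.triangles
    v = mesh.vertices
    I, J, W = [], [], []
    for k in range(3):
        i, j, o = tris[:, k], tris[:, (k + 1) % 3], tris[:, (k + 2) % 3]
        a = v[i] - v[o]
        b = v[j] - v[o]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        dot = np.einsum("ij,ij->i", a, b)
        cot = np.where(cross > 1e-12, dot / np.maximum(cross, 1e-300), 1.0)
        I.extend([i, j])
        J.extend([j, i])
        W.extend([0.5 * cot, 0.5 * cot])
    W = np.concatenate(W)
    I = np.concatenate(I)
    J = np.concatenate(J)
    A = coo_matrix((W, (I, J)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    from scipy.sparse import diags

    return diags(deg) - A


def interpolate_missing(
    mesh: SurfaceMesh, known_vertices: np.ndarray, known_values: np.ndarray
) -> np.ndarray:
    """Fill unknown vertex values by discrete-harmonic interpolation.

    Unknown values solve the cotangent-Laplacian system with the known
    values as Dirichlet constraints, per frame (columns of
    ``known_values``).  By the discrete maximum principle the filled
    values lie within the range of the known ones.
    """
    known_vertices = np.asarray(known_vertices, dtype=int)
    if known_vertices.size == 0:
        raise ValueError("no known vertices to interpolate from")
    vals = np.asarray(known_values, dtype=float)
    single = vals.ndim == 1
    if single:
        vals = vals[:, None]
    if vals.shape[0] != len(known_vertices):
        raise ValueError("known_values rows must match known_vertices")
    n = mesh.n_vertices
    out = np.empty((n, vals.shape[1]))
    out[known_vertices] = vals
    unknown = np.setdiff1d(np.arange(n), known_vertices)
    if len(unknown):
        Lap = _cotangent_laplacian(mesh).tocsr()
        Luu = Lap[unknown][:, unknown].tocsc()
        Luk = Lap[unknown][:, known_vertices]
        sol = spsolve(Luu + 1e-14 * identity(len(unknown)), -Luk @ vals)
        out[unknown] = sol if sol.ndim == 2 else np.atleast_2d(sol).reshape(len(unknown), -1)
    return out[:, 0] if single else out


def detect_pacing_site(
    potentials: np.ndarray, mode: str = "min", spread_fraction: float = 0.05
) -> int | None:
    """Locate the paced vertex from a reconstructed frame.

    The default rule takes the most negative potential at the pacing frame
    (the earliest-depolarizing region of a unipolar electrogram); an
    alternative ``mode="dvdt"`` takes the steepest negative temporal
    derivative (pass a vertices x time window).  When the potential spread
    is below ``spread_fraction`` of the frame's dynamic range the detection
    is indeterminate and None is returned (the reconstruction contains no
    usable extremum).
    """
    potentials = np.asarray(potentials, dtype=float)
    if mode == "dvdt":
        if potentials.ndim != 2 or potentials.shape[1] < 2:
            raise ValueError("dvdt mode needs a vertices x time window")
        rate = np.min(np.diff(potentials, axis=1), axis=1)
        frame = rate
    elif mode == "min":
        frame = potentials if potentials.ndim == 1 else potentials[:, 0]
    else:
        raise ValueError("mode must be 'min' or 'dvdt'")
    rng = float(frame.max() - frame.min())
    scale = float(np.abs(frame).max())
    if scale == 0 or rng < spread_fraction * max(rng, scale):
        return None
    return int(np.argmin(frame))


def localization_error(mesh: SurfaceMesh, true_site: int, detected_site: int) -> float:
    """Geodesic distance between true and detected pacing vertices."""
    return geodesic_distance(mesh, true_site, detected_site)


@dataclasses.dataclass
class EvaluationReport:
    """Per-frame and per-vertex RE/CC with summary statistics."""

    spatial_re: np.ndarray  # (T,)
    spatial_cc: np.ndarray  # (T,)
    temporal_re: np.ndarray  # (n,)
    temporal_cc: np.ndarray  # (n,)
    re_d: np.ndarray | None = None  # (T,)
    pacing_true: int | None = None
    pacing_detected: int | None = None
    pacing_error: float | None = None

    @property
    def summary(self) -> dict[str, float]:
        out = {
            "spatial_re_mean": float(np.mean(self.spatial_re)),
            "spatial_re_std": float(np.std(self.spatial_re)),
            "spatial_cc_mean": float(np.mean(self.spatial_cc)),
            "spatial_cc_std": float(np.std(self.spatial_cc)),
            "temporal_re_mean": float(np.mean(self.temporal_re)),
            "temporal_re_std": float(np.std(self.temporal_re)),
            "temporal_cc_mean": float(np.mean(self.temporal_cc)),
            "temporal_cc_std": float(np.std(self.temporal_cc)),
        }
        if self.re_d is not None:
            out["re_d_mean"] = float(np.mean(self.re_d))
        if self.pacing_error is not None:
            out["pacing_error"] = float(self.pacing_error)
        return out


def evaluate_frames(
    X_computed: np.ndarray, X_exact: np.ndarray, A: np.ndarray | None = None,
    B: np.ndarray | None = None,
) -> EvaluationReport:
    """Spatial (per frame) and temporal (per vertex) RE/CC between a
    reconstructed and a reference vertices x frames matrix."""
    Xc = np.atleast_2d(np.asarray(X_computed, dtype=float))
    Xe = np.atleast_2d(np.asarray(X_exact, dtype=float))
    if Xc.shape != Xe.shape:
        raise ValueError("shape mismatch between computed and exact potentials")
    sp_re = np.array([relative_error(Xc[:, t], Xe[:, t]) for t in range(Xc.shape[1])])
    sp_cc = np.array(
        [correlation_coefficient(Xc[:, t], Xe[:, t]) for t in range(Xc.shape[1])]
    )
    tm_re = np.array([relative_error(Xc[i], Xe[i]) for i in range(Xc.shape[0])])
    tm_cc = np.array(
        [correlation_coefficient(Xc[i], Xe[i]) for i in range(Xc.shape[0])]
    )
    re_d = None
    if A is not None and B is not None:
        B2 = np.atleast_2d(np.asarray(B, dtype=float))
        re_d = np.array(
            [transfer_residual(A, Xe[:, t], B2[:, t]) for t in range(B2.shape[1])]
        )
    return EvaluationReport(
        spatial_re=sp_re, spatial_cc=sp_cc, temporal_re=tm_re, temporal_cc=tm_cc, re_d=re_d
    )
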