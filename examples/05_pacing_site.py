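"""Pacing-site localization from reconstructed epicardial potentials.

A paced-wavefront phantom is inverted with MFS + GCV shortly after the
stimulus; the most negative reconstructed potential marks the earliest
depolarized site and its geodesic distance to the true pacing vertex is
the localization error.
"""

import numpy as np

from ecgikit import param_selection as ps
from ecgikit.evaluation import detect_pacing_site, localization_error
from ecgikit.forward_models import (
    build_mfs_transfer,
    choose_mfs_sources,
    mfs_reconstruct_epicardial,
)
from ecgikit.geometry import mean_edge_length
from ecgikit.regularizers import solve_zot
from ecgikit.spectral import compute_svd
from ecgikit.synthetic_data import make_phantom

pacing_vertex, pace_frame = 7, 4
phantom = make_phantom(kind="paced", seed=3, snr_db=20.0, frames=10,
                       pacing_vertex=pacing_vertex)
mfs = build_mfs_transfer(
    phantom.heart, phantom.torso, inflation=1.5, deflation=0.6,
    heart_source_idx=choose_mfs_sources(phantom.heart, phantom.torso,
                                        2 * phantom.torso.n_vertices),
)
bundle = compute_svd(mfs.A, mfs.stack_rhs(phantom.B_noisy))
lam = ps.gcv_lambda(bundle, pace_frame).lam
x = mfs_reconstruct_epicardial(mfs, solve_zot(bundle, pace_frame, lam).x)

detected = detect_pacing_site(x)
err = localization_error(phantom.heart, pacing_vertex, detected)
edge = mean_edge_length(phantom.heart)
print(f"true pacing vertex: {pacing_vertex}   detected: {detected}")
print(f"geodesic error: {err:.1f} mm  ({err / edge:.2f} mean edge lengths)")
print(f"realized SNR: {phantom.realized_snr_db():.1f} dB")

# An error of zero means the exact vertex was found; errors are judged
# against the mesh's mean edge length, the spatial resolution limit of
# the phantom.
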