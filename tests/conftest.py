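"""Shared fixtures: desk-scale geometries, phantoms and reconstructions.

Everything is generated programmatically; expensive end-to-end artifacts
(simulated scans, reconstructions, denoised volumes) are session-scoped so
several tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from minltv.core import GridSpec, ScanGeometry
from minltv.denoise import DenoiseParams, denoise
from minltv.phantom import default_catphan_spec, make_catphan_like, simulate_projections
from minltv.pipeline import phantom_rois
from minltv.recon import mu_to_hu, reconstruct_fbp


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def desk_geometry() -> ScanGeometry:
    """60-view full-scan cone-beam geometry with a 128x128 detector."""
    return ScanGeometry.circular(
        n_views=60, arc_deg=360.0, sad=1000.0, sdd=1536.0,
        det_nu=128, det_nv=128, det_du=1.6, det_dv=1.0,
    )


@pytest.fixture()
def desk_grid() -> GridSpec:
    return GridSpec.centered((16, 96, 96), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def study():
    """Low-dose Catphan-like study: truth, per-seed RDB reconstructions and
    their MI-NLTV denoised counterparts (seeds 1-3, I0 = 2e4)."""
    grid = GridSpec.centered((16, 96, 96), (1.0, 1.0, 1.0))
    geo = ScanGeometry.circular(
        n_views=60, arc_deg=360.0, sad=1000.0, sdd=1536.0,
        det_nu=128, det_nv=128, det_du=1.6, det_dv=1.0,
    )
    spec = default_catphan_spec(z_extent=(-7.5, 7.5))
    truth = make_catphan_like(grid, spec)
    rois = phantom_rois(spec, grid)
    runs = {}
    for seed in (1, 2, 3):
        proj = simulate_projections(truth, geo, i0=2e4, seed=seed)
        proj = proj.with_data(proj.data, stage="raw")
        rec = reconstruct_fbp(proj, grid, "rdb")
        dn, states = denoise(rec, DenoiseParams())
        runs[seed] = {
            "recon_hu": mu_to_hu(rec),
            "denoised_hu": mu_to_hu(dn),
            "recon_mu": rec,
            "denoised_mu": dn,
            "states": states,
        }
    return {"grid": grid, "geometry": geo, "spec": spec, "truth": truth,
            "rois": rois, "runs": runs}
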