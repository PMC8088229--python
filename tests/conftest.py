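import numpy as np
import pytest

import flatsphere as fs

# reference parameters: a mouse-eye-sized sphere with a typical distortion
# coefficient (k conventionally reported as k/2pi)
R_REF = 1.58
K_REF = 2 * np.pi * 0.1355


def binning_gap_oracle(mask, origin, scale_um_per_px, radii_px):
    """Brute-force gap measurement: bin every pixel by its rounded distance
    to the origin and take the background fraction per bin.

    Independent of the ring rasterizer used by ``measure_gap_profile``.
    """
    h, w = mask.shape
    ys, xs = np.mgrid[0:h, 0:w]
    d = np.round(np.hypot(xs - origin[0], ys - origin[1])).astype(int)
    maxr = int(np.ceil(np.max(radii_px))) + 1
    cnt = np.bincount(d.ravel(), minlength=maxr + 1).astype(float)
    bg = np.bincount(d.ravel(), weights=mask.ravel().astype(float), minlength=maxr + 1)
    frac = bg[: maxr + 1] / np.maximum(cnt[: maxr + 1], 1.0)
    r_int = np.round(np.asarray(radii_px)).astype(int)
    L_mm = np.asarray(radii_px) * scale_um_per_px / 1000.0
    return frac[r_int] * 2.0 * np.pi * L_mm


def aggregate_rel_err(measured, reference):
    """Cohort-level relative error sum|d|/sum(ref); robust where ref -> 0."""
    measured = np.asarray(measured)
    reference = np.asarray(reference)
    return float(np.sum(np.abs(measured - reference)) / np.sum(reference))


@pytest.fixture(scope="session")
def rendered_sample():
    """A 4-lobe flatmount rendered at 5 um/px with known (R, k)."""
    return fs.render_flatmount(R_REF, K_REF, seed=3, scale_um_per_px=5.0)


@pytest.fixture(scope="session")
def rendered_mask(rendered_sample):
    return fs.segment_tissue(rendered_sample.image)


@pytest.fixture(scope="session")
def rendered_profile(rendered_sample, rendered_mask):
    return fs.measure_gap_profile(
        rendered_mask, rendered_sample.annotations, rendered_sample.scale_um_per_px
    )


@pytest.fixture(scope="session")
def noiseless_profile():
    """Exact forward-simulated profile at the reference parameters."""
    return fs.simulate_profile(R_REF, K_REF, M_min=0.65 * np.pi * R_REF)
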