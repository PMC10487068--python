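import numpy as np
import pytest

from caseoscan import imaging, synthetic


@pytest.fixture(scope="session")
def porosity_slice():
    """Synthetic defective-cheese slice planted at 0.26 % porosity, segmented."""
    img, truth = synthetic.porosity_fixture(seed=11)
    regions = imaging.segment_openings(img)
    return img, truth, regions


@pytest.fixture(scope="session")
def twelve_ellipse_slice():
    """The 12-ellipse eye/crack benchmark slice, segmented."""
    img, truth = synthetic.twelve_ellipse_fixture(seed=11)
    regions = imaging.segment_openings(img)
    return img, truth, regions


@pytest.fixture(scope="session")
def ndc_noisy_decay():
    """Reference 4-population decay at SNR 1000 (benchmark acquisition)."""
    return synthetic.make_cpmg_decay(snr=1000.0, seed=0)


@pytest.fixture(scope="session")
def ndc_noiseless_decay():
    return synthetic.make_cpmg_decay(snr=None)


def dummy_regions(areas, eccentricities=None):
    """OpeningRegion list with given areas (helper for summary tests)."""
    areas = np.asarray(areas, dtype=float)
    if eccentricities is None:
        eccentricities = np.zeros_like(areas)
    regs = []
    for i, (a, e) in enumerate(zip(areas, eccentricities)):
        regs.append(
            imaging.OpeningRegion(
                label=i + 1,
                pixel_set=np.zeros((3, 2)),
                area_mm2=float(a),
                centroid=(0.0, 0.0),
                major_axis_a=1.0,
                foci_distance_c=float(e),
                eccentricity_e=float(e),
                opening_class=imaging.classify_opening(float(e)),
            )
        )
    return regs
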