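import numpy as np
import pandas as pd
import pytest

from telofish.simulate import (AcquisitionSpec, CompartmentSpec, SpecimenSpec,
                               simulate_specimen)


def small_acquisition(**overrides) -> AcquisitionSpec:
    """Compact field used by unit tests (full-size defaults are exercised in
    the acceptance suite)."""
    base = dict(width=512, height=512)
    base.update(overrides)
    return AcquisitionSpec(**base)


def small_compartments(n_epithelial=16, n_stromal=12, ratio=0.9,
                       spots_lambda=8.0, radius=12.0):
    stromal = CompartmentSpec(compartment="stromal", n_cells=n_stromal,
                              arrangement="scattered",
                              nucleus_radius_mean=radius,
                              spots_per_cell_lambda=spots_lambda)
    epi = CompartmentSpec(compartment="epithelial", subtype="non-mucus",
                          n_cells=n_epithelial, arrangement="crypt-ring",
                          nucleus_radius_mean=radius,
                          spots_per_cell_lambda=spots_lambda,
                          spot_intensity_mu=stromal.spot_intensity_mu
                          + float(np.log(ratio)))
    return (epi, stromal)


@pytest.fixture(scope="session")
def noisy_specimen():
    """One default-noise specimen with its ground truth (session-cached)."""
    spec = SpecimenSpec("unit_s1", "test", small_acquisition(),
                        small_compartments(48, 36), seed=11)
    cy3, dapi, labels, truth = simulate_specimen(spec)
    return spec, cy3, dapi, labels, truth


@pytest.fixture(scope="session")
def clean_specimen():
    """Noise-free, blur-free, background-free specimen: the Cy3 integral over
    each ROI equals T_true exactly, so measurement is checkable to
    floating-point accuracy."""
    acq = small_acquisition(psf_sigma=0.0, background_offset=0.0,
                            background_gradient=0.0, read_noise_sd=0.0,
                            shot_noise=False)
    spec = SpecimenSpec("unit_clean", "test", acq,
                        small_compartments(spots_lambda=4.0), seed=5)
    cy3, dapi, labels, truth = simulate_specimen(spec)
    return spec, cy3, dapi, labels, truth


def cell_table(rows):
    """Build a tidy cell table from (specimen, image, label, compartment,
    subtype, tfi) tuples."""
    return pd.DataFrame(rows, columns=["specimen_id", "image_id", "cell_label",
                                       "compartment", "subtype", "tfi"]) \
        .assign(tissue_class="t")
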