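import logging
import os

import numpy as np
import pytest

import spinflux as sf

# per-spectrum baseline warnings are expected on noisy fixtures; keep the
# test log readable
logging.getLogger("spinflux").setLevel(logging.ERROR)
logging.getLogger().setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def grid():
    """Default 33 mT / 1024-point X-band field grid."""
    return sf.default_grid()


@pytest.fixture(scope="session")
def fine_grid():
    """Finer grid for analytic moment checks."""
    return sf.default_grid(n=4096)


def gaussian_absorption_spectrum(grid, center=335.0, sigma=0.5):
    """Spectrum whose derivative is that of a unit-area Gaussian line."""
    from spinflux.synth import _gauss_deriv

    return sf.Spectrum(grid, _gauss_deriv(grid - center, sigma), {})


@pytest.fixture(scope="session")
def noiseless_titration():
    """Default titration ground truth, no noise/baseline, fully analyzed."""
    truth = sf.TitrationGroundTruth(noise_sd=0.0, baseline_coeffs=())
    spectra = sf.simulate_titration(truth)
    processed = {}
    for c, labeling, spec in spectra:
        corrected, _ = sf.baseline_correct(spec)
        processed[(c, labeling)] = (corrected, sf.integrate(corrected))
    return truth, spectra, processed


def write_titration_dir(truth, directory):
    """Materialize a simulated titration as native files + manifest."""
    entries = []
    for c, labeling, spec in sf.simulate_titration(truth):
        fname = f"lpc{c:g}_{labeling}.dat"
        sf.write_spectrum(spec, os.path.join(directory, fname))
        entries.append(sf.ManifestEntry(fname, c, labeling, "sample"))
    manifest = sf.TitrationManifest(entries)
    path = os.path.join(directory, "manifest.csv")
    sf.write_manifest(manifest, path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
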