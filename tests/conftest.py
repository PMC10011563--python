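import warnings

import numpy as np
import pandas as pd
import pytest

import chertspec as cs

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def assemblage():
    """Default synthetic assemblage (40 eukaryotes / 9 prokaryotes), seed 11."""
    cfg = cs.AssemblageConfig(seed=11)
    sset, truth = cs.generate_assemblage(cfg)
    return cfg, sset, truth


@pytest.fixture(scope="session")
def preprocessed(assemblage):
    """Feature matrix, segmented spectra and anchor reports for the fixture."""
    _, sset, _ = assemblage
    matrix, segs, reports = cs.preprocess_pipeline(sset)
    return matrix, segs, reports


@pytest.fixture(scope="session")
def labels(assemblage):
    _, sset, _ = assemblage
    return pd.Series(sset.groups(), index=sset.specimen_ids, name="group")


@pytest.fixture(scope="session")
def ratios(preprocessed):
    _, segs, _ = preprocessed
    return cs.ratio_table(segs)


def single_band_spectrum(center=2960.0, amplitude=1.0, fwhm=20.0,
                         lo=650.0, hi=4000.0, step=1.0, specimen_id="one_band"):
    """A bare Gaussian band on a zero baseline (helper, not a fixture)."""
    w = np.arange(lo, hi + step / 2, step)
    y = amplitude * np.exp(-4 * np.log(2) * ((w - center) / fwhm) ** 2)
    return cs.Spectrum(specimen_id, w, y)
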