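import numpy as np
import pytest

from fwavekit.simulate import gen_fwave, gen_ventricular, make_fwave_params


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_mixture():
    """2-s pulse-train + modulated-sinusoid mixture with known parts."""
    fs, n = 500.0, 1000
    t = np.arange(n) / fs
    osc = (1.0 + 0.3 * np.sin(2 * np.pi * 0.3 * t)) * np.sin(2 * np.pi * 8 * t)
    trn = np.zeros(n)
    for c in np.arange(0.3, 1.9, 0.4):
        trn += 3.0 * np.exp(-0.5 * ((t - c) / 0.012) ** 2)
        trn -= 1.5 * np.exp(-0.5 * ((t - c - 0.05) / 0.015) ** 2)
    return osc, trn, osc + trn, fs


@pytest.fixture(scope="session")
def af_record_parts():
    """10-s type-B F-wave + synthetic ventricular activity, separate parts."""
    fw = gen_fwave(make_fwave_params("B", "II"), 5000)
    vent, ann = gen_ventricular(10.0, seed=3)
    return fw, vent, ann
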