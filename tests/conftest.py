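import numpy as np
import pytest

import tuberelax as tx
from tuberelax.phantom import DEFAULT_MIXTURES, mixture_signal
from tuberelax.relaxometry import DecayCurve

#: 32-DASE control mixtures used throughout (fraction, T2 ms) and the
#: printed means/SDs they must be recovered against.
CONTROL_MIXES = {
    "cortex": ((0.19, 64.0), (0.81, 268.0)),
    "flesh": ((0.24, 61.0), (0.76, 268.0)),
    "pith": ((0.12, 52.0), (0.88, 353.0)),
}
PRINTED = {  # (i0_rel_2 mean, sd), (t2_1 mean, sd), (t2_2 mean, sd)
    "cortex": {"i0_rel_2": (81.0, 2.0), "t2_1": (64.0, 17.0), "t2_2": (268.0, 4.0)},
    "flesh": {"i0_rel_2": (76.0, 2.0), "t2_1": (61.0, 11.0), "t2_2": (268.0, 4.0)},
    "pith": {"i0_rel_2": (88.0, 2.0), "t2_1": (52.0, 15.0), "t2_2": (353.0, 15.0)},
}
TE_MS = 6.5
N_ECHOES = 256


def make_curve(components, noise_frac=0.0, seed=0, te_ms=TE_MS, n_echoes=N_ECHOES,
               amplitude=1.0):
    """Synthetic ROI decay curve with optional Rician noise.

    ``noise_frac`` is sigma as a fraction of the first-echo signal; the
    curve's noise_sigma_est is set to the true sigma.
    """
    t = te_ms * np.arange(1, n_echoes + 1)
    y = amplitude * mixture_signal(components, t)
    sigma = noise_frac * y[0]
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = tx.phantom.rician(y, sigma, rng)
    return DecayCurve(echo_times=t, signal=y, n_pixels=1,
                      noise_sigma_est=sigma if sigma > 0 else 1e-12)


def fit_curve(components, noise_frac, seed):
    """Truncate-at-SNR-7 + model selection on one synthetic curve."""
    curve = make_curve(components, noise_frac=noise_frac, seed=seed)
    kept = tx.truncate_by_snr(curve, snr_min=7.0)
    return tx.select_model(kept)


@pytest.fixture(scope="session")
def default_phantom():
    """Default 8-tuber phantom at sigma = 2 (2 % of peak), seed 1."""
    spec = tx.default_phantom_spec(noise_sigma=2.0, seed=1)
    img, truth = tx.generate_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def segmented_phantom(default_phantom):
    spec, img, truth = default_phantom
    labels = tx.segment_tissues(img)
    return spec, img, truth, labels


@pytest.fixture(scope="session")
def replicate_fits():
    """Full phantom -> segmentation -> fit chain over seeds 1-4.

    Returns the concatenated tidy fits table with a ``seed`` column.
    """
    import pandas as pd
    tables = []
    for seed in (1, 2, 3, 4):
        spec = tx.default_phantom_spec(noise_sigma=2.0, seed=seed)
        img, _ = tx.generate_phantom(spec)
        labels = tx.segment_tissues(img)
        t = tx.fit_all_tissues(img, labels)
        t["seed"] = seed
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


def dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
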