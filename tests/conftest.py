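import numpy as np
import pytest

from telomr.summary_io import HarmonizedVariant, InstrumentSet


def build_set(x, y, sigma_y, sigma_x=None, snp_ids=None) -> InstrumentSet:
    """Build a harmonized instrument set straight from effect arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sigma_y = np.asarray(sigma_y, dtype=float)
    if sigma_x is None:
        sigma_x = np.full_like(x, 0.01)
    else:
        sigma_x = np.broadcast_to(np.asarray(sigma_x, dtype=float), x.shape)
    if snp_ids is None:
        snp_ids = [f"rs{i:04d}" for i in range(len(x))]
    return InstrumentSet([
        HarmonizedVariant(snp_id=s, long_allele="A", x=float(xi),
                          sigma_x=float(sxi), y=float(yi), sigma_y=float(syi))
        for s, xi, sxi, yi, syi in zip(snp_ids, x, sigma_x, y, sigma_y)])


@pytest.fixture
def three_snp_set():
    """Small set whose IVW solution is known from the WLS oracle."""
    return build_set([0.1, 0.05, 0.2], [0.05, 0.04, 0.12],
                     [0.02, 0.03, 0.05])


@pytest.fixture
def proportional_set():
    """y exactly proportional to x with equal outcome SEs: zero
    heterogeneity by construction."""
    x = np.array([0.05, 0.07, 0.09, 0.11, 0.12])
    return build_set(x, 0.8 * x, np.full(5, 0.03))
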