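import numpy as np
import pytest

from calseize.preprocess import DffTrace

FS = 1.33


def make_dff(dff_pct, fs=FS, larva_id="L0", group="control"):
    """Wrap a raw dF/F0 array in a DffTrace (unit baseline)."""
    dff_pct = np.asarray(dff_pct, dtype=float)
    return DffTrace(
        larva_id=larva_id,
        sampling_rate_hz=fs,
        baseline=np.ones_like(dff_pct) * 100.0,
        dff_pct=dff_pct,
        window_s=150.0,
        group=group,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_trace():
    """Symmetric triangle 0 -> 150% -> 0, rising over 30 s, at 1 Hz.

    50% crossings sit analytically at t=10 s and t=50 s.
    """
    t = np.arange(80, dtype=float)  # 1 Hz
    dff = np.where(t <= 30, 150.0 * t / 30.0, np.maximum(150.0 * (2 - t / 30.0), 0.0))
    return make_dff(dff, fs=1.0)
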