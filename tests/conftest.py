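import numpy as np
import pytest

from vepdecode.sim import (SessionSpec, VEPModel, make_session_events,
                           synthesize_recording)


@pytest.fixture(scope="session")
def tiny_spec() -> SessionSpec:
    """4 classes x 5 images: 20 trials, one minute of signal."""
    return SessionSpec(n_classes=4, images_per_class=5)


@pytest.fixture(scope="session")
def tiny_model() -> VEPModel:
    return VEPModel.default(n_classes=4, snr=2.0, seed=7)


@pytest.fixture(scope="session")
def tiny_recording(tiny_spec, tiny_model):
    events = make_session_events(tiny_spec, seed=1)
    return synthesize_recording(events, tiny_model, seed=2)


@pytest.fixture(scope="session")
def clean_recording(tiny_spec):
    """Noise-free, jitter-free recording: every trial equals its template."""
    events = make_session_events(tiny_spec, seed=3)
    model = VEPModel.default(n_classes=4, snr=2.0, seed=7).noiseless()
    return synthesize_recording(events, model, seed=4)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
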