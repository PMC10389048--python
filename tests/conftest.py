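import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from beefit.synthetic import default_problem


class ScriptedRNG:
    """Deterministic stand-in for a numpy Generator.

    Pops pre-scripted values in call order, so tests can force specific
    partner/dimension/phi choices and enumerate every RNG outcome of a
    phase. ``integers(n)`` and scalar/vector ``uniform``/``random`` mirror
    the subset of the Generator API the optimizer uses.
    """

    def __init__(self, values):
        self.values = list(values)

    def _pop(self):
        if not self.values:
            raise AssertionError("scripted RNG exhausted")
        return self.values.pop(0)

    def integers(self, n):
        v = int(self._pop())
        assert 0 <= v < n, f"scripted integer {v} out of range [0, {n})"
        return v

    def uniform(self, low, high, size=None):
        if size is None:
            v = float(self._pop())
        else:
            v = np.array([float(self._pop()) for _ in range(int(size))])
        assert np.all((low <= np.asarray(v)) & (np.asarray(v) <= high))
        return v

    def random(self, size=None):
        if size is None:
            return float(self._pop())
        return np.array([float(self._pop()) for _ in range(int(size))])


@pytest.fixture(scope="session")
def noiseless_problem():
    """The bundled benchmark instance without observation noise."""
    return default_problem(seed=0, sigma=0.0)


@pytest.fixture(scope="session")
def noisy_problem():
    """The bundled benchmark instance with the default 1%-of-range noise."""
    return default_problem(seed=0)
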