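import numpy as np
import pytest

from micellekit import TruthParams


@pytest.fixture
def noiseless_params() -> TruthParams:
    """APFO-in-water truth with all noise channels at zero."""
    return TruthParams().noiseless()


@pytest.fixture
def default_params() -> TruthParams:
    return TruthParams()


@pytest.fixture
def write_csv(tmp_path):
    """Write (text, name) to a temp CSV and return its path."""

    def _write(text: str, name: str = "input.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
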