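import numpy as np
import pytest

from combmetrics.synthetic import SyntheticTabSpec, generate_tab


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_tabs():
    """Factory: n synthetic tabs of a kind, with their truths."""

    def _make(kind, n_tabs=2, seed=11, **spec_kwargs):
        g = np.random.default_rng(seed)
        spec = SyntheticTabSpec(kind=kind, **spec_kwargs)
        pairs = [generate_tab(spec, g, tab_id=f"{kind}_{i}") for i in range(n_tabs)]
        return [t for t, _ in pairs], [tr for _, tr in pairs]

    return _make
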