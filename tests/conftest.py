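import random

import pytest

from phfcorr import GeneratorConfig, random_phfs


@pytest.fixture(scope="session")
def random_pairs():
    """200 seeded random PHFS pairs on a shared universe, for invariants."""
    pairs = []
    for seed in range(200):
        a = random_phfs(GeneratorConfig(seed=seed * 2 + 1, n=3, max_len=4))
        b = random_phfs(GeneratorConfig(seed=seed * 2 + 2, n=3, max_len=4))
        pairs.append((a, b))
    return pairs


@pytest.fixture(scope="session")
def random_weights():
    """Deterministic normalized weight vectors matching the pair universe."""
    rng = random.Random(12345)
    out = []
    for _ in range(200):
        raw = [rng.random() + 1e-9 for _ in range(3)]
        s = sum(raw)
        out.append(tuple(r / s for r in raw))
    return out
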