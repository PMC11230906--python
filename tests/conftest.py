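import numpy as np
import pytest

from kemix.sequences import ChargeSequence


def scd_bruteforce(seq: ChargeSequence) -> float:
    """Independent O(N²) double-loop SCD oracle."""
    q = seq.charges
    n = len(q)
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            total += q[i] * q[j] * np.sqrt(j - i)
    return total / n


def random_neutral(length: int, rng: np.random.Generator) -> ChargeSequence:
    half = length // 2
    residues = list("K" * half + "E" * (length - half))
    rng.shuffle(residues)
    return ChargeSequence("".join(residues))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ke_series():
    from kemix.synth import ke_standins

    return ke_standins()
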