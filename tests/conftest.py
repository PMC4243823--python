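import numpy as np
import pytest

from repseq.synthetic import (
    ErrorModel,
    make_germline_reference,
    sample_reads,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def ref5():
    """Small toy reference: 5 V genes, 2 J genes."""
    return make_germline_reference(5, 2, 200, 50, seed=1)


@pytest.fixture(scope="session")
def ref20():
    """Reference sized like a realistic V panel subset: 20 V, 3 J."""
    return make_germline_reference(20, 3, 200, 50, seed=1)


@pytest.fixture(scope="session")
def healthy_repertoire(ref20):
    return simulate_repertoire(ref20, "healthy", 2000, seed=11)


@pytest.fixture(scope="session")
def cll_repertoire(ref20):
    return simulate_repertoire(ref20, "CLL", 60, seed=12)


@pytest.fixture(scope="session")
def small_readset(ref5):
    """2000 error-free reads from a 200-clone diverse sample."""
    rep = simulate_repertoire(ref5, "healthy", 200, seed=7)
    return rep, sample_reads(rep, 2000, error_model=ErrorModel.none(), seed=3)


def edit_distance_leq1(a: str, b: str) -> bool:
    """Independent oracle: edit distance between a and b is exactly 1.

    Equal lengths -> Hamming distance 1; lengths differing by 1 -> the
    longer equals the shorter with one extra character (two-pointer scan);
    anything else is > 1 (or 0 for equal strings).
    """
    if a == b:
        return False
    la, lb = len(a), len(b)
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if abs(la - lb) != 1:
        return False
    if la > lb:
        a, b = b, a
        la, lb = lb, la
    i = j = mismatches = 0
    while i < la and j < lb:
        if a[i] == b[j]:
            i += 1
            j += 1
        else:
            mismatches += 1
            if mismatches > 1:
                return False
            j += 1
    return True


def rng_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
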