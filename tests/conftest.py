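import numpy as np
import pytest

from radlesion.geometry import Domain


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def disk5():
    return Domain("disk2d", 5.0)


def tv_distance(counts_a, counts_b):
    """Total-variation distance between two empirical count samples.

    Each argument is an array of integer outcomes (1-D) or tuples (2-D,
    one row per draw); the TV distance is computed between the two
    empirical pmfs over the union of observed outcomes.
    """
    import collections

    def to_pmf(arr):
        arr = np.asarray(arr)
        if arr.ndim == 1:
            keys = arr.tolist()
        else:
            keys = [tuple(row) for row in arr]
        c = collections.Counter(keys)
        n = len(keys)
        return {k: v / n for k, v in c.items()}

    pa, pb = to_pmf(counts_a), to_pmf(counts_b)
    support = set(pa) | set(pb)
    return 0.5 * sum(abs(pa.get(k, 0.0) - pb.get(k, 0.0)) for k in support)


def tv_from_pmf(counts, pmf_dict):
    """TV distance between an empirical sample and an exact pmf dict."""
    import collections

    arr = np.asarray(counts)
    keys = arr.tolist() if arr.ndim == 1 else [tuple(r) for r in arr]
    c = collections.Counter(keys)
    n = len(keys)
    emp = {k: v / n for k, v in c.items()}
    support = set(emp) | set(pmf_dict)
    return 0.5 * sum(abs(emp.get(k, 0.0) - pmf_dict.get(k, 0.0)) for k in support)
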