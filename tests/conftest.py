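import numpy as np
import pytest

from wcps import ExpressionProfile


def brute_force_dn(control, case_block, as_sequence=True):
    """Independent exhaustive evaluation of the scan: for every candidate
    split p = n1..n-1, the sup of |F_segment - F_control| over every jump
    point of either ECDF (both one-sided limits), times sqrt(m)."""
    control = np.asarray(control, float)
    case = np.asarray(case_block, float)
    if not as_sequence:
        case = np.sort(case)
    seq = np.concatenate([np.sort(control), case])
    n1, n = control.size, seq.size
    out = []
    for p in range(n1, n):
        seg = seq[p:]
        sup = 0.0
        for x in seq:
            for le in (True, False):
                if le:
                    f1 = np.mean(control <= x)
                    fs = np.mean(seg <= x)
                else:
                    f1 = np.mean(control < x)
                    fs = np.mean(seg < x)
                sup = max(sup, abs(fs - f1))
        out.append(np.sqrt(n - p) * sup)
    return np.array(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def null_profile(rng):
    return ExpressionProfile(
        "null", rng.standard_normal(25), rng.standard_normal(25), as_sequence=True
    )


@pytest.fixture
def shifted_profile(rng):
    """Sequence-model gene: 9 of 25 case samples shifted by +2."""
    case = rng.standard_normal(25)
    case[16:] += 2.0
    return ExpressionProfile("shifted", rng.standard_normal(25), case, as_sequence=True)
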