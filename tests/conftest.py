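import numpy as np
import pytest

from paspectrum.processing import EpochSeries

T0 = "2013-09-02T00:00:00"


def make_series(vm, t0=T0, subject_id="t", **kw):
    return EpochSeries(subject_id=subject_id, t0=np.datetime64(t0, "s"),
                       vm_mg=np.asarray(vm, dtype=float), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_nonwear(vm, epoch_s=3, window_min=60.0, allowance_min=2.0,
                        lpa_cut_mg=40.0, zero_floor_mg=1.0):
    """Exhaustive span-by-span non-wear oracle (quadratic, test-only).

    A span [i, j] is non-wear when it starts/ends on zero epochs, contains no
    epoch at/above the LPA cut, its sub-cut interruptions total at most the
    allowance, and it lasts at least the window.
    """
    vm = np.asarray(vm, dtype=float)
    n = vm.size
    is_zero = vm < zero_floor_mg
    is_active = vm >= lpa_cut_mg
    interrupt = (~is_zero) & (~is_active)
    win = int(np.ceil(window_min * 60.0 / epoch_s))
    allow = int(np.floor(allowance_min * 60.0 / epoch_s))
    nonwear = np.zeros(n, dtype=bool)
    for i in range(n):
        if not is_zero[i]:
            continue
        n_int = 0
        for j in range(i, n):
            if is_active[j]:
                break
            n_int += interrupt[j]
            if n_int > allow:
                break
            if is_zero[j] and (j - i + 1) >= win:
                nonwear[i : j + 1] = True
    return ~nonwear
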