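import numpy as np
import pytest

from critpower import PerformanceTrial


def hyperbola_trials(cp, w_prime, durations, protocol="constant_duration"):
    """Trials lying exactly on P = W'/t + CP."""
    return [
        PerformanceTrial(duration_s=t, power_w=w_prime / t + cp, protocol=protocol)
        for t in durations
    ]


@pytest.fixture
def exact_trials():
    """Noiseless hyperbola CP=250 W, W'=20 kJ at 180/600/900 s."""
    return hyperbola_trials(250.0, 20_000.0, [180.0, 600.0, 900.0])


def wbal_direct_sum(time_s, power_w, cp, w0, tau):
    """O(n^2) direct-convolution reference for the W' balance.

    wbal[k] = w0 - sum_{j<k} max(P_j - cp, 0) * dt * exp(-(t_k - t_j)/tau),
    expenditure attributed at step start.  Deliberately naive; the
    implementation under test uses an equivalent one-pass recursion.
    """
    time_s = np.asarray(time_s, float)
    power_w = np.asarray(power_w, float)
    dt = time_s[1] - time_s[0]
    e = np.maximum(power_w - cp, 0.0) * dt
    n = time_s.size
    wbal = np.empty(n)
    for k in range(n):
        acc = 0.0
        for j in range(k):
            decay = 1.0 if np.isinf(tau) else np.exp(-(time_s[k] - time_s[j]) / tau)
            acc += e[j] * decay
        wbal[k] = w0 - acc
    return wbal


def wbal_direct_sum_fast(time_s, power_w, cp, w0, tau):
    """Vectorised O(n^2) variant of :func:`wbal_direct_sum` for larger n."""
    time_s = np.asarray(time_s, float)
    power_w = np.asarray(power_w, float)
    dt = time_s[1] - time_s[0]
    e = np.maximum(power_w - cp, 0.0) * dt
    lags = time_s[:, None] - time_s[None, :]
    mask = lags > 0
    kernel = np.zeros_like(lags)
    kernel[mask] = np.exp(-lags[mask] / tau) if np.isfinite(tau) else 1.0
    return w0 - kernel @ e
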