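import numpy as np
import pytest

import graftquant as gq


def brute_force_baseline(trace, dt, window_s=30.0, fraction=0.5):
    """Independent per-frame sort-and-average oracle for the sliding
    lowest-percentile baseline."""
    import math

    x = np.asarray(trace, float)
    w = max(1, int(round(window_s / dt)))
    out = np.empty_like(x)
    for t in range(x.size):
        lo = max(0, t - w + 1)
        window = sorted(x[lo : t + 1])
        m = math.ceil(fraction * len(window))
        out[t] = float(np.mean(window[:m]))
    return out


@pytest.fixture(scope="session")
def default_field():
    """One simulated field under the study's default recording conditions."""
    params = gq.TraceSimParams(seed=0, noise_sd=0.3)
    traces, truth = gq.simulate_trace_set(params)
    return params, traces, truth


@pytest.fixture(scope="session")
def analyzed_fields():
    """Twelve simulated fields (50 ROIs x 10,000 frames at 30.33 Hz each)
    analyzed with the default detection parameters, plus their scores.

    Session-scoped: this is the expensive fixture shared by the recovery
    tests.
    """
    results = []
    for seed in range(12):
        params = gq.TraceSimParams(seed=seed, noise_sd=0.3)
        traces, truth = gq.simulate_trace_set(params)
        table = gq.analyze_field(traces)
        score = gq.score_detection(table, truth)
        results.append((params, truth, table, score))
    return results
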