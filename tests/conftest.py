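import numpy as np
import pytest

from caplast.synth import SynthSessionConfig, generate_calcium_session


def percentile_oracle(values, q):
    """Sort-based midpoint-anchored percentile: ranks anchored at
    probabilities 100·(k − 0.5)/n, linear interpolation, clamped ends."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    probs = 100.0 * (np.arange(1, n + 1) - 0.5) / n
    if q <= probs[0]:
        return x[0]
    if q >= probs[-1]:
        return x[-1]
    k = np.searchsorted(probs, q, side="right") - 1
    frac = (q - probs[k]) / (probs[k + 1] - probs[k])
    return x[k] + frac * (x[k + 1] - x[k])


def group_transients(binary_col):
    """Consecutive binary frames grouped into (start, end) inclusive spans."""
    idx = np.nonzero(np.asarray(binary_col))[0]
    if idx.size == 0:
        return []
    groups, start, prev = [], idx[0], idx[0]
    for f in idx[1:]:
        if f == prev + 1:
            prev = f
            continue
        groups.append((start, prev))
        start = prev = f
    groups.append((start, prev))
    return groups


def match_events(true_frames, detected_spans, tol_frames):
    """Greedy one-to-one matching of ground-truth event frames to detected
    transients.  Returns (n_matched, n_missed, n_spurious)."""
    used = set()
    matched = 0
    for f in true_frames:
        for i, (s, e) in enumerate(detected_spans):
            if i in used:
                continue
            if s - tol_frames <= f <= e + tol_frames:
                used.add(i)
                matched += 1
                break
    return matched, len(true_frames) - matched, len(detected_spans) - len(used)


@pytest.fixture(scope="session")
def small_session():
    """One compact synthetic session shared by read-only tests."""
    cfg = SynthSessionConfig(
        n_rois=3,
        n_trials_pre=8,
        n_trials_post=8,
        frames_per_trial=310,
        noise_sd=5.0,
        seed=11,
    )
    traces, truth = generate_calcium_session(cfg)
    return cfg, traces, truth
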