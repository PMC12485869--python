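import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccmkit.trackio import TrackSet


def pooled_marginal_p(groups, control):
    """Unadjusted many-to-one t p-values with the pooled variance estimate.

    Same per-contrast statistic as Dunnett's procedure (pooled s^2,
    df = N - k) but without the multiplicity adjustment: the reference
    that the adjusted p-values must dominate.
    """
    ctrl = np.asarray(groups[control], float)
    labels = sorted(k for k in groups if k != control)
    arrays = [np.asarray(groups[l], float) for l in labels]
    everyone = [ctrl] + arrays
    df = sum(len(g) for g in everyone) - len(everyone)
    s2 = sum(((g - g.mean()) ** 2).sum() for g in everyone) / df
    out = {}
    for label, g in zip(labels, arrays):
        t = (g.mean() - ctrl.mean()) / np.sqrt(s2 * (1 / len(g) + 1 / len(ctrl)))
        out[label] = 2 * stats.t.sf(abs(t), df)
    return out


def make_trackset(rows, **meta):
    """TrackSet from (track_id, frame, x, y) tuples."""
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    meta.setdefault("field_width", 1000.0)
    meta.setdefault("field_height", 1000.0)
    return TrackSet(df, **meta)


@pytest.fixture
def shared_drift_trackset():
    """25 cells on a grid, all translating by (3, 4) px every frame."""
    rows = []
    for i in range(25):
        x0, y0 = 100.0 + 50 * (i % 5), 100.0 + 50 * (i // 5)
        for f in range(10):
            rows.append((i, f, x0 + 3.0 * f, y0 + 4.0 * f))
    return make_trackset(rows)


@pytest.fixture
def random_walk_trackset():
    """60 independent isotropic random walkers, 40 frames."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(60):
        pos = rng.uniform(200, 800, size=2)
        for f in range(40):
            rows.append((i, f, pos[0], pos[1]))
            pos = pos + rng.normal(0, 12, size=2)
    return make_trackset(rows)
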