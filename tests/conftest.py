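import numpy as np
import pytest

import ithquant as iq


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale generator conditions: 8x8 patch grid maps."""
    return iq.SyntheticParams(n_patients=30, map_side_px=248, seed=42)


@pytest.fixture(scope="session")
def cohort100():
    """Default-condition synthetic cohort (n=100): stacks, cohort table and
    the extracted feature matrix, computed once per session."""
    params = iq.SyntheticParams(n_patients=100, seed=7)
    stacks, cohort = iq.generate_cohort(params)
    fm = iq.compute_feature_matrix([iq.exclude_dcis(s) for s in stacks])
    return params, stacks, cohort, fm


def brute_force_cm(level_map, valid=None, distance=1):
    """Independent oracle: enumerate every neighbouring patch pair over the
    eight unit-offset directions, count each unordered pair once per
    orientation, normalize."""
    level_map = np.asarray(level_map)
    if valid is None:
        valid = np.ones(level_map.shape, dtype=bool)
    H, W = level_map.shape
    levels = sorted(set(level_map[valid].ravel().tolist()))
    idx = {v: k for k, v in enumerate(levels)}
    counts = np.zeros((len(levels), len(levels)))
    offsets = [(0, 1), (0, -1), (1, 0), (-1, 0),
               (1, 1), (1, -1), (-1, 1), (-1, -1)]
    for r in range(H):
        for c in range(W):
            if not valid[r, c]:
                continue
            for dy, dx in offsets:
                rr, cc = r + dy * distance, c + dx * distance
                if 0 <= rr < H and 0 <= cc < W and valid[rr, cc]:
                    counts[idx[level_map[r, c]], idx[level_map[rr, cc]]] += 1
    counts /= 2.0
    total = counts.sum()
    if total == 0:
        return None, np.asarray(levels, dtype=float)
    return counts / total, np.asarray(levels, dtype=float)
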