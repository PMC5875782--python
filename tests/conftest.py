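import numpy as np
import pytest

from omentex import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A scaled-down configuration for fast image-backed tests."""
    return SimConfig(seed=7, n_pairs_test=4, n_pairs_validation=2, image_size=64)


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive; never share code with
# the implementation under test)
# ---------------------------------------------------------------------------


def point_in_polygon_even_odd(x: float, y: float, verts) -> bool:
    """Classic even-odd ray casting, one point at a time."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def brute_glcm(image, mask, distance, directions, symmetric):
    """Count co-occurring gray-value pairs with explicit python loops."""
    counts = {}
    nrows, ncols = image.shape
    for r in range(nrows):
        for c in range(ncols):
            if not mask[r, c]:
                continue
            for dy, dx in directions:
                rr, cc = r + dy * distance, c + dx * distance
                if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc]:
                    key = (int(image[r, c]), int(image[rr, cc]))
                    counts[key] = counts.get(key, 0) + 1
                    if symmetric:
                        rev = (key[1], key[0])
                        counts[rev] = counts.get(rev, 0) + 1
    return counts


def brute_wilcoxon_two_sided(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    import itertools

    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    return min(1.0, 2 * min(p_ge, p_le))


def brute_fisher_two_sided(table):
    """Sum of hypergeometric point probabilities <= observed, by enumeration."""
    from math import comb

    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(n - r1, c1 - a) / denom
    p = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = comb(r1, x) * comb(n - r1, c1 - x) / denom
        if px <= p_obs * (1 + 1e-7):
            p += px
    return min(1.0, p)


def brute_best_youden(scores, labels):
    """Exhaustive threshold scan for the maximal Youden J (strict > rule)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    best = -np.inf
    for t in np.concatenate([[-np.inf], np.unique(s)]):
        sens = np.mean(s[y] > t)
        spec = np.mean(s[~y] <= t)
        best = max(best, sens + spec - 1.0)
    return best


def grid_clogit_1d(diffs, lo=-20.0, hi=20.0, n_grid=200001):
    """Dense-grid maximizer of the 1-covariate pair-difference log-likelihood."""
    d = np.asarray(diffs, dtype=float)
    betas = np.linspace(lo, hi, n_grid)
    ll = -(np.logaddexp(0.0, -np.outer(d, betas))).sum(axis=0)
    return betas[np.argmax(ll)]
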