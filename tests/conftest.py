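"""Shared fixtures and independent oracles for the test suite.

The oracle functions here recompute statistics by brute force (explicit
double loops, exhaustive permutation enumeration) so they stay independent
of the vectorized implementations they check.
"""

import itertools
import math

import numpy as np
import pytest

from phyloacoustics.phylo import tree_from_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20231207)


@pytest.fixture
def three_tip_tree():
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    labels = ",".join(f"t{i}:1.5" for i in range(8))
    return tree_from_newick(f"({labels});")


# ------------------------------------------------------------------- oracles

def moran_oracle(z, W):
    """Moran's I by explicit double loop."""
    z = np.asarray(z, float)
    W = np.asarray(W, float)
    n = len(z)
    zc = z - z.mean()
    num = sum(W[i, j] * zc[i] * zc[j] for i in range(n) for j in range(n))
    return (n / W.sum()) * num / (zc @ zc)


def geary_oracle(z, W):
    z = np.asarray(z, float)
    W = np.asarray(W, float)
    n = len(z)
    zc = z - z.mean()
    num = sum(W[i, j] * (z[i] - z[j]) ** 2 for i in range(n) for j in range(n))
    return ((n - 1) / (2 * W.sum())) * num / (zc @ zc)


def blomberg_oracle(y, C):
    """Blomberg's K from the defining ratio-of-ratios, via explicit inverses."""
    y = np.asarray(y, float)
    C = np.asarray(C, float)
    n = len(y)
    Ci = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Ci @ y) / (ones @ Ci @ ones)
    mse0 = ((y - a) @ (y - a)) / (n - 1)
    mse = ((y - a) @ Ci @ (y - a)) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Ci @ ones)) / (n - 1)
    return (mse0 / mse) / expected


def mantel_oracle(DX, DY):
    """Pearson r over the strict lower triangles, element by element."""
    DX = np.asarray(DX, float)
    DY = np.asarray(DY, float)
    n = DX.shape[0]
    xs, ys = [], []
    for i in range(n):
        for j in range(i):
            xs.append(DX[i, j])
            ys.append(DY[i, j])
    xs, ys = np.array(xs), np.array(ys)
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    return float((xs @ ys) / math.sqrt((xs @ xs) * (ys @ ys)))


def exact_perm_p(stat_fn, z, upper=True):
    """Exact permutation p over all n! relabelings (n small)."""
    z = np.asarray(z, float)
    obs = stat_fn(z)
    stats = [stat_fn(z[list(p)]) for p in itertools.permutations(range(len(z)))]
    stats = np.asarray(stats)
    if upper:
        return (stats >= obs - 1e-12).mean()
    return (stats <= obs + 1e-12).mean()


def exact_mantel_p(DX, DY):
    """Exact upper-tail Mantel p over all simultaneous relabelings of DY."""
    DX = np.asarray(DX, float)
    DY = np.asarray(DY, float)
    n = DX.shape[0]
    obs = mantel_oracle(DX, DY)
    vals = []
    for p in itertools.permutations(range(n)):
        p = list(p)
        vals.append(mantel_oracle(DX, DY[np.ix_(p, p)]))
    return (np.asarray(vals) >= obs - 1e-12).mean()
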