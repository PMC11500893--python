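"""Texture matrices against independent brute-force enumeration oracles.

The oracles below re-derive each matrix with naive nested loops and explicit
line/zone walks, sharing no code with the implementation: co-occurrences by
enumerating every voxel pair, runs by run-length-encoding every lattice line,
zones by breadth-first flood fill, neighbourhood differences by looping over
all 26 neighbours of every voxel.
"""

import itertools
from collections import deque

import numpy as np
import pytest

from petpaint.texture import (
    DIRECTIONS_13,
    glcm_matrix,
    glrlm_matrix,
    glzlm_matrix,
    ngldm_stats,
)
from .conftest import make_glv, random_glv

N_RANDOM_VOLUMES = 110


def oracle_glcm(levels, mask, n_levels):
    counts = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for p in itertools.product(*(range(s) for s in shape)):
        if not mask[p]:
            continue
        for d in DIRECTIONS_13:
            q = tuple(p[a] + d[a] for a in range(3))
            if all(0 <= q[a] < shape[a] for a in range(3)) and mask[q]:
                i, j = levels[p] - 1, levels[q] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    total = counts.sum()
    return counts / total if total else counts


def oracle_glrlm(levels, mask, n_levels, directions=DIRECTIONS_13):
    """Run-length encode every lattice line along each direction."""
    shape = levels.shape
    max_run = max(shape)
    counts = np.zeros((n_levels, max_run))
    for d in directions:
        # line starts: positions whose predecessor along d is outside the box
        starts = [
            p for p in itertools.product(*(range(s) for s in shape))
            if not all(0 <= p[a] - d[a] < shape[a] for a in range(3))
        ]
        for start in starts:
            seq = []
            p = start
            while all(0 <= p[a] < shape[a] for a in range(3)):
                seq.append(levels[p] if mask[p] else 0)
                p = tuple(p[a] + d[a] for a in range(3))
            for lev, group in itertools.groupby(seq):
                if lev > 0:
                    counts[lev - 1, len(list(group)) - 1] += 1
    return counts


def oracle_glzlm(levels, mask, n_levels):
    """Flood-fill 26-connected equal-level zones."""
    shape = levels.shape
    n_vox = int((mask & (levels > 0)).sum())
    counts = np.zeros((n_levels, max(n_vox, 1)))
    seen = np.zeros(shape, dtype=bool)
    offsets = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for p in itertools.product(*(range(s) for s in shape)):
        if seen[p] or not mask[p] or levels[p] == 0:
            continue
        lev = levels[p]
        size = 0
        queue = deque([p])
        seen[p] = True
        while queue:
            q = queue.popleft()
            size += 1
            for d in offsets:
                r = tuple(q[a] + d[a] for a in range(3))
                if (all(0 <= r[a] < shape[a] for a in range(3)) and not seen[r]
                        and mask[r] and levels[r] == lev):
                    seen[r] = True
                    queue.append(r)
        counts[lev - 1, size - 1] += 1
    return counts


def oracle_ngldm(levels, mask, n_levels):
    shape = levels.shape
    inside = mask & (levels > 0)
    n_vox = int(inside.sum())
    p = np.zeros(n_levels)
    s = np.zeros(n_levels)
    for pos in itertools.product(*(range(d) for d in shape)):
        if not inside[pos]:
            continue
        p[levels[pos] - 1] += 1
        neigh = []
        for d in itertools.product((-1, 0, 1), repeat=3):
            if d == (0, 0, 0):
                continue
            q = tuple(pos[a] + d[a] for a in range(3))
            if all(0 <= q[a] < shape[a] for a in range(3)) and inside[q]:
                neigh.append(levels[q])
        if neigh:
            s[levels[pos] - 1] += abs(levels[pos] - np.mean(neigh))
    return p / n_vox, s, n_vox


@pytest.fixture(scope="module")
def random_volumes():
    rng = np.random.default_rng(20240)
    return [random_glv(rng) for _ in range(N_RANDOM_VOLUMES)]


class TestAgainstOracles:
    def test_glcm_matches_pair_enumeration(self, random_volumes):
        for glv in random_volumes:
            expected = oracle_glcm(glv.levels, glv.mask, glv.n_levels)
            got = glcm_matrix(glv.levels, glv.mask, glv.n_levels)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_glrlm_matches_line_encoding(self, random_volumes):
        for glv in random_volumes:
            expected = oracle_glrlm(glv.levels, glv.mask, glv.n_levels)
            got = glrlm_matrix(glv.levels, glv.mask, glv.n_levels)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_glzlm_matches_flood_fill(self, random_volumes):
        for glv in random_volumes:
            expected = oracle_glzlm(glv.levels, glv.mask, glv.n_levels)
            got = glzlm_matrix(glv.levels, glv.mask, glv.n_levels)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_ngldm_matches_neighbour_loops(self, random_volumes):
        for glv in random_volumes:
            p_exp, s_exp, n_exp = oracle_ngldm(glv.levels, glv.mask, glv.n_levels)
            p_got, s_got, n_got = ngldm_stats(glv.levels, glv.mask, glv.n_levels)
            assert n_got == n_exp
            np.testing.assert_allclose(p_got, p_exp, atol=1e-10)
            np.testing.assert_allclose(s_got, s_exp, atol=1e-10)


class TestMatrixNormalizations:
    def test_glcm_sums_to_one(self, random_volumes):
        for glv in random_volumes[:30]:
            assert glcm_matrix(glv.levels, glv.mask, glv.n_levels).sum() == pytest.approx(1.0)

    def test_glrlm_length_weighted_total_counts_voxels(self, random_volumes):
        # along each single direction, runs weighted by length tile the VOI
        for glv in random_volumes[:30]:
            n_vox = int((glv.mask & (glv.levels > 0)).sum())
            for d in [(0, 0, 1), (1, 1, 0), (1, -1, 1)]:
                m = glrlm_matrix(glv.levels, glv.mask, glv.n_levels, directions=[d])
                lengths = np.arange(1, m.shape[1] + 1)
                assert (m * lengths).sum() == pytest.approx(n_vox)

    def test_glzlm_size_weighted_total_counts_voxels(self, random_volumes):
        for glv in random_volumes[:30]:
            n_vox = int((glv.mask & (glv.levels > 0)).sum())
            m = glzlm_matrix(glv.levels, glv.mask, glv.n_levels)
            sizes = np.arange(1, m.shape[1] + 1)
            assert (m * sizes).sum() == pytest.approx(n_vox)


class TestKnownSmallCases:
    def test_alternating_line_glcm(self):
        # 1,2,1,2 along one axis: 3 adjacent pairs, all dissimilar by 1
        glv = make_glv(np.array([1, 2, 1, 2]).reshape(1, 1, 4))
        p = glcm_matrix(glv.levels, glv.mask, glv.n_levels, directions=[(0, 0, 1)])
        assert p[0, 0] == p[1, 1] == 0
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)

    def test_constant_line_single_run(self):
        glv = make_glv(np.ones((1, 1, 5), dtype=int))
        m = glrlm_matrix(glv.levels, glv.mask, glv.n_levels, directions=[(0, 0, 1)])
        assert m.sum() == 1
        assert m[0, 4] == 1

    def test_checkerboard_zones_are_singletons_in_6_connectivity_sense(self):
        # 26-connectivity joins diagonal same-level voxels of a checkerboard
        zz, yy, xx = np.indices((3, 3, 3))
        glv = make_glv(((zz + yy + xx) % 2 + 1).astype(int))
        m = glzlm_matrix(glv.levels, glv.mask, glv.n_levels)
        # each level forms one single 26-connected zone
        assert m.sum() == 2
        sizes = np.argwhere(m > 0)[:, 1] + 1
        assert sorted(sizes) == [13, 14]
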