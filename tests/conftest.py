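"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's code paths: the CBS
oracle scores every circular arc with nested Python loops, and the Ward
oracle agglomerates clusters from the closed-form minimum-variance
distance between centroids.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import oacgh as og

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


@pytest.fixture(scope="session")
def toy_genome() -> og.GenomeModel:
    return og.toy_genome()


@pytest.fixture(scope="session")
def toy_probes(toy_genome) -> pd.DataFrame:
    return og.gen_probes(toy_genome)


@pytest.fixture(scope="session")
def noisefree_profile(toy_genome, toy_probes) -> og.NormalizedProfile:
    """Toy profile with planted CNAs and zero ratio noise."""
    signal = og.gen_signal_profile(
        toy_probes, og.toy_cnas(toy_genome), noise_sd=0.0, seed=11
    )
    return og.normalize_profile(signal)


def brute_max_circular_t(x: np.ndarray) -> tuple[float, int, int]:
    """Exhaustive circular two-arc t maximization, pure Python."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    s = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    best = (-1.0, 0, 1)
    for i in range(n):
        for j in range(i + 1, n + 1):
            w = j - i
            if w == n:
                continue
            arc = x[i:j]
            rest = x[:i] + x[j:]
            m_in = sum(arc) / w
            m_out = sum(rest) / (n - w)
            t = abs(m_in - m_out) / (s * math.sqrt(1 / w + 1 / (n - w)))
            if t > best[0] + 1e-12:
                best = (t, i, j)
    return best


def brute_max_circular_t_fast(x: np.ndarray) -> tuple[float, int, int]:
    """Same exhaustive maximization via Python-loop prefix sums.

    Scales to a few hundred points; cross-checked against the naive
    version in the unit tests.
    """
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    s = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    prefix = [0.0]
    for v in x:
        prefix.append(prefix[-1] + v)
    total = prefix[-1]
    best = (-1.0, 0, 1)
    for i in range(n):
        for j in range(i + 1, n + 1):
            w = j - i
            if w == n:
                continue
            t = abs(n * (prefix[j] - prefix[i]) - w * total) / (
                s * math.sqrt(n * w * (n - w))
            )
            if t > best[0] + 1e-12:
                best = (t, i, j)
    return best


def ward_oracle_clades(data: np.ndarray) -> set[frozenset[int]]:
    """All clades of a brute-force Ward agglomeration.

    Clusters merge greedily by the minimum-variance distance
    d^2(A, B) = 2|A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2,
    recomputed from centroids at every step.
    """
    clusters: list[list[int]] = [[i] for i in range(len(data))]
    clades: set[frozenset[int]] = {frozenset(c) for c in clusters}
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = data[clusters[a]].mean(axis=0)
                cb = data[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d2 = 2 * na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or d2 < best[0] - 1e-12:
                    best = (d2, a, b)
        _, a, b = best
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        clades.add(frozenset(merged))
    return clades


def scipy_linkage_clades(linkage: np.ndarray, n: int) -> set[frozenset[int]]:
    """Clades implied by a scipy linkage matrix."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    clades = set(members.values())
    for k, (left, right, _, _) in enumerate(linkage):
        merged = members[int(left)] | members[int(right)]
        members[n + k] = merged
        clades.add(merged)
    return clades
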