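import numpy as np
import pytest

from statemapper import GridPoint, SynthParams, simulate_subject
from statemapper.grid import enumerate_grid


@pytest.fixture(scope="session")
def full_grid() -> list[GridPoint]:
    return enumerate_grid()


@pytest.fixture(scope="session")
def planted_subject():
    """One noise-controlled subject with a planted return at t = 63."""
    params = SynthParams(n_channels=20, planted_return=63, seed=7)
    series, truth = simulate_subject(params)
    return series, truth, params


def naive_single_linkage(points: np.ndarray):
    """Brute-force agglomerative single linkage, independent of scipy.

    Returns (merge heights ascending, list of partitions after each merge,
    starting from singletons). Partitions are lists of frozensets of row
    indices.
    """
    n = len(points)
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters = [frozenset([i]) for i in range(n)]
    partitions = [list(clusters)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        heights.append(d)
        partitions.append(list(clusters))
    return np.asarray(heights), partitions


def cut_dendrogram(points: np.ndarray, cutoff: float):
    """Partition by applying all single-linkage merges with height < cutoff."""
    heights, partitions = naive_single_linkage(points)
    k = int(np.sum(heights < cutoff))
    return {frozenset(c) for c in partitions[k]}
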