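"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive each criterion from its definition with
straightforward loops, sharing no code with the implementation.
"""

import heapq
import itertools
import math

import numpy as np

from roikit.extraction import EPSILON_COST


def otsu_oracle(hist):
    """Exhaustive maximization of omega0*omega1*(mu0-mu1)^2 over cuts."""
    c = hist.counts.astype(float)
    m = hist.centers
    best_val, best_t = -1.0, None
    for t in range(1, hist.n_bins):
        if c[t - 1] == 0:  # same partition as the next-lower cut
            continue
        w0, w1 = c[:t].sum(), c[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (c[:t] * m[:t]).sum() / w0
        mu1 = (c[t:] * m[t:]).sum() / w1
        val = w0 * w1 * (mu0 - mu1) ** 2
        if val > best_val:
            best_val, best_t = val, t
    return float(hist.bin_edges[best_t])


def multi_otsu_oracle(hist, k):
    """Exhaustive maximization of sum_c omega_c*(mu_c - mu)^2 over all cut
    vectors, lexicographically first maximizer."""
    c = hist.counts.astype(float)
    m = hist.centers
    total_w = c.sum()
    mu_all = (c * m).sum() / total_w
    n = hist.n_bins
    best_val, best_cuts = -1.0, None
    candidates = [t for t in range(1, n) if c[t - 1] > 0]
    for cuts in itertools.combinations(candidates, k - 1):
        bounds = (0,) + cuts + (n,)
        val = 0.0
        ok = True
        for a, b in zip(bounds, bounds[1:]):
            w = c[a:b].sum()
            if w == 0:
                ok = False
                break
            mu = (c[a:b] * m[a:b]).sum() / w
            val += w / total_w * (mu - mu_all) ** 2
        if ok and val > best_val:
            best_val, best_cuts = val, cuts
    return tuple(float(hist.bin_edges[t]) for t in best_cuts)


def renyi_oracle(hist, alpha):
    """Direct evaluation of H_a(back) + H_a(fore) at every cut."""
    c = hist.counts.astype(float)
    best_val, best_t = -math.inf, None
    for t in range(1, hist.n_bins):
        if c[t - 1] == 0:
            continue
        w0, w1 = c[:t].sum(), c[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        val = 0.0
        for cls in (c[:t] / w0, c[t:] / w1):
            p = cls[cls > 0]
            if alpha == 1.0:
                val += float(-(p * np.log(p)).sum())
            else:
                val += float(np.log((p**alpha).sum()) / (1.0 - alpha))
        if val > best_val:
            best_val, best_t = val, t
    return float(hist.bin_edges[best_t])


def shanbhag_oracle(hist):
    """Direct evaluation of |E_back - E_fore| with cumulative fuzzy
    memberships, minimized over cuts."""
    p = hist.counts.astype(float)
    p = p / p.sum()
    n = hist.n_bins
    best_val, best_t = math.inf, None
    for t in range(1, n):
        if p[t - 1] == 0:
            continue
        w0 = p[:t].sum()
        w1 = p[t:].sum()
        if w0 <= 0 or w1 <= 0:
            continue
        e_back = 0.0
        for i in range(t):
            below = p[:i].sum()
            e_back -= p[i] * math.log(1.0 - below / (2.0 * w0))
        e_back /= 2.0 * w0
        e_fore = 0.0
        for i in range(t, n):
            above = p[i + 1 :].sum()
            e_fore -= p[i] * math.log(1.0 - above / (2.0 * w1))
        e_fore /= 2.0 * w1
        val = abs(e_back - e_fore)
        if val < best_val:
            best_val, best_t = val, t
    return float(hist.bin_edges[best_t])


def random_histogram(rng, n_bins=32, multimodal=True):
    from roikit.thresholding import Histogram

    counts = rng.integers(0, 40, size=n_bins)
    if multimodal:
        for _ in range(rng.integers(1, 4)):
            counts[rng.integers(0, n_bins)] += rng.integers(50, 300)
    if np.count_nonzero(counts) < 2:
        counts[0] += 1
        counts[-1] += 1
    edges = np.arange(n_bins + 1, dtype=float) * rng.uniform(0.5, 3.0) + rng.uniform(-10, 10)
    return Histogram(edges, counts)


def fdt_oracle(mu, seeds, region, edge_cost, steps):
    """Dijkstra with an explicit heap over the 26-adjacency graph."""
    shape = mu.shape
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    dist = np.full(shape, np.inf)
    pq = []
    for p in np.argwhere(seeds):
        dist[tuple(p)] = 0.0
        pq.append((0.0, tuple(p)))
    heapq.heapify(pq)
    while pq:
        d, u = heapq.heappop(pq)
        if d > dist[u]:
            continue
        for o in offsets:
            v = (u[0] + o[0], u[1] + o[1], u[2] + o[2])
            if not all(0 <= v[i] < shape[i] for i in range(3)):
                continue
            if not region[v]:
                continue
            length = math.sqrt(sum((o[i] * steps[i]) ** 2 for i in range(3)))
            if edge_cost == "object":
                w = (2.0 - mu[u] - mu[v]) / 2.0
            else:
                w = (mu[u] + mu[v]) / 2.0
            nd = d + length * (w + EPSILON_COST)
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(pq, (nd, v))
    return dist


def flood_fill_components(member, connectivity):
    """BFS flood fill returning the voxel partition as a set of frozensets."""
    conn_offsets = []
    for o in itertools.product((-1, 0, 1), repeat=3):
        nz = sum(1 for d in o if d != 0)
        if nz == 0:
            continue
        if connectivity == 6 and nz > 1:
            continue
        if connectivity == 18 and nz > 2:
            continue
        conn_offsets.append(o)
    shape = member.shape
    seen = np.zeros(shape, bool)
    parts = []
    for start in map(tuple, np.argwhere(member)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(u)
            for o in conn_offsets:
                v = (u[0] + o[0], u[1] + o[1], u[2] + o[2])
                if not all(0 <= v[i] < shape[i] for i in range(3)):
                    continue
                if member[v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        parts.append(frozenset(comp))
    return set(parts)
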