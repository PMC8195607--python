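"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the most literal O(n·m) formulations — explicit
loops over segments × radii, over spike triplets, and pixel-by-pixel
flood fill — and share no code with the package internals they verify.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def sholl_crossings_bruteforce(tree, center, radii, mode="2d") -> np.ndarray:
    """Count straddling segments per radius by looping over every pair."""
    center = np.asarray(center, dtype=float)
    counts = np.zeros(len(radii), dtype=int)
    for k, r in enumerate(radii):
        for child_pos, parent_pos in tree.segments():
            pc = tree.xyz[child_pos] - center
            pp = tree.xyz[parent_pos] - center
            if mode == "2d":
                pc, pp = pc[:2], pp[:2]
            dc = float(np.sqrt(np.sum(pc**2)))
            dp = float(np.sqrt(np.sum(pp**2)))
            lo, hi = min(dc, dp), max(dc, dp)
            if lo < r <= hi:
                counts[k] += 1
    return counts


def regularity_index_bruteforce(spike_times, cv2_threshold=0.2) -> float:
    """Enumerate all consecutive spike triplets; a triplet with local CV2
    below threshold marks its three spikes as regular."""
    t = np.asarray(spike_times, dtype=float)
    n = len(t)
    regular = [False] * n
    for i in range(n - 2):
        isi1 = t[i + 1] - t[i]
        isi2 = t[i + 2] - t[i + 1]
        cv2 = 2.0 * abs(isi2 - isi1) / (isi2 + isi1)
        if cv2 < cv2_threshold:
            regular[i] = regular[i + 1] = regular[i + 2] = True
    return sum(regular) / n


def count_components_floodfill(binary: np.ndarray, min_size: int = 1) -> int:
    """8-connected component count by explicit BFS flood fill."""
    binary = np.asarray(binary, dtype=bool)
    visited = np.zeros_like(binary)
    ny, nx = binary.shape
    n_comp = 0
    for i0 in range(ny):
        for j0 in range(nx):
            if not binary[i0, j0] or visited[i0, j0]:
                continue
            size = 0
            queue = deque([(i0, j0)])
            visited[i0, j0] = True
            while queue:
                i, j = queue.popleft()
                size += 1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < ny and 0 <= jj < nx and binary[ii, jj] and not visited[ii, jj]:
                            visited[ii, jj] = True
                            queue.append((ii, jj))
            if size >= min_size:
                n_comp += 1
    return n_comp


def forward_recurrence_pause_oracle(rate, shape, enforced_pause, n_mc=200_000, seed=12345) -> float:
    """Monte-Carlo expectation of the CS-to-next-SS pause (ms) when every
    SS within ``enforced_pause`` after a CS is deleted: pause + the
    forward recurrence time of the gamma renewal process at a random
    inspection point."""
    rng = np.random.default_rng(seed)
    scale = 1.0 / (rate * shape)
    # stationary forward recurrence time: simulate long ISI sequences and
    # inspect at a uniform random time
    isis = rng.gamma(shape, scale, size=n_mc)
    arrival = np.cumsum(isis)
    horizon = arrival[-1] * 0.9
    inspect = rng.uniform(0, horizon, size=n_mc // 4)
    nxt = arrival[np.searchsorted(arrival, inspect)]
    frt = nxt - inspect
    return (enforced_pause + frt.mean()) * 1e3
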