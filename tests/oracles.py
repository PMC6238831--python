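"""Independent brute-force oracles used to check the fast implementations.

The flood oracle keeps a plain list as its "queue" and re-scans it for the
minimum on every pop, following the stated rule literally: lowest relief
first, FIFO by insertion order among equal relief, a popped pixel takes the
label of the neighbor that enqueued it, seeds visited in row-major order and
neighbors in up/down/left/right order.
"""

import numpy as np

N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def brute_force_flood(relief, seeds):
    relief = np.asarray(relief, dtype=float)
    h, w = relief.shape
    labels = np.asarray(seeds, dtype=int).copy()
    queue = []  # entries: [relief, insertion_index, r, c, label]
    counter = 0

    def enqueue(r, c, lab):
        nonlocal counter
        queue.append((float(relief[r, c]), counter, r, c, lab))
        counter += 1

    for r in range(h):
        for c in range(w):
            if labels[r, c] != 0:
                for dr, dc in N4:
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and labels[nr, nc] == 0:
                        enqueue(nr, nc, int(labels[r, c]))
    while queue:
        best = min(range(len(queue)), key=lambda i: (queue[i][0], queue[i][1]))
        _, _, r, c, lab = queue.pop(best)
        if labels[r, c] != 0:
            continue
        labels[r, c] = lab
        for dr, dc in N4:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and labels[nr, nc] == 0:
                enqueue(nr, nc, lab)
    return labels


def brute_force_relief(lum):
    """4-neighbor max absolute luminance difference, computed pointwise."""
    lum = np.asarray(lum, dtype=float)
    h, w = lum.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            diffs = [
                abs(lum[r, c] - lum[r + dr, c + dc])
                for dr, dc in N4
                if 0 <= r + dr < h and 0 <= c + dc < w
            ]
            out[r, c] = max(diffs) if diffs else 0.0
    return out
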