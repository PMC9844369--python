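"""Naive O(N²) recurrence oracle: explicit double loops and line walks.

Deliberately independent of the package's vectorised implementation — used
to pin down the exact values of every recurrence measure on small inputs.
"""

from __future__ import annotations

import math


def oracle_embed(series, dim, delay):
    x = list(map(float, series))
    if dim == 1 or delay == 0:
        return [[v] for v in x]
    n = len(x) - (dim - 1) * delay
    return [[x[t + i * delay] for i in range(dim)] for t in range(n)]


def oracle_matrix(x_emb, y_emb, radius):
    out = []
    for xi in x_emb:
        row = []
        for yj in y_emb:
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(xi, yj)))
            row.append(1 if d <= radius else 0)
        out.append(row)
    return out


def _valid(i, j, theiler):
    return theiler is None or abs(i - j) > theiler


def oracle_measures(r, lmin, theiler):
    """rec %, det %, entropy (bits), lmax, lam % by explicit enumeration."""
    n, m = len(r), len(r[0])
    n_valid = n_rec = 0
    for i in range(n):
        for j in range(m):
            if _valid(i, j, theiler):
                n_valid += 1
                if r[i][j]:
                    n_rec += 1
    rec = 100.0 * n_rec / n_valid

    diag_lines = []
    for d in range(-(n - 1), m):
        if theiler is not None and abs(d) <= theiler:
            continue
        run = 0
        cells = [(i, i + d) for i in range(n) if 0 <= i + d < m]
        for i, j in cells:
            if r[i][j]:
                run += 1
            else:
                if run:
                    diag_lines.append(run)
                run = 0
        if run:
            diag_lines.append(run)

    vert_lines = []
    for j in range(m):
        run = 0
        for i in range(n):
            if r[i][j] and _valid(i, j, theiler):
                run += 1
            else:
                if run:
                    vert_lines.append(run)
                run = 0
        if run:
            vert_lines.append(run)

    dl = [v for v in diag_lines if v >= lmin]
    vl = [v for v in vert_lines if v >= lmin]
    det = 100.0 * sum(dl) / n_rec if n_rec else 0.0
    lam = 100.0 * sum(vl) / n_rec if n_rec else 0.0
    lmax = max(dl) if dl else 0
    if dl:
        counts = {}
        for v in dl:
            counts[v] = counts.get(v, 0) + 1
        total = sum(counts.values())
        ent = -sum(c / total * math.log2(c / total) for c in counts.values())
    else:
        ent = 0.0
    return {"rec": rec, "det": det, "ent": ent, "lmax": lmax, "lam": lam}
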