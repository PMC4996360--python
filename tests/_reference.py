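"""Independent literal transcriptions of the normalization procedures.

Pure-Python, loop-by-loop renderings of the five MHMN steps and of
sort/row-mean/un-sort quantile normalization, kept deliberately free of any
vectorization and of any code shared with the production implementation.
They serve as oracles in the equivalence tests.
"""

from __future__ import annotations


def mhmn_reference(values: list[list[float]]) -> list[list[float]]:
    """Step-by-step modified histogram matching normalization."""
    m = len(values)
    n = len(values[0])
    # step 1: sort all data in the whole matrix by magnitude, low to high
    pooled = sorted(v for row in values for v in row)
    # step 2: partition the sorted data into m bins of exactly n numbers
    bins = [pooled[i * n : (i + 1) * n] for i in range(m)]
    # step 3: sort each column of the original matrix (stable on ties)
    orders: list[list[int]] = []
    s = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col = [values[i][j] for i in range(m)]
        order = sorted(range(m), key=lambda i: col[i])  # stable
        orders.append(order)
        for r in range(m):
            s[r][j] = col[order[r]]
    # step 4: scale row i of S into the range of bin i
    scaled = [[0.0] * n for _ in range(m)]
    for i in range(m):
        row = s[i]
        row_min, row_max = min(row), max(row)
        bin_min, bin_max = bins[i][0], bins[i][-1]
        for j in range(n):
            if row_max == row_min:  # degenerate row: bin midpoint
                scaled[i][j] = 0.5 * (bin_min + bin_max)
            else:
                scaled[i][j] = (bin_max - bin_min) * (row[j] - row_min) / (
                    row_max - row_min
                ) + bin_min
    # step 5: return each scaled element to its original position in its column
    out = [[0.0] * n for _ in range(m)]
    for j in range(n):
        for r in range(m):
            out[orders[j][r]][j] = scaled[r][j]
    return out


def quantile_normalize_reference(values: list[list[float]]) -> list[list[float]]:
    """Sort each column, replace each rank row by its mean, un-sort."""
    m = len(values)
    n = len(values[0])
    orders: list[list[int]] = []
    s = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col = [values[i][j] for i in range(m)]
        order = sorted(range(m), key=lambda i: col[i])
        orders.append(order)
        for r in range(m):
            s[r][j] = col[order[r]]
    row_means = [sum(s[i]) / n for i in range(m)]
    out = [[0.0] * n for _ in range(m)]
    for j in range(n):
        for r in range(m):
            out[orders[j][r]][j] = row_means[r]
    return out
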