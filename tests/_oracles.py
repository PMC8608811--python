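"""Independent brute-force oracles used to cross-check the package.

Everything here is written as a direct transcription of the defining
formulas (explicit loops, flood fill, normal equations) and deliberately
shares no code with ``intpipe``.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def acf_biased(x, max_lag):
    """Biased (1/T denominator) sample ACF by direct summation."""
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    denom = float(np.sum(d * d))
    return np.array(
        [np.sum(d[: x.size - k] * d[k:]) / denom for k in range(max_lag + 1)]
    )


def int_by_scan(acf_values, tr, include_lag0=False):
    """INT by a literal scan of the ACF from lag 1 to the first negative."""
    total = 1.0 if include_lag0 else 0.0
    for k in range(1, len(acf_values)):
        if acf_values[k] < 0:
            break
        total += acf_values[k]
    return tr * total


def pooled_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def welch_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df


def t_pvalue(t, df):
    from scipy.special import stdtr

    return 2.0 * float(stdtr(df, -abs(t)))


def pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    r = float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))
    n = x.size
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, t_pvalue(t, n - 2)


def _neighbour_offsets(connectivity):
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    return offsets


def connected_components(binary, connectivity):
    """Flood-fill connected components; returns a list of voxel-index sets."""
    binary = np.asarray(binary, dtype=bool)
    offsets = _neighbour_offsets(connectivity)
    seen = np.zeros(binary.shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            vox = queue.popleft()
            comp.add(vox)
            for off in offsets:
                nb = tuple(v + o for v, o in zip(vox, off))
                if any(c < 0 or c >= s for c, s in zip(nb, binary.shape)):
                    continue
                if binary[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(comp)
    return components


def _dummy_columns(col):
    """Treatment-coded dummies for a categorical column (levels sorted)."""
    col = np.asarray(col)
    levels = sorted(set(col.tolist()))
    return [np.asarray(col == lev, dtype=float) for lev in levels[1:]]


def type2_main_effects(y, factors):
    """Type II F per term in an additive OLS model, via RSS comparisons.

    For each term, fit the full additive model and the model with that term
    dropped (both by normal equations / lstsq) and form
    ``F = ((RSS_drop - RSS_full) / df_term) / (RSS_full / df_resid)``.
    """
    from scipy.special import fdtrc

    y = np.asarray(y, dtype=float)
    blocks = {}
    for name, col in factors.items():
        arr = np.asarray(col)
        if arr.dtype.kind in "OUS":
            blocks[name] = _dummy_columns(arr)
        else:
            blocks[name] = [arr.astype(float)]

    def rss(cols):
        X = np.column_stack([np.ones(y.size)] + cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), X.shape[1]

    full_cols = [c for cols in blocks.values() for c in cols]
    rss_full, k_full = rss(full_cols)
    df_resid = y.size - k_full
    out = {}
    for name in factors:
        reduced = [c for other, cols in blocks.items() if other != name for c in cols]
        rss_red, _ = rss(reduced)
        df_term = len(blocks[name])
        F = ((rss_red - rss_full) / df_term) / (rss_full / df_resid)
        out[name] = (F, float(fdtrc(df_term, df_resid, F)))
    return out
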