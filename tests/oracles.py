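"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-implementations — per-pixel loops,
closed forms, exhaustive searches — kept free of any code path they
check.
"""

import numpy as np
from shapely.geometry import Point


def label_oracle(grid, impact_polys, control_buffer=None, control_polys=None,
                 exclude_polys=None, exclude_impact_buffer=None):
    """Exhaustive per-pixel geometric labelling: 1/0/NaN array."""
    labels = np.full(grid.shape, np.nan)
    for r in range(grid.height):
        for c in range(grid.width):
            x, y = grid.xy(r, c)
            p = Point(x, y)
            if any(poly.covers(p) for poly in impact_polys):
                labels[r, c] = 1.0
                continue
            d_imp = min(poly.distance(p) for poly in impact_polys)
            in_src = False
            if control_buffer is not None and d_imp <= control_buffer:
                in_src = True
            if control_polys is not None and any(g.covers(p) for g in control_polys):
                in_src = True
            if not in_src:
                continue
            if exclude_polys is not None and any(g.covers(p) for g in exclude_polys):
                continue
            if exclude_impact_buffer is not None and d_imp <= exclude_impact_buffer:
                continue
            labels[r, c] = 0.0
    return labels


def greedy_match_oracle(impact_ids, control_ids, impact_scores, control_scores,
                        ratio, replace, caliper_abs, order_idx):
    """Naive greedy sequential nearest-neighbour matching on 1-D scores.

    Returns a set of (impact_id, control_id, rank) triples and the list
    of unmatched impact ids.  ``order_idx`` gives the processing order
    as indices into ``impact_ids``.
    """
    pool = {int(c) for c in control_ids}
    pairs = set()
    unmatched = []
    for i in order_idx:
        iid = int(impact_ids[i])
        cands = []
        for j, cid in enumerate(control_ids):
            if not replace and int(cid) not in pool:
                continue
            d = abs(impact_scores[i] - control_scores[j])
            if caliper_abs is not None and d > caliper_abs:
                continue
            cands.append((d, int(cid)))
        cands.sort()
        take = cands[:ratio]
        if not take:
            unmatched.append(iid)
            continue
        for rank, (_, cid) in enumerate(take, start=1):
            pairs.add((iid, cid, rank))
            if not replace:
                pool.discard(cid)
    return pairs, unmatched


def vif_oracle(X):
    """1/(1-R^2) per column, R^2 via numpy lstsq with explicit intercept."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        A = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def ols_slope_oracle(t, v):
    """Closed-form OLS slope of v on t (finite pairs only)."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    ok = np.isfinite(t) & np.isfinite(v)
    t, v = t[ok], v[ok]
    tb, vb = t.mean(), v.mean()
    return float(((t - tb) * (v - vb)).sum() / ((t - tb) ** 2).sum())


def masked_median_oracle(stack_vals, masks):
    """Element-wise median over valid observations; NaN where none."""
    n_obs, h, w = stack_vals.shape
    out = np.full((h, w), np.nan)
    for r in range(h):
        for c in range(w):
            vals = [
                stack_vals[k, r, c]
                for k in range(n_obs)
                if masks[k, r, c] and np.isfinite(stack_vals[k, r, c])
            ]
            if vals:
                out[r, c] = float(np.median(vals))
    return out
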