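"""Before-after-control-impact (BACI) difference-in-difference estimation.

For impact unit i with matched controls M(i) and weights w_c, the
per-unit contrast is

    contrast_i = (mu_CA - mu_CB) - (mu_IA - mu_IB)

where mu_I are the unit's own before/after values and mu_C the
match-weighted control means.  The overall contrast is the unweighted
mean over impact units; significance comes from a two-sided one-sample
t-test of the per-unit contrasts against zero.  Under this sign
convention a gain at the impact sites relative to their counterfactual
controls yields a NEGATIVE contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridGeometry, Raster
from .matching import MatchResult
from .timeseries import TsMetrics

__all__ = ["BaciModel", "BaciResults", "baci_contrast"]

log = logging.getLogger(__name__)


def _as_unit_values(obs, grid: GridGeometry | None) -> dict[str, np.ndarray]:
    """Normalise an observable container to {name: flat per-pixel array}."""
    if isinstance(obs, TsMetrics):
        return {k: np.asarray(v, dtype=float).ravel() for k, v in obs.observables().items()}
    if isinstance(obs, Mapping):
        out = {}
        for k, v in obs.items():
            arr = v.values if isinstance(v, Raster) else v
            out[k] = np.asarray(arr, dtype=float).ravel()
        return out
    raise TypeError("observables must be a TsMetrics or a mapping of name -> array/Raster")


class BaciModel:
    """BACI contrast model over matched units and before/after observables.

    Parameters
    ----------
    matches
        Matched impact-control pairs (``MatchResult``); unit ids index
        into the flattened observable rasters.
    before, after
        Observable layers for the two periods: a :class:`TsMetrics` or a
        mapping of observable name to 2-D array / :class:`Raster`.  The
        two periods must provide the same observable names.
    grid
        Grid geometry used for spatialising per-unit contrasts.
    """

    def __init__(self, matches: MatchResult, before, after, grid: GridGeometry | None = None):
        self.matches = matches
        self.grid = grid or getattr(before, "grid", None) or matches.grid
        self.before = _as_unit_values(before, self.grid)
        self.after = _as_unit_values(after, self.grid)
        if set(self.before) != set(self.after):
            raise ValueError(
                f"before/after observables differ: {sorted(self.before)} vs {sorted(self.after)}"
            )
        if matches.pairs.empty:
            raise ValueError("no matched pairs: cannot form a BACI contrast")

    @classmethod
    def from_metrics(
        cls, matches: MatchResult, before: TsMetrics, after: TsMetrics
    ) -> "BaciModel":
        return cls(matches, before, after, grid=before.grid)

    def fit(self, flip_sign: bool = False) -> "BaciResults":
        """Compute per-impact-unit contrasts, their mean, and the t-test."""
        pairs = self.matches.pairs
        rows = []
        per_impact = {}
        for name in sorted(self.before):
            vb, va = self.before[name], self.after[name]
            contrasts = {}
            n_excluded = 0
            for iid, grp in pairs.groupby("impact_id"):
                cid = grp["control_id"].to_numpy()
                w = grp["weight"].to_numpy()
                mu_ib, mu_ia = vb[iid], va[iid]
                cb, ca = vb[cid], va[cid]
                ok = np.isfinite(cb) & np.isfinite(ca)
                if not np.isfinite(mu_ib) or not np.isfinite(mu_ia) or not ok.any():
                    n_excluded += 1
                    continue
                wv = w[ok] / w[ok].sum()
                mu_cb = float(np.sum(wv * cb[ok]))
                mu_ca = float(np.sum(wv * ca[ok]))
                c = (mu_ca - mu_cb) - (mu_ia - mu_ib)
                contrasts[int(iid)] = -c if flip_sign else c
            vals = np.array(list(contrasts.values()))
            n = vals.size
            if n == 0:
                raise ValueError(f"no impact unit has complete data for observable {name!r}")
            contrast = float(vals.mean())
            t_stat = p = wilcoxon_p = np.nan
            df = n - 1
            degenerate = False
            if n < 2:
                log.warning("observable %r: only one impact unit; p-value undefined", name)
            else:
                sd = vals.std(ddof=1)
                if sd == 0:
                    degenerate = True
                    p = 0.0 if contrast != 0 else 1.0
                    t_stat = np.inf * np.sign(contrast) if contrast != 0 else 0.0
                    log.warning("observable %r: zero variance in contrasts", name)
                else:
                    res = stats.ttest_1samp(vals, 0.0)
                    t_stat, p = float(res.statistic), float(res.pvalue)
                    if n >= 2 and np.any(vals != vals[0]):
                        wilcoxon_p = float(stats.wilcoxon(vals).pvalue)
            rows.append(
                {
                    "observable": name,
                    "contrast": contrast,
                    "t": t_stat,
                    "df": df,
                    "p_value": p,
                    "wilcoxon_p": wilcoxon_p,
                    "n_impact": n,
                    "n_excluded": n_excluded,
                    "degenerate": degenerate,
                }
            )
            per_impact[name] = pd.Series(contrasts, name=name)
        table = pd.DataFrame(rows).set_index("observable")
        return BaciResults(
            table=table,
            per_impact=pd.DataFrame(per_impact),
            grid=self.grid,
            flip_sign=flip_sign,
        )


@dataclass
class BaciResults:
    """Fitted BACI contrasts.

    ``table`` has one row per observable: contrast, t, df, p_value, a
    Wilcoxon signed-rank companion p, and unit counts.  ``per_impact``
    is indexed by impact unit id with one column per observable.
    """

    table: pd.DataFrame
    per_impact: pd.DataFrame
    grid: GridGeometry | None = None
    flip_sign: bool = False

    @property
    def contrasts(self) -> pd.Series:
        return self.table["contrast"]

    def summary(self) -> str:
        sign = "impact-minus-control" if self.flip_sign else "control-minus-impact"
        lines = [
            "BACI difference-in-difference contrast",
            f"  sign convention: {sign}"
            + ("" if self.flip_sign else " (negative = gain at impact sites)"),
            "",
            f"  {'observable':<16s}{'contrast':>12s}{'t':>10s}{'df':>5s}"
            f"{'p-value':>12s}{'n':>6s}",
        ]
        for name, r in self.table.iterrows():
            lines.append(
                f"  {name:<16s}{r.contrast:>12.5f}{r.t:>10.3f}{int(r.df):>5d}"
                f"{r.p_value:>12.3g}{int(r.n_impact):>6d}"
            )
        excluded = int(self.table["n_excluded"].sum())
        if excluded:
            lines.append(f"  ({excluded} impact units excluded for missing observables)")
        return "\n".join(lines)

    def spatialise(self, grid: GridGeometry | None = None) -> dict[str, Raster]:
        """Rasters of per-impact-unit contrast plus a constant p-value band
        per observable, on the unit grid (NaN outside matched impact cells)."""
        grid = grid or self.grid
        if grid is None:
            raise ValueError("no grid available to spatialise on")
        out = {}
        for name in self.per_impact.columns:
            vals = np.full(grid.height * grid.width, np.nan)
            s = self.per_impact[name].dropna()
            vals[s.index.to_numpy().astype(int)] = s.to_numpy()
            out[f"{name}_contrast"] = Raster(f"{name}_contrast", vals.reshape(grid.shape), grid)
            pband = np.where(
                np.isfinite(vals), self.table.loc[name, "p_value"], np.nan
            ).reshape(grid.shape)
            out[f"{name}_p"] = Raster(f"{name}_p", pband, grid)
        return out


def baci_contrast(matches: MatchResult, before, after, flip_sign: bool = False) -> BaciResults:
    """Convenience wrapper: build a :class:`BaciModel` and fit it."""
    return BaciModel(matches, before, after).fit(flip_sign=flip_sign)
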