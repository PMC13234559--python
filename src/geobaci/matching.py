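"""Control-impact matching on covariates and balance evaluation.

Supports nearest-neighbour matching on a propensity score (logistic
regression, distances on the logit scale) or on Mahalanobis distance,
and exact matching on categorical covariates.  Balance diagnostics use
standardised mean differences with a fixed pre-matching pooled-SD
denominator, so before/after SMDs are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .covariates import expand_categoricals

__all__ = [
    "DistanceModel",
    "MatchResult",
    "fit_propensity",
    "mahalanobis_distances",
    "match_nearest",
    "match_exact",
    "balance_evaluation",
    "BalanceReport",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceModel:
    """Fitted distance metric for matching.

    ``kind`` is ``"propensity-logistic"``, ``"mahalanobis"`` or
    ``"user"``.  For the propensity model, ``scores`` holds per-unit
    probabilities and ``logit_scores`` the linear predictor (matching
    distances and calipers operate on the logit scale).  For Mahalanobis
    matching ``covariance`` is the pooled covariate covariance.
    """

    kind: str
    unit_ids: np.ndarray
    scores: pd.Series | None = None
    logit_scores: pd.Series | None = None
    coefficients: pd.Series | None = None
    covariance: np.ndarray | None = None
    covariance_inv: np.ndarray | None = None
    design_columns: list[str] = field(default_factory=list)


def fit_propensity(table: pd.DataFrame) -> DistanceModel:
    """Logistic regression of treatment on covariates (with intercept).

    Returns per-unit propensity scores and logit scores.  Perfect
    separation and non-convergence raise with advice to revise the
    covariate set.
    """
    X = expand_categoricals(table)
    if X.shape[1] < 1:
        raise ValueError("no covariates to fit the propensity model on")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        # zero-variance covariates carry no information; intercept-only
        # limit gives every unit the treatment prevalence as its score
        log.warning("dropping constant covariate(s) from propensity model: %s", const)
        X = X.drop(columns=const)
    y = table["treatment"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both treatment classes required")

    # indicator levels containing a single treatment class make that
    # coefficient diverge (quasi-separation); those units can never be
    # propensity-matched on that level anyway, so drop the indicator
    one_sided = [
        c
        for c in X.columns
        if X[c].nunique() == 2
        and set(X[c].unique()) == {0.0, 1.0}
        and (y[X[c] == 1].min() == y[X[c] == 1].max())
    ]
    if one_sided:
        log.warning(
            "dropping one-sided indicator(s) from propensity model "
            "(single treatment class in level): %s", one_sided,
        )
        X = X.drop(columns=one_sided)

    # standardise continuous columns for a well-conditioned fit; the
    # scores are invariant and coefficients are rescaled back below
    mu = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    binary = X.nunique() <= 2
    mu[binary] = 0.0
    sd[binary] = 1.0
    Z = (X - mu) / sd
    design = sm.add_constant(Z.to_numpy(), has_constant="add")

    params = None
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if fit.mle_retvals.get("converged", True):
            params = np.asarray(fit.params)
    except Exception:
        params = None
    if params is None:
        # Newton can fail near (quasi-)separation; IRLS maximises the
        # same likelihood and is far more forgiving
        try:
            with np.errstate(all="ignore"):
                glm = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception as exc:
            raise ValueError(
                "propensity model failed (possible perfect separation); "
                f"review the covariate set: {exc}"
            ) from exc
        if not glm.converged:
            raise ValueError("propensity model did not converge after 200 iterations")
        log.warning("propensity Logit fell back to IRLS (near-separation)")
        params = np.asarray(glm.params)

    eta = design @ params
    if eta[y == 1].min() > eta[y == 0].max():
        # ML found a hyperplane perfectly splitting the classes: the
        # coefficients diverge and propensities are degenerate 0/1
        raise ValueError(
            "perfect separation: the covariates perfectly predict treatment; "
            "review the covariate set"
        )
    p = 1.0 / (1.0 + np.exp(-eta))
    ids = table["unit_id"].to_numpy()
    slopes = params[1:] / sd.to_numpy()
    const = params[0] - float(np.sum(params[1:] * (mu / sd).to_numpy()))
    coef = pd.Series(np.r_[const, slopes], index=["const"] + list(X.columns))
    return DistanceModel(
        kind="propensity-logistic",
        unit_ids=ids,
        scores=pd.Series(p, index=ids, name="propensity"),
        logit_scores=pd.Series(eta, index=ids, name="logit"),
        coefficients=coef,
        design_columns=list(X.columns),
    )


def mahalanobis_distances(
    table: pd.DataFrame, model: DistanceModel | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, DistanceModel]:
    """Impact x control Mahalanobis distance matrix.

    d(i, c) = sqrt((x_i - x_c)' S^-1 (x_i - x_c)) with S the covariate
    covariance over all units, ridge-regularised when ill-conditioned.
    """
    X = expand_categoricals(table)
    if X.shape[1] < 1:
        raise ValueError("Mahalanobis distance needs at least one covariate")
    V = X.to_numpy()
    if model is None or model.covariance_inv is None:
        S = np.cov(V, rowvar=False)
        S = np.atleast_2d(S)
        if np.linalg.cond(S) > 1e12:
            S = S + np.eye(S.shape[0]) * 1e-10 * np.trace(S) / S.shape[0]
        try:
            S_inv = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariate covariance singular after regularisation") from exc
        model = DistanceModel(
            kind="mahalanobis",
            unit_ids=table["unit_id"].to_numpy(),
            covariance=S,
            covariance_inv=S_inv,
            design_columns=list(X.columns),
        )
    treat = table["treatment"].to_numpy() == 1
    Xi, Xc = V[treat], V[~treat]
    diff = Xi[:, None, :] - Xc[None, :, :]
    d2 = np.einsum("ick,kl,icl->ic", diff, model.covariance_inv, diff)
    D = np.sqrt(np.maximum(d2, 0.0))
    ids = table["unit_id"].to_numpy()
    return D, ids[treat], ids[~treat], model


@dataclass
class MatchResult:
    """Matched impact-control pairs plus the model and match settings.

    ``pairs`` columns: impact_id, control_id, rank, distance, weight.
    ``control_weights`` counts how often each control was selected
    (replacement reuse).  ``spec`` records ratio/replace/caliper/
    caliper_scale/order for provenance.
    """

    pairs: pd.DataFrame
    model: DistanceModel | None
    spec: dict
    unmatched_impact: list = field(default_factory=list)
    grid: object | None = None

    @property
    def control_weights(self) -> pd.Series:
        if self.pairs.empty:
            return pd.Series(dtype=float, name="weight")
        return self.pairs.groupby("control_id")["weight"].sum()

    @property
    def n_matched_impact(self) -> int:
        return self.pairs["impact_id"].nunique() if not self.pairs.empty else 0


def _impact_order(order: str, impact_ids, extremity, rng) -> np.ndarray:
    idx = np.arange(len(impact_ids))
    if order == "data":
        return idx
    if order == "random":
        return rng.permutation(idx)
    if order == "extremity":
        # hardest-to-match first; ties by unit id for determinism
        key = np.lexsort((impact_ids, -extremity))
        return key
    raise ValueError(f"unknown order {order!r}")


def match_nearest(
    table: pd.DataFrame,
    model: DistanceModel,
    ratio: int = 1,
    replace: bool = False,
    caliper: float | None = None,
    order: str = "extremity",
    seed: int = 0,
) -> MatchResult:
    """Greedy sequential nearest-neighbour matching.

    Impact units are processed in ``order`` (default: descending
    extremity of their distance score, i.e. hardest first; only relevant
    without replacement).  Each takes its ``ratio`` nearest eligible
    controls; ties go to the lowest control id.  For a propensity model
    the distance is |logit_i - logit_c| and the caliper is expressed in
    standard deviations of the logit scores over all units; for a
    distance matrix the caliper is on the raw distance.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    treat = table["treatment"].to_numpy() == 1
    ids = table["unit_id"].to_numpy()
    impact_ids, control_ids = ids[treat], ids[~treat]
    if impact_ids.size == 0 or control_ids.size == 0:
        raise ValueError("both impact and control units required")
    if not replace and caliper is None and control_ids.size < ratio * impact_ids.size:
        raise ValueError(
            f"need {ratio * impact_ids.size} controls for ratio={ratio} without "
            f"replacement, have {control_ids.size}"
        )

    caliper_scale = None
    caliper_abs = None
    if model.kind == "propensity-logistic":
        s = model.logit_scores
        si = s.loc[impact_ids].to_numpy()
        sc = s.loc[control_ids].to_numpy()
        D = np.abs(si[:, None] - sc[None, :])
        extremity = np.abs(si - np.mean(s.to_numpy()))
        if caliper is not None:
            caliper_scale = "sd-of-logit"
            caliper_abs = caliper * np.std(s.to_numpy(), ddof=1)
    elif model.kind == "mahalanobis":
        D, impact_ids, control_ids, model = mahalanobis_distances(table, model)
        extremity = D.min(axis=1)
        if caliper is not None:
            caliper_scale = "raw"
            caliper_abs = caliper
    else:
        raise ValueError(f"cannot match on model kind {model.kind!r}")

    # eligibility mask: beyond-caliper pairs never match
    eligible = np.ones_like(D, dtype=bool)
    if caliper_abs is not None:
        eligible &= D <= caliper_abs

    rows = []
    unmatched = []
    in_pool = np.ones(control_ids.size, dtype=bool)
    for i in _impact_order(order, impact_ids, extremity, rng):
        ok = eligible[i] & (in_pool if not replace else True)
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            unmatched.append(int(impact_ids[i]))
            continue
        # sort by (distance, control_id): deterministic tie-break
        key = np.lexsort((control_ids[cand], D[i, cand]))
        take = cand[key[:ratio]]
        for rank, j in enumerate(take, start=1):
            rows.append((int(impact_ids[i]), int(control_ids[j]), rank, float(D[i, j])))
        if not replace:
            in_pool[take] = False

    if not rows:
        log.warning("no matches found (caliper too tight?); all impact units unmatched")
    pairs = pd.DataFrame(rows, columns=["impact_id", "control_id", "rank", "distance"])
    pairs["weight"] = 1.0
    pairs = pairs.sort_values(["impact_id", "rank"], kind="stable").reset_index(drop=True)
    return MatchResult(
        pairs=pairs,
        model=model,
        spec={
            "method": "nearest",
            "ratio": ratio,
            "replace": replace,
            "caliper": caliper,
            "caliper_scale": caliper_scale,
            "order": order,
            "seed": seed,
        },
        unmatched_impact=sorted(unmatched),
    )


def match_exact(table: pd.DataFrame, vars: list[str]) -> MatchResult:
    """Exact matching: each impact unit pairs with every control sharing
    its combination of ``vars``; pair weights are 1/k for the k controls
    in the stratum."""
    for v in vars:
        if v not in table.columns:
            raise ValueError(f"unknown matching variable {v!r}")
    rows = []
    unmatched = []
    matched_any = False
    for _, stratum in table.groupby(list(vars), sort=True):
        imp = stratum.loc[stratum["treatment"] == 1, "unit_id"]
        ctl = stratum.loc[stratum["treatment"] == 0, "unit_id"]
        if imp.empty:
            continue
        if ctl.empty:
            unmatched.extend(int(u) for u in imp)
            continue
        matched_any = True
        w = 1.0 / len(ctl)
        for iu in imp:
            for rank, cu in enumerate(sorted(ctl), start=1):
                rows.append((int(iu), int(cu), rank, 0.0, w))
    if not matched_any:
        raise ValueError("no stratum contains both impact and control units")
    pairs = pd.DataFrame(
        rows, columns=["impact_id", "control_id", "rank", "distance", "weight"]
    )
    return MatchResult(
        pairs=pairs,
        model=None,
        spec={"method": "exact", "vars": list(vars)},
        unmatched_impact=sorted(unmatched),
    )


@dataclass
class BalanceReport:
    """Covariate balance before/after matching.

    ``smd`` has one row per covariate (plus the distance score where
    available): SMD before and after matching and variance ratios.
    ``control_selection`` counts reuse of each matched control;
    ``overlap`` holds binned density data per covariate for plotting.
    """

    smd: pd.DataFrame
    control_selection: pd.Series
    overlap: dict
    n_unmatched_impact: int

    def __str__(self) -> str:
        with pd.option_context("display.float_format", "{:8.4f}".format):
            return (
                f"Balance report ({len(self.smd)} variables, "
                f"{self.n_unmatched_impact} unmatched impact units)\n"
                + self.smd.to_string()
            )


def _weighted_mean_var(v: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    w = w / w.sum()
    m = float(np.sum(w * v))
    return m, float(np.sum(w * (v - m) ** 2))


def balance_evaluation(
    result: MatchResult, table: pd.DataFrame, bins: int = 30
) -> BalanceReport:
    """Standardised mean differences and overlap before/after matching.

    SMD_before = (mean_impact - mean_all_controls) / SD_pooled with
    SD_pooled = sqrt((var_impact + var_control)/2) over the unmatched
    sample; SMD_after reuses the same denominator with match-weighted
    controls (fixed-denominator convention).  A zero pooled SD makes the
    SMD undefined (NaN).
    """
    if result.pairs.empty:
        raise ValueError("empty match result: nothing to evaluate")
    tab = table.set_index("unit_id")
    X = expand_categoricals(table).set_index(table["unit_id"])
    if result.model is not None and result.model.logit_scores is not None:
        X.insert(0, "distance_score", result.model.logit_scores.reindex(X.index))

    treat = tab["treatment"] == 1
    impact_all = X.loc[treat[treat].index]
    control_all = X.loc[treat[~treat].index]
    matched_impact = X.loc[sorted(result.pairs["impact_id"].unique())]
    cw = result.pairs.groupby("control_id")["weight"].sum()
    matched_control = X.loc[cw.index]
    w = cw.to_numpy()

    rows = []
    overlap = {}
    for col in X.columns:
        vi, vc = impact_all[col].to_numpy(), control_all[col].to_numpy()
        var_i, var_c = np.var(vi, ddof=1), np.var(vc, ddof=1)
        sd_pool = np.sqrt((var_i + var_c) / 2.0)
        smd_b = (vi.mean() - vc.mean()) / sd_pool if sd_pool > 0 else np.nan
        mi_a = matched_impact[col].to_numpy().mean()
        mc_a, vc_a = _weighted_mean_var(matched_control[col].to_numpy(), w)
        smd_a = (mi_a - mc_a) / sd_pool if sd_pool > 0 else np.nan
        vr_b = var_i / var_c if var_c > 0 else np.nan
        vr_a = (
            np.var(matched_impact[col].to_numpy(), ddof=1) / vc_a if vc_a > 0 else np.nan
        )
        rows.append((col, smd_b, smd_a, vr_b, vr_a))

        lo = np.nanmin(np.concatenate([vi, vc]))
        hi = np.nanmax(np.concatenate([vi, vc]))
        edges = np.linspace(lo, hi, bins + 1) if hi > lo else np.array([lo - 0.5, lo + 0.5])
        overlap[col] = {
            "edges": edges,
            "impact": np.histogram(vi, bins=edges, density=True)[0],
            "control_before": np.histogram(vc, bins=edges, density=True)[0],
            "control_after": np.histogram(
                matched_control[col].to_numpy(), bins=edges, weights=w, density=True
            )[0],
        }

    smd = pd.DataFrame(
        rows, columns=["variable", "smd_before", "smd_after", "vr_before", "vr_after"]
    ).set_index("variable")
    return BalanceReport(
        smd=smd,
        control_selection=result.pairs.groupby("control_id").size().rename("n_selected"),
        overlap=overlap,
        n_unmatched_impact=len(result.unmatched_impact),
    )
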