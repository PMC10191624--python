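"""Statistical scaffold: Box-Cox transform, interaction models with type-III
F tests, per-temperature follow-ups, and Benjamini-Hochberg correction.

The headline analysis fits a Gaussian linear model to a (Box-Cox
transformed) response with temperature as a continuous covariate, mating
system as a factor, and their interaction; each term is tested with a
type-III F computed as a full-versus-reduced model comparison.  When the
interaction is of interest, per-temperature follow-up models estimate the
mating-system effect within each temperature stratum.  Raw p-values across
a family of responses are corrected with the Benjamini-Hochberg step-up
procedure.

Responses that include zeros or negatives are shifted positive before the
Box-Cox transform; the shift is recorded in the fit.  Survival-model,
Gamma/binomial and zero-inflated analyses are deliberately not implemented
here — the component tables this package exports are analysis-ready inputs
for standard survival/GLM software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "BoxCoxFit",
    "TermTest",
    "ModelResult",
    "boxcox_fit",
    "boxcox_transform",
    "fit_interaction_model",
    "per_temperature_models",
    "bh_adjust",
    "apply_bh",
]

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(-2.0, 2.0001, 0.05), 10))


# ---------------------------------------------------------------------------
# Box-Cox


@dataclass(frozen=True)
class BoxCoxFit:
    """Profile-likelihood Box-Cox fit over a lambda grid."""

    lambda_: float
    shift: float
    loglik_profile: tuple[tuple[float, float], ...]  # (lambda, loglik)


def boxcox_fit(values: Sequence[float], lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID) -> BoxCoxFit:
    """Choose the Box-Cox lambda maximizing the profile log-likelihood.

    If any value is <= 0, all values are shifted by ``1 - min(values)`` first
    (zero responses are legitimate data, e.g. females with zero lifetime
    offspring); the shift is part of the fit and applied by
    :func:`boxcox_transform`.
    """
    y = np.asarray(values, dtype=float)
    if y.size == 0 or not np.all(np.isfinite(y)):
        raise ValueError("Box-Cox requires a non-empty, finite sample")
    grid = list(lambda_grid)
    if not grid:
        raise ValueError("lambda grid is empty")
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - y.min()
    ys = y + shift
    profile = [(float(lam), float(sps.boxcox_llf(lam, ys))) for lam in grid]
    best = max(profile, key=lambda p: p[1])
    return BoxCoxFit(lambda_=best[0], shift=shift, loglik_profile=tuple(profile))


def boxcox_transform(values: Sequence[float], fit: BoxCoxFit) -> np.ndarray:
    """Apply a fitted transform: ((y+shift)^lambda - 1)/lambda, log at lambda=0."""
    ys = np.asarray(values, dtype=float) + fit.shift
    if np.any(ys <= 0):
        raise ValueError("values not strictly positive after recorded shift")
    if fit.lambda_ == 0:
        return np.log(ys)
    return (ys**fit.lambda_ - 1.0) / fit.lambda_


# ---------------------------------------------------------------------------
# linear models with type-III F


@dataclass(frozen=True)
class TermTest:
    term: str
    estimate: Optional[float]  # coefficient when the term is 1 df, else None
    ci_low: Optional[float]
    ci_high: Optional[float]
    F: float
    df_num: int
    df_den: int
    p: float
    p_adj: Optional[float] = None


@dataclass
class ModelResult:
    """Type-III F tests for one response, with per-term estimates and CIs."""

    response: str
    stratum: Optional[str]  # e.g. "24.0" for per-temperature models
    terms: list[TermTest]
    nobs: int

    def term(self, name: str) -> TermTest:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "response": self.response,
                    "stratum": self.stratum,
                    "term": t.term,
                    "estimate": t.estimate,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "F": t.F,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "p": t.p,
                    "p_adj": t.p_adj,
                }
                for t in self.terms
            ]
        )


def _design_columns(df: pd.DataFrame, temperature_as: str):
    """Design-matrix building blocks plus a map term -> column indices.

    ``temperature_as`` is 'covariate' (continuous, centred) or
    'factor_quadratic' (orthogonal-polynomial linear + quadratic contrasts).
    """
    system = (df["mating_system"] == "polyandry").astype(float).to_numpy()
    temp = df["temperature"].astype(float).to_numpy()
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["Intercept"]
    term_cols: dict[str, list[int]] = {}
    if temperature_as == "covariate":
        tc = temp - temp.mean()
        cols.append(tc)
        names.append("temperature")
        term_cols["temperature"] = [1]
        t_block = [tc]
    elif temperature_as == "factor_quadratic":
        levels = np.sort(np.unique(temp))
        if len(levels) != 3:
            raise ValueError("quadratic contrasts need exactly three temperature levels")
        lin_map = dict(zip(levels, (-1.0, 0.0, 1.0)))
        quad_map = dict(zip(levels, (1.0, -2.0, 1.0)))
        lin = np.array([lin_map[t] for t in temp])
        quad = np.array([quad_map[t] for t in temp])
        cols += [lin, quad]
        names += ["temperature_lin", "temperature_quad"]
        term_cols["temperature"] = [1, 2]
        t_block = [lin, quad]
    else:
        raise ValueError(f"unknown temperature coding {temperature_as!r}")
    return system, term_cols, names, cols, t_block


def _ols_sse(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rank = np.linalg.matrix_rank(X)
    return float(resid @ resid), int(len(y) - rank)


def fit_interaction_model(
    table: pd.DataFrame,
    response: str,
    include_main_system: bool = True,
    temperature_as: str = "covariate",
) -> ModelResult:
    """Gaussian linear model of ``response ~ temperature * mating_system``.

    Type-III F for each term is the change-in-SSE F between the full model
    and the model with that term's columns removed.  With
    ``include_main_system=False`` the main mating-system effect is dropped
    from the design (the collinearity refit: interaction retained, main
    effect omitted).
    """
    df = table.dropna(subset=[response, "temperature", "mating_system"]).copy()
    if df["mating_system"].nunique() < 2:
        raise ValueError("need both mating-system levels")
    if df["temperature"].nunique() < 2:
        raise ValueError("need at least two temperature values")
    y = df[response].astype(float).to_numpy()

    system, term_cols, names, cols, t_block = _design_columns(df, temperature_as)
    if include_main_system:
        term_cols["mating_system"] = [len(cols)]
        cols.append(system)
        names.append("mating_system[polyandry]")
    inter_idx = []
    for k, tcol in enumerate(t_block):
        inter_idx.append(len(cols))
        cols.append(tcol * system)
        names.append(f"temperature:mating_system[{k}]" if len(t_block) > 1 else "temperature:mating_system")
    term_cols["temperature:mating_system"] = inter_idx

    X = np.column_stack(cols)
    model = sm.OLS(y, X)
    res = model.fit()
    sse_full, df_den = _ols_sse(y, X)

    terms: list[TermTest] = []
    for term, idxs in term_cols.items():
        keep = [j for j in range(X.shape[1]) if j not in idxs]
        sse_red, _ = _ols_sse(y, X[:, keep])
        df_num = len(idxs)
        if df_den <= 0 or sse_full <= 0:
            raise ValueError("degenerate fit: no residual degrees of freedom")
        F = ((sse_red - sse_full) / df_num) / (sse_full / df_den)
        p = float(sps.f.sf(F, df_num, df_den))
        if df_num == 1:
            j = idxs[0]
            est = float(res.params[j])
            ci = res.conf_int(alpha=0.05)
            lo, hi = float(ci[j][0]), float(ci[j][1])
        else:
            est = lo = hi = None
        terms.append(TermTest(term, est, lo, hi, float(F), df_num, int(df_den), p))
    return ModelResult(response=response, stratum=None, terms=terms, nobs=len(df))


def per_temperature_models(table: pd.DataFrame, response: str) -> list[ModelResult]:
    """One mating-system-effect model per temperature stratum.

    The estimate is the polyandry-minus-monogamy mean difference with its
    95% CI; strata with a single mating-system level are skipped with a
    warning.
    """
    out: list[ModelResult] = []
    df = table.dropna(subset=[response, "temperature", "mating_system"])
    for T in sorted(df["temperature"].unique()):
        cell = df[df["temperature"] == T]
        if cell["mating_system"].nunique() < 2:
            warnings.warn(f"temperature {T}: only one mating-system level; skipped")
            continue
        y = cell[response].astype(float).to_numpy()
        system = (cell["mating_system"] == "polyandry").astype(float).to_numpy()
        X = np.column_stack([np.ones(len(y)), system])
        res = sm.OLS(y, X).fit()
        sse_full, df_den = _ols_sse(y, X)
        sse_red, _ = _ols_sse(y, X[:, :1])
        F = (sse_red - sse_full) / (sse_full / df_den)
        p = float(sps.f.sf(F, 1, df_den))
        ci = res.conf_int(alpha=0.05)
        out.append(
            ModelResult(
                response=response,
                stratum=f"{T:g}",
                terms=[
                    TermTest(
                        "mating_system",
                        float(res.params[1]),
                        float(ci[1][0]),
                        float(ci[1][1]),
                        float(F),
                        1,
                        int(df_den),
                        p,
                    )
                ],
                nobs=len(cell),
            )
        )
    return out


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, mapped back to
    the input positions.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return [float(v) for v in out]


def apply_bh(results: Iterable[ModelResult]) -> list[ModelResult]:
    """Fill ``p_adj`` across all terms of a family of model results (one
    correction family per experiment, spanning responses and strata)."""
    results = list(results)
    flat: list[tuple[ModelResult, int]] = [
        (res, k) for res in results for k in range(len(res.terms))
    ]
    adj = bh_adjust([res.terms[k].p for res, k in flat])
    for (res, k), a in zip(flat, adj):
        t = res.terms[k]
        res.terms[k] = TermTest(
            t.term, t.estimate, t.ci_low, t.ci_high, t.F, t.df_num, t.df_den, t.p, a
        )
    return results
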