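"""Multivariate-regression calibration of concentration against (x1, x2).

The calibrator is an ordinary-least-squares polynomial in the NO-sensor
eigenvalue x1 and the scaled flow eigenvalue x2.  Two forms are offered:

* ``linear``:     y = b0 + b1*x1 + b2*x2
* ``quadratic``:  y = b0 + b1*x1 + b2*x2 + b3*x1*x2 + b4*x2**2

The quadratic term set deliberately omits x1**2 — the sensor response is
close to linear in concentration, while the flow dependence is curved —
matching the form used for flow correction in this instrument class; a
``full_quadratic`` variant with the x1**2 term is available behind the
``form`` flag.  Model selection compares candidates by coefficient t-tests
and the overall F-test first, then AIC, then RMSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import CalibrationSample

__all__ = [
    "LINEAR_TERMS",
    "QUADRATIC_TERMS",
    "FULL_QUADRATIC_TERMS",
    "MRModel",
    "reference_quadratic",
    "fit_mr",
    "predict_mr",
    "model_select",
    "comparison_table",
]

# Monomial terms as (power of x1, power of x2); the intercept is implicit.
LINEAR_TERMS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1))
QUADRATIC_TERMS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (0, 2))
FULL_QUADRATIC_TERMS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (0, 2), (2, 0))

_FORMS = {"linear": LINEAR_TERMS, "quadratic": QUADRATIC_TERMS, "full_quadratic": FULL_QUADRATIC_TERMS}


@dataclass
class MRModel:
    """A fitted polynomial calibrator with its fit statistics.

    ``coef[0]`` is the intercept; ``coef[1:]`` follow ``terms``.  The
    scaling metadata records the conventions the model was fitted under:
    ``x2_divisor`` is the factor the raw flow eigenvalue (SCCM) was divided
    by upstream, and ``y_scale`` the factor dividing the concentration.
    AIC uses the Gaussian profile form ``n*ln(SSE/n) + 2*(k+1)``.
    """

    form: str
    terms: tuple[tuple[int, int], ...]
    coef: np.ndarray
    se: np.ndarray | None = None
    t_values: np.ndarray | None = None
    p_values: np.ndarray | None = None
    f_pvalue: float = np.nan
    r2_adj: float = np.nan
    rmse: float = np.nan
    aic: float = np.nan
    n: int = 0
    x2_divisor: float = 1000.0
    y_scale: float = 1.0

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (len(self.terms) + 1,):
            raise ValueError("need exactly one coefficient per term plus the intercept")

    def predict(self, x1, x2):
        return predict_mr(self, x1, x2)

    def to_dict(self) -> dict:
        return {
            "kind": "mr",
            "form": self.form,
            "terms": [list(t) for t in self.terms],
            "coef": self.coef.tolist(),
            "se": None if self.se is None else np.asarray(self.se).tolist(),
            "t_values": None if self.t_values is None else np.asarray(self.t_values).tolist(),
            "p_values": None if self.p_values is None else np.asarray(self.p_values).tolist(),
            "f_pvalue": None if np.isnan(self.f_pvalue) else self.f_pvalue,
            "r2_adj": None if np.isnan(self.r2_adj) else self.r2_adj,
            "rmse": None if np.isnan(self.rmse) else self.rmse,
            "aic": None if np.isnan(self.aic) else self.aic,
            "n": self.n,
            "x2_divisor": self.x2_divisor,
            "y_scale": self.y_scale,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MRModel":
        def arr(v):
            return None if v is None else np.asarray(v, dtype=float)

        def num(v):
            return np.nan if v is None else float(v)

        return cls(
            form=data["form"],
            terms=tuple(tuple(t) for t in data["terms"]),
            coef=np.asarray(data["coef"], dtype=float),
            se=arr(data.get("se")),
            t_values=arr(data.get("t_values")),
            p_values=arr(data.get("p_values")),
            f_pvalue=num(data.get("f_pvalue")),
            r2_adj=num(data.get("r2_adj")),
            rmse=num(data.get("rmse")),
            aic=num(data.get("aic")),
            n=int(data.get("n", 0)),
            x2_divisor=float(data.get("x2_divisor", 1000.0)),
            y_scale=float(data.get("y_scale", 1.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MRModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: The reference quadratic flow-correction calibration: a fixed coefficient
#: set, in term order (1, x1, x2, x1*x2, x2^2), used throughout the tests as
#: a known ground truth for coefficient recovery and as the worked example.
REFERENCE_QUADRATIC_COEF: tuple[float, ...] = (0.41225, 1.3929, -0.35554, -0.063957, 0.075741)


def reference_quadratic() -> MRModel:
    """The reference quadratic calibrator (fixed, immutable coefficients)."""
    return MRModel(form="quadratic", terms=QUADRATIC_TERMS, coef=np.array(REFERENCE_QUADRATIC_COEF))


def _design_matrix(x1: np.ndarray, x2: np.ndarray, terms) -> np.ndarray:
    cols = [np.ones_like(x1)] + [x1**p * x2**q for p, q in terms]
    return np.column_stack(cols)


def fit_mr(
    samples: Sequence[CalibrationSample] | None = None,
    *,
    x1=None,
    x2=None,
    y=None,
    form: str = "quadratic",
    x2_divisor: float = 1000.0,
    y_scale: float = 1.0,
) -> MRModel:
    """Least-squares fit of the chosen polynomial form.

    Accepts either a list of calibration samples or explicit ``x1, x2, y``
    arrays.  Raises on a rank-deficient design or too few samples.
    """
    if form not in _FORMS:
        raise ValueError(f"form must be one of {sorted(_FORMS)}, got {form!r}")
    terms = _FORMS[form]
    if samples is not None:
        x1 = np.array([s.x1 for s in samples], dtype=float)
        x2 = np.array([s.x2 for s in samples], dtype=float)
        y = np.array([s.y for s in samples], dtype=float)
    else:
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        y = np.asarray(y, dtype=float)
    k = len(terms)
    n = y.size
    if n < k + 1:
        raise ValueError(f"too few samples: need at least {k + 1}, got {n}")
    X = _design_matrix(x1, x2, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fit: design matrix is rank deficient")

    ols = sm.OLS(y, X).fit()
    sse = float(np.sum(ols.resid**2))
    rmse = float(np.sqrt(sse / n))
    aic = n * np.log(max(sse / n, 1e-300)) + 2 * (k + 1)
    return MRModel(
        form=form,
        terms=terms,
        coef=np.asarray(ols.params, dtype=float),
        se=np.asarray(ols.bse, dtype=float),
        t_values=np.asarray(ols.tvalues, dtype=float),
        p_values=np.asarray(ols.pvalues, dtype=float),
        f_pvalue=float(ols.f_pvalue),
        r2_adj=float(ols.rsquared_adj),
        rmse=rmse,
        aic=float(aic),
        n=n,
        x2_divisor=x2_divisor,
        y_scale=y_scale,
    )


def predict_mr(model: MRModel, x1, x2):
    """Evaluate the fitted polynomial at (x1, x2), on the model's input scale."""
    x1a = np.asarray(x1, dtype=float)
    x2a = np.asarray(x2, dtype=float)
    if np.any(~np.isfinite(x1a)) or np.any(~np.isfinite(x2a)):
        raise ValueError("inputs must be finite")
    out = _design_matrix(np.atleast_1d(x1a), np.atleast_1d(x2a), model.terms) @ model.coef
    out = out * model.y_scale
    return float(out[0]) if np.isscalar(x1) or x1a.ndim == 0 else out.reshape(x1a.shape)


def comparison_table(candidates: Sequence[MRModel], alpha: float = 0.05) -> pd.DataFrame:
    """Side-by-side comparison of candidate fits."""
    rows = []
    for m in candidates:
        all_sig = (
            m.p_values is not None
            and np.all(m.p_values < alpha)
            and np.isfinite(m.f_pvalue)
            and m.f_pvalue < alpha
        )
        rows.append(
            {
                "form": m.form,
                "n_terms": len(m.terms),
                "max_coef_p": np.nan if m.p_values is None else float(np.max(m.p_values)),
                "f_pvalue": m.f_pvalue,
                "all_significant": bool(all_sig),
                "r2_adj": m.r2_adj,
                "rmse": m.rmse,
                "aic": m.aic,
            }
        )
    return pd.DataFrame(rows)


def model_select(candidates: Sequence[MRModel], alpha: float = 0.05) -> MRModel:
    """Pick the preferred calibrator.

    Lexicographic rule: models whose coefficients are all significant at
    ``alpha`` (t-tests) with a significant overall F-test are preferred;
    within a tier, lowest AIC wins; ties break on lowest RMSE.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate model")
    table = comparison_table(candidates, alpha)

    def sort_key(i: int):
        row = table.iloc[i]
        return (not row["all_significant"], row["aic"], row["rmse"])

    best = min(range(len(candidates)), key=sort_key)
    return candidates[best]
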