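"""Ordinary least-squares fitting of the response models, ANOVA summaries,
prediction, and pooled replicate variance.

The ANOVA convention for the no-intercept mixture models is the Scheffé one:
the total sum of squares is mean-corrected and the regression degrees of
freedom are ``p - 1``, because the mixture terms jointly absorb the
intercept (the linear-blend columns sum to 1 on every row).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import stats
from scipy.linalg import qr

from .dataset import RESPONSES, RunCondition, StudyDataset
from .design import ModelSpec, matrix_from_arrays, model_matrix
from .errors import (
    ArgumentError,
    DegenerateResponseError,
    DataError,
    FittingError,
)

__all__ = [
    "FitResult",
    "fit_response",
    "anova_regression",
    "predict",
    "predict_many",
    "replicate_variance",
]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class FitResult:
    """OLS fit of one response to a :class:`~mixproc.design.ModelSpec`."""

    spec: ModelSpec
    response: str
    coeffs: np.ndarray
    stderr: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    sse: float
    sst: float
    r2: float
    f_stat: float
    p_value: float
    df_model: int
    df_resid: int

    @property
    def n_obs(self) -> int:
        return len(self.residuals)

    @property
    def term_names(self) -> tuple[str, ...]:
        return self.spec.term_names

    def predict(self, condition: RunCondition, **kw) -> float:
        return predict(self, condition, **kw)

    def evaluate_batch(
        self, p80: np.ndarray, us: np.ndarray, blends: np.ndarray
    ) -> np.ndarray:
        """Vectorized prediction on parallel arrays of conditions."""
        x1 = (np.asarray(p80, float) - 50.0) / 50.0
        x2 = (np.asarray(us, float) - 5.5) / 4.5
        blends = np.asarray(blends, float)
        X = matrix_from_arrays(x1, x2, blends[..., 0], blends[..., 1], blends[..., 2], self.spec)
        return X @ self.coeffs

    # ------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "response": self.response,
            "terms": list(self.term_names),
            "coeffs": [float(c) for c in self.coeffs],
            "stderr": [float(s) for s in self.stderr],
            "r2": float(self.r2),
            "f_stat": float(self.f_stat),
            "p_value": float(self.p_value),
            "p_value_pct": float(self.p_value) * 100.0,
            "df_model": int(self.df_model),
            "df_resid": int(self.df_resid),
            "sse": float(self.sse),
            "sst": float(self.sst),
            "residuals": [float(e) for e in self.residuals],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        spec = ModelSpec.from_name(d["model"])
        residuals = np.asarray(d["residuals"], float)
        return cls(
            spec=spec,
            response=d["response"],
            coeffs=np.asarray(d["coeffs"], float),
            stderr=np.asarray(d["stderr"], float),
            residuals=residuals,
            fitted=np.full_like(residuals, np.nan),
            sse=float(d["sse"]),
            sst=float(d["sst"]),
            r2=float(d["r2"]),
            f_stat=float(d["f_stat"]),
            p_value=float(d["p_value"]),
            df_model=int(d["df_model"]),
            df_resid=int(d["df_resid"]),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "FitResult":
        return cls.from_dict(yaml.safe_load(text))


def _collinear_terms(X: np.ndarray, spec: ModelSpec, rank: int) -> list[str]:
    # Pivoted QR: the trailing pivots index the (nearly) dependent columns.
    _, _, piv = qr(X, mode="economic", pivoting=True)
    return [spec.term_names[j] for j in sorted(piv[rank:])]


def fit_response(dataset: StudyDataset, spec: ModelSpec, response: str) -> FitResult:
    """Fit one response column of ``dataset`` by OLS to ``spec``.

    Records with the response missing are dropped.  Raises
    :class:`~mixproc.errors.FittingError` naming the collinear terms on rank
    deficiency, and :class:`~mixproc.errors.ArgumentError` when fewer usable
    records than model terms remain.
    """
    if response not in RESPONSES:
        raise ArgumentError(f"unknown response {response!r}; expected one of {RESPONSES}")
    records = [rec for rec in dataset if rec.response(response) is not None]
    p = len(spec.terms)
    if len(records) < p:
        raise ArgumentError(
            f"{len(records)} records carry {response!r}; at least {p} needed for {spec.name!r}"
        )
    X = model_matrix([rec.condition for rec in records], spec)
    y = np.array([rec.response(response) for rec in records], dtype=float)

    svals = np.linalg.svd(X, compute_uv=False)
    rank = int(np.sum(svals > _RANK_RTOL * svals[0]))
    if rank < p:
        bad = _collinear_terms(X, spec, rank)
        raise FittingError(
            f"model matrix is rank-deficient (rank {rank} < {p}); "
            f"collinear terms: {', '.join(bad)}"
        )

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    n = len(y)
    df_model = p - 1  # mean-corrected convention: mixture terms absorb the intercept
    df_resid = n - p

    sigma2 = sse / df_resid if df_resid > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    stderr = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))

    if sst > 0:
        r2 = 1.0 - sse / sst
        f_stat, p_value = _regression_f(sse, sst, df_model, df_resid)
    else:
        r2 = np.nan
        f_stat = np.nan
        p_value = np.nan

    return FitResult(
        spec=spec,
        response=response,
        coeffs=beta,
        stderr=stderr,
        residuals=resid,
        fitted=fitted,
        sse=sse,
        sst=sst,
        r2=r2,
        f_stat=f_stat,
        p_value=p_value,
        df_model=df_model,
        df_resid=df_resid,
    )


def _regression_f(sse: float, sst: float, df_model: int, df_resid: int):
    ssr = sst - sse
    if df_resid < 1:
        return np.nan, np.nan
    if sse <= 0.0:
        return np.inf, 0.0
    f = (ssr / df_model) / (sse / df_resid)
    return float(f), float(stats.f.sf(f, df_model, df_resid))


def anova_regression(fit: FitResult) -> tuple[float, float, float]:
    """Regression F statistic, upper-tail p, and R² from a fit's sums of squares."""
    if fit.df_resid < 1:
        raise ArgumentError("df_resid must be >= 1 for an ANOVA summary")
    if fit.sst <= 0.0:
        raise DegenerateResponseError(
            f"response {fit.response!r} is constant; R² and F are undefined"
        )
    r2 = 1.0 - fit.sse / fit.sst
    f_stat, p_value = _regression_f(fit.sse, fit.sst, fit.df_model, fit.df_resid)
    return f_stat, p_value, r2


def predict(
    fit: FitResult, condition: RunCondition, *, allow_extrapolation: bool = False
) -> float:
    """Model prediction at a single condition (row dot coefficients)."""
    x = model_matrix([condition], fit.spec)
    del allow_extrapolation  # RunCondition already enforces the domains
    return float(x[0] @ fit.coeffs)


def predict_many(fit: FitResult, conditions: Sequence[RunCondition]) -> np.ndarray:
    X = model_matrix(conditions, fit.spec)
    return X @ fit.coeffs


def replicate_variance(dataset: StudyDataset, response: str) -> tuple[float, int]:
    """Pooled pure-error variance from condition-identical replicate groups.

    Returns ``(s2, df)`` where ``s2 = sum_g sum_i (y_gi - ybar_g)^2 / df`` and
    ``df = sum_g (n_g - 1)``.  For duplicate pairs this reduces to the
    half-squared-difference average, df = number of pairs.
    """
    if response not in RESPONSES:
        raise ArgumentError(f"unknown response {response!r}; expected one of {RESPONSES}")
    ss = 0.0
    df = 0
    for group in dataset.replicate_groups():
        ys = np.array(
            [rec.response(response) for rec in group if rec.response(response) is not None],
            dtype=float,
        )
        if len(ys) < 2:
            continue
        ss += float(np.sum((ys - ys.mean()) ** 2))
        df += len(ys) - 1
    if df == 0:
        raise DataError(f"no condition-identical replicates carry {response!r}")
    return ss / df, df
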