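"""Partial correlation of multivariate components with clinical scores.

For PD subjects, the per-subject mean component scores (CV1, CV2 and
PC1-3) are correlated with UPDRS III, H&Y and LEDD while controlling
for age and sex (encoded 0/1).  The partial Pearson coefficient is the
plain Pearson correlation of the least-squares residuals of both
variables on [1, covariates]; the two-sided p-value comes from
t = r * sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k degrees of freedom.
An equivalent precision-matrix formulation is provided as an
independent computation route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import CohortDataset, ValidationError
from .mva import ComponentModel

CLINICAL_VARIABLES = ("updrs3", "hy", "ledd")
COMPONENT_NAMES = ("CV1", "CV2", "PC1", "PC2", "PC3")


@dataclass
class PartialCorrelationResult:
    component: str
    variable: str
    r: float
    p: float
    n: int
    covariates: tuple[str, ...]

    @property
    def stars(self) -> str:
        for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < cut:
                return mark
        return ""


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def partial_pearson(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariate columns.

    With no covariates this is exactly the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValidationError("x and y must have equal length")
    if covariates is None or (hasattr(covariates, "size")
                              and np.asarray(covariates).size == 0) \
            or (isinstance(covariates, (list, tuple)) and not covariates):
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValidationError("covariates must have n rows")
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValidationError("covariate matrix is rank deficient")
    if n <= k + 2:
        raise ValidationError(f"need n > {k + 2} samples, got {n}")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    tol_x = 1e-8 * max(np.linalg.norm(x - x.mean()), 1e-300)
    tol_y = 1e-8 * max(np.linalg.norm(y - y.mean()), 1e-300)
    if sx <= tol_x or sy <= tol_y:
        raise ValidationError(
            "zero residual variance: a variable is an exact linear "
            "function of the covariates")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r ** 2))
    p = float(2 * scipy.stats.t.sf(abs(t), dof))
    return r, p


def partial_pearson_precision(x, y, covariates=None) -> float:
    """Partial correlation via the inverse correlation (precision)
    matrix: r = -P01 / sqrt(P00 * P11).  Independent route used for
    cross-checking the residualization formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = [x, y]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != x.size:
            C = C.T
        cols.extend(C[:, j] for j in range(C.shape[1]))
    R = np.corrcoef(np.column_stack(cols), rowvar=False)
    P = np.linalg.inv(R)
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


def subject_component_table(model: ComponentModel,
                            dataset: CohortDataset) -> pd.DataFrame:
    """Per-subject mean CV1/CV2/PC1-3 scores from a fitted model.

    The model's scores are per spectrum; a subject's component score is
    the mean over that subject's spectra.
    """
    if model.cv_scores is None:
        raise ValidationError("model has no LDA canonical scores")
    sids = np.array([s.subject_id for s in dataset.spectra])
    rows = []
    for sid in sorted(set(sids.tolist())):
        mask = sids == sid
        cv = model.cv_scores[mask].mean(axis=0)
        pc = model.pc_scores[mask].mean(axis=0)
        rows.append({
            "subject_id": sid,
            "CV1": cv[0],
            "CV2": cv[1] if cv.size > 1 else np.nan,
            "PC1": pc[0], "PC2": pc[1], "PC3": pc[2],
        })
    return pd.DataFrame(rows)


def correlation_panel(scores_table: pd.DataFrame,
                      clinical_table: pd.DataFrame,
                      covariates: tuple[str, ...] = ("age", "sex"),
                      components: tuple[str, ...] = COMPONENT_NAMES,
                      variables: tuple[str, ...] = CLINICAL_VARIABLES
                      ) -> list[PartialCorrelationResult]:
    """Grid of partial correlations (components x clinical variables).

    Tables join on subject_id; only rows with defined clinical scores
    (i.e. PD subjects) enter.  Sex is encoded numerically (M=1, F=0).
    Raises when fewer than 6 subjects remain (insufficient degrees of
    freedom for two covariates).
    """
    merged = scores_table.merge(clinical_table, on="subject_id", how="inner")
    merged = merged.dropna(subset=[v for v in variables])
    if len(merged) < 6:
        raise ValidationError(
            f"only {len(merged)} subjects with clinical scores; need >= 6")
    cov_cols = []
    for cov in covariates:
        col = merged[cov]
        if col.dtype == object:
            col = (col == "M").astype(float)
        cov_cols.append(col.to_numpy(dtype=float))
    Z = np.column_stack(cov_cols) if cov_cols else None
    out = []
    for comp in components:
        for var in variables:
            r, p = partial_pearson(merged[comp].to_numpy(dtype=float),
                                   merged[var].to_numpy(dtype=float), Z)
            out.append(PartialCorrelationResult(
                component=comp, variable=var, r=r, p=p, n=len(merged),
                covariates=tuple(covariates)))
    return out


def panel_to_frame(panel: list[PartialCorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "component": res.component, "variable": res.variable,
        "r": res.r, "p": res.p, "stars": res.stars, "n": res.n,
        "covariates": "+".join(res.covariates),
    } for res in panel])
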