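"""Feature preparation: residualize, normalize, scale.

Each outcome column is regressed on the covariates (age, sex, education,
income, BMI by default) and replaced by its least-squares residual — the
Frisch-Waugh-Lovell route to partialling covariates out. Residuals are
then pushed toward normality with Tukey's Ladder of Powers (grid search
on lambda, maximizing the Shapiro-Wilk W of the transformed column) and
finally min-max scaled to [0, 1]. The transform chain is rank-preserving,
and every column's lineage (lambda, positivity shift, scaling bounds) is
recorded so it can be replayed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .config import COVARIATES

PREPARED_DOMAINS = ("structure.volume", "structure.dti", "metabolism",
                    "connectivity", "cognition", "nutrient")

#: Default Tukey ladder grid.
LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.025), 3)


@dataclass
class ColumnLineage:
    lam: float
    shift: float
    scale_min: float
    scale_max: float
    covariates: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "shift": self.shift,
                "scale_min": self.scale_min, "scale_max": self.scale_max,
                "covariates": list(self.covariates)}


@dataclass
class PreparedMatrix:
    """Participants x features in [0, 1] with per-column lineage."""

    values: pd.DataFrame
    lineage: dict[str, ColumnLineage] = field(default_factory=dict)
    manifest: pd.DataFrame | None = None

    def features(self, *domains: str) -> list[str]:
        if self.manifest is None:
            raise ValueError("no manifest attached")
        mask = self.manifest["domain"].isin(domains)
        return [f for f in self.manifest.loc[mask, "feature"]
                if f in self.values.columns]


def _design(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    """[1, X] with categorical columns expanded to indicators."""
    if isinstance(X, pd.DataFrame):
        X = pd.get_dummies(X, drop_first=True, dtype=float)
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{i}" for i in range(mat.shape[1])]
    design = np.column_stack([np.ones(mat.shape[0]), mat])
    return design, ["intercept"] + names


def fwl_residualize(y, X) -> np.ndarray:
    """Residuals of y on [1, X]: the covariate-orthogonal component of y.

    By the Frisch-Waugh-Lovell theorem these equal the coefficients'-path
    partialled residuals, so a single least-squares fit suffices. A
    rank-deficient design is rejected, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    design, names = _design(X)
    if design.shape[0] != y.shape[0]:
        raise ValueError("y and X row counts differ")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via the pivoted QR diagonal
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def tukey_transform(x: np.ndarray, lam: float) -> np.ndarray:
    """One rung of the ladder, monotone increasing on positive support."""
    if lam > 0:
        return x ** lam
    if lam == 0:
        return np.log(x)
    return -(x ** lam)


def _shifted(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Shift to strictly positive support (residuals are signed)."""
    rng_ = np.ptp(x)
    shift = -x.min() + 1e-6 * (rng_ if rng_ > 0 else 1.0)
    return x + shift, shift


def _scan(xs: np.ndarray, grid) -> tuple[float, float, np.ndarray | None]:
    best_w, best_lam, best_t = -np.inf, None, None
    for lam in grid:
        t = tukey_transform(xs, float(lam))
        if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
            continue
        w = stats.shapiro(t).statistic
        better = w > best_w + 1e-12
        tie = abs(w - best_w) <= 1e-12 and best_lam is not None \
            and abs(lam - 1.0) < abs(best_lam - 1.0)
        if better or tie:
            best_w, best_lam, best_t = w, float(lam), t
    return best_w, best_lam, best_t


def tukey_ladder(x, grid: np.ndarray = LAMBDA_GRID, coarse_step: float = 0.2
                 ) -> tuple[np.ndarray, float, float]:
    """Pick lambda maximizing Shapiro-Wilk W of the transformed column.

    The grid is scanned coarse-to-fine: every ``coarse_step``-th rung
    first, then the full resolution within one coarse step of the best
    rung (W is smooth in lambda, so the refinement recovers the flat-scan
    optimum at a fraction of the cost; pass ``coarse_step=0`` to force a
    flat scan). Returns ``(transformed, lambda, shift)``. Ties resolve to
    the grid value closest to 1 (the identity) for stability.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant column: Tukey ladder undefined")
    xs, shift = _shifted(x)
    grid = np.asarray(grid, dtype=float)
    fine_step = np.min(np.diff(np.unique(grid))) if grid.size > 1 else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if coarse_step and coarse_step > fine_step and grid.size > 20:
            stride = max(int(round(coarse_step / fine_step)), 1)
            _, lam0, _ = _scan(xs, grid[::stride])
            if lam0 is None:
                best_lam, best_t = None, None
            else:
                near = grid[np.abs(grid - lam0) <= coarse_step + 1e-9]
                _, best_lam, best_t = _scan(xs, near)
        else:
            _, best_lam, best_t = _scan(xs, grid)
    if best_lam is None:
        raise ValueError("no ladder rung produced a finite non-constant column")
    return best_t, best_lam, shift


def minmax_scale(x) -> np.ndarray:
    """(x - min) / (max - min); rejects constant columns."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant column: min-max scaling undefined")
    return (x - lo) / (hi - lo)


def prepare(cohort: CohortTable, covariates: tuple[str, ...] = COVARIATES,
            domains: tuple[str, ...] = PREPARED_DOMAINS,
            grid: np.ndarray = LAMBDA_GRID) -> PreparedMatrix:
    """Residualize -> Tukey -> [0,1] scale every outcome column.

    Applied to brain, cognition, and nutrient columns alike; covariates and
    brain age pass through untouched (brain age is reported in years).
    Missing values are rejected.
    """
    cols = cohort.features(*domains)
    X = cohort.data[list(covariates)]
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing covariate values in {bad}")
    out = {}
    lineage: dict[str, ColumnLineage] = {}
    for col in cols:
        y = cohort.data[col].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"column {col!r}: missing values not allowed")
        try:
            resid = fwl_residualize(y, X)
            t, lam, shift = tukey_ladder(resid, grid=grid)
            scaled = minmax_scale(t)
        except ValueError as err:
            raise ValueError(f"column {col!r}: {err}") from err
        out[col] = scaled
        lineage[col] = ColumnLineage(lam=lam, shift=shift,
                                     scale_min=float(t.min()),
                                     scale_max=float(t.max()),
                                     covariates=tuple(covariates))
    values = pd.DataFrame(out, index=cohort.data.index)
    return PreparedMatrix(values=values, lineage=lineage,
                          manifest=cohort.manifest.copy())
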