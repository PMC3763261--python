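"""Least-squares fitting of the multimutation model to cumulative incidence data.

The observations are age-binned cumulative incidence counts per 100,000
population (first-admission style data).  Both the data and the model curve
are converted to dimensionless cumulative fractions before differencing, so
the objective

    chisq = sum_i (x_i - d_i)^2,   x_i = f_s * P_s(t_i)

is independent of the population scale.  The integer mutation count ``m1``
is searched exhaustively; for each candidate the continuous parameters are
optimised in log space from a multistart lattice (the objective has ridges
in (k1, m1), so a single start is unreliable).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import model
from .params import ModelParams

__all__ = ["IncidenceDataset", "FitResult", "chisq", "fit_mmm", "read_incidence_csv"]

DEFAULT_SCALE = 1e5


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclasses.dataclass(frozen=True)
class IncidenceDataset:
    """Age-binned cumulative incidence observations.

    ``cumulative_incidence`` is per ``scale`` population (default 100,000)
    and must be nondecreasing with age.
    """

    ages: np.ndarray
    cumulative_incidence: np.ndarray
    sex_label: str = ""
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        cum = np.asarray(self.cumulative_incidence, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "cumulative_incidence", cum)
        if ages.ndim != 1 or ages.size == 0:
            raise DataError("ages must be a nonempty 1-D array")
        if cum.shape != ages.shape:
            raise DataError("ages and cumulative_incidence must have equal length")
        if np.any(np.diff(ages) <= 0):
            raise DataError("ages must be strictly increasing")
        if np.any(ages < 0):
            raise DataError("ages must be nonnegative")
        if np.any(cum < 0):
            raise DataError("cumulative incidence must be nonnegative")
        if np.any(np.diff(cum) < -1e-9 * max(cum.max(), 1.0)):
            raise DataError("cumulative incidence must be nondecreasing with age")
        if not self.scale > 0:
            raise DataError("scale must be positive")

    @property
    def fractions(self) -> np.ndarray:
        """Observations as dimensionless cumulative fractions d_i."""
        return self.cumulative_incidence / self.scale

    def __len__(self) -> int:
        return self.ages.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"age_years": self.ages, "cum_incidence_per_100k": self.cumulative_incidence}
        )
        if self.sex_label:
            df["sex"] = self.sex_label
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_incidence_csv(path: str | Path, sex: str | None = None) -> IncidenceDataset:
    """Read an incidence CSV (columns ``age_years, cum_incidence_per_100k``).

    An optional ``sex`` column may stratify the table, in which case ``sex``
    selects one stratum.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DataError(f"{path}: not a parsable CSV ({exc})") from exc
    for col in ("age_years", "cum_incidence_per_100k"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column '{col}'")
    label = ""
    if "sex" in df.columns:
        strata = df["sex"].dropna().unique().tolist()
        if sex is not None:
            df = df[df["sex"] == sex]
            if df.empty:
                raise DataError(f"{path}: no rows with sex == {sex!r} (have {strata})")
            label = sex
        elif len(strata) > 1:
            raise DataError(f"{path}: multiple sex strata {strata}; pass sex=...")
        elif strata:
            label = str(strata[0])
    for col in ("age_years", "cum_incidence_per_100k"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise DataError(f"{path}: non-numeric '{col}' at row(s) {bad.index.tolist()}")
    return IncidenceDataset(
        ages=df["age_years"].to_numpy(float),
        cumulative_incidence=df["cum_incidence_per_100k"].to_numpy(float),
        sex_label=label,
    )


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit."""

    params: ModelParams
    chisq: float
    fitted_values: np.ndarray  # model curve at the data ages, on the data's scale
    n_params: int
    converged: bool

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(chisq=self.chisq, n_params=self.n_params, converged=self.converged)
        return d


def chisq(data: IncidenceDataset, params: ModelParams) -> float:
    """Sum of squared residuals on the cumulative-fraction scale."""
    if len(data) == 0:
        raise DataError("empty dataset")
    x = model.population_prevalence(params, data.ages)
    return float(np.sum((x - data.fractions) ** 2))


def _residuals(theta: np.ndarray, m1: int, tied: bool, data: IncidenceDataset):
    theta = np.clip(theta, -30.0, 8.0)  # keep exp() finite on wild LM steps
    if tied:
        lk1, lfs = theta
        lk2 = lk1
    else:
        lk1, lk2, lfs = theta
    p = ModelParams(m1=m1, k1=np.exp(lk1), k2=np.exp(lk2), f_s=min(np.exp(lfs), 1.0))
    return model.population_prevalence(p, data.ages) - data.fractions


def _starts(data: IncidenceDataset, tied: bool, rng: np.random.Generator):
    """Multistart lattice in log space, seeded from the data's plateau."""
    d_max = max(data.fractions.max(), 1e-6)
    k_grid = np.log(np.array([0.01, 0.03, 0.1, 0.3, 1.0]))
    fs_grid = np.log(np.array([d_max, min(2.5 * d_max, 1.0), 1e-3]))
    starts = []
    if tied:
        for lk in k_grid:
            for lf in fs_grid:
                starts.append(np.array([lk, lf]))
    else:
        for lk1 in k_grid:
            for lk2 in k_grid[::2]:
                for lf in fs_grid[:2]:
                    starts.append(np.array([lk1, lk2, lf]))
    jitter = rng.normal(scale=0.05, size=(len(starts), starts[0].size))
    return [s + j for s, j in zip(starts, jitter)]


def _fit_one_m1(
    data: IncidenceDataset,
    m1: int,
    tied: bool,
    rng: np.random.Generator,
    extra_starts: list[np.ndarray] | None = None,
):
    best = None
    starts = _starts(data, tied, rng)
    if extra_starts:
        starts = list(extra_starts) + starts
    for x0 in starts:
        try:
            res = least_squares(
                _residuals,
                x0,
                args=(m1, tied, data),
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:
            continue
        c = float(np.sum(res.fun**2))
        if best is None or c < best[0]:
            best = (c, res.x, bool(res.success))
    return best


def fit_mmm(
    data: IncidenceDataset,
    n_params: int = 4,
    m1_range: range | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the 3- or 4-parameter model, searching the integer ``m1``.

    For each candidate ``m1`` the continuous parameters — (k1, f_s) with
    ``k2`` tied to ``k1`` for the 3-parameter model, (k1, k2, f_s) for the
    4-parameter model — are optimised from a multistart log-space lattice,
    and the global best over ``m1`` is returned.  For the 4-parameter model
    the tied optimum is included among the starts, so the 4-parameter fit
    never ends worse than the 3-parameter fit on the same data.

    Raises ``DataError`` if the dataset is too small; a fit in which no
    start converged is returned with ``converged=False``, never silently.
    """
    if n_params not in (3, 4):
        raise ValueError("n_params must be 3 or 4")
    if m1_range is None:
        m1_range = range(1, 41)
    if len(data) < n_params + 1:
        raise DataError(f"need at least {n_params + 1} data points, got {len(data)}")
    rng = np.random.default_rng(seed)
    tied = n_params == 3
    best = None  # (chisq, m1, theta, success)
    for m1 in m1_range:
        tied_fit = _fit_one_m1(data, m1, True, rng)
        if tied:
            fit = tied_fit
        else:
            extra = []
            if tied_fit is not None:
                lk, lf = tied_fit[1]
                extra.append(np.array([lk, lk, lf]))
            fit = _fit_one_m1(data, m1, False, rng, extra_starts=extra)
        if fit is None:
            continue
        c, theta, ok = fit
        if best is None or c < best[0]:
            best = (c, m1, theta, ok)
    if best is None:
        raise model.SolverError("no start converged for any m1 candidate")
    c, m1, theta, ok = best
    if tied:
        k1 = k2 = float(np.exp(theta[0]))
        fs = float(min(np.exp(theta[1]), 1.0))
    else:
        k1, k2 = float(np.exp(theta[0])), float(np.exp(theta[1]))
        fs = float(min(np.exp(theta[2]), 1.0))
    params = ModelParams(m1=m1, k1=k1, k2=k2, f_s=fs)
    fitted = model.population_prevalence(params, data.ages) * data.scale
    return FitResult(
        params=params, chisq=c, fitted_values=fitted, n_params=n_params, converged=ok
    )
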