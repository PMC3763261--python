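"""Twin-cohort concordance algebra of the multimutation model.

A twin study's pairs are split at random into two subcohorts.  With
``p_s = P_s(t)`` the susceptible prevalence at census age ``t``, the joint
pair states are p_ss = p1*p2, p_sx = p1(1-p2) + p2(1-p1), p_xx =
(1-p1)(1-p2).  *Subcohort concordance* — the quantity this model predicts —
is the fraction of pairs with at least one affected member in which both are
affected,

    C = p_ss / (p_ss + p_sx).

For monozygotic (MZ) pairs both members are susceptible and share the same
prevalence curve, so C_M = p_s / (2 - p_s).  For dizygotic (DZ) pairs the
cotwin of an affected index twin inherits susceptibility with probability
``S_inher``, giving C_D = S p_s / (1 + S - S p_s), which plateaus at
``S_inher`` as p_s -> 1.

Note this is deliberately *not* the pairwise or probandwise concordance of
the broader twin literature: it conditions on at least one affected member
of a randomly matched subcohort pair, not on ascertained probands.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from . import model
from .model import SolverError
from .params import ModelParams

__all__ = [
    "TwinStudyRecord",
    "TwinStateProbabilities",
    "TwinDerived",
    "subcohort_concordance",
    "mz_state_probabilities",
    "dz_state_probabilities",
    "mz_concordance",
    "invert_mz_concordance",
    "dz_concordance",
    "s_inher_from_prevalence",
    "s_inher_from_concordances",
    "average_mz_concordance",
    "equivalent_age",
    "clock_rate_from_concordance",
    "clock_rate_from_mean_age",
    "fraction_unable",
    "analyze_study",
    "analyze_table",
    "load_twin_studies",
]

_CLOCK_BRACKET = (1e-3, 1e2)
_AGE_BRACKET = (0.0, 200.0)


def _check_prob(x: float, name: str) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return x


@dataclasses.dataclass(frozen=True)
class TwinStudyRecord:
    """One twin study's MZ/DZ concordant-pair counts and cohort age data."""

    investigator: str
    year: int
    country: str
    mz_concordant: int
    mz_total: int
    dz_concordant: int | None = None
    dz_total: int | None = None
    age_low: float | None = None
    age_high: float | None = None
    mean_onset_age: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mz_concordant <= self.mz_total:
            raise ValueError(f"{self.investigator}: MZ counts out of range")
        if (self.dz_concordant is None) != (self.dz_total is None):
            raise ValueError(f"{self.investigator}: DZ counts must come as a pair")
        if self.dz_total is not None and not 0 <= self.dz_concordant <= self.dz_total:
            raise ValueError(f"{self.investigator}: DZ counts out of range")
        if (
            self.age_low is not None
            and self.age_high is not None
            and not self.age_low < self.age_high
        ):
            raise ValueError(f"{self.investigator}: need age_low < age_high")

    @property
    def mz_fraction(self) -> float:
        return self.mz_concordant / self.mz_total

    @property
    def dz_fraction(self) -> float | None:
        if self.dz_total is None:
            return None
        return self.dz_concordant / self.dz_total


@dataclasses.dataclass(frozen=True)
class TwinStateProbabilities:
    """Joint pair-state probabilities at one census age."""

    p_ss: float
    p_sx: float
    p_xx: float
    p_first_onset: float  # P(at least one member affected) = 1 - p_xx

    def __post_init__(self) -> None:
        total = self.p_ss + self.p_sx + self.p_xx
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pair-state probabilities sum to {total}, not 1")


@dataclasses.dataclass(frozen=True)
class TwinDerived:
    """Model-derived quantities for one twin study."""

    prevalence_at_match: float
    s_inher: float | None
    frac_unable: float | None
    clock_rate: float | None = None
    equivalent_age: float | None = None
    mean_onset_age: float | None = None
    note: str = ""


def subcohort_concordance(p_s_1: float, p_s_2: float) -> float:
    """C = p_ss / (p_ss + p_sx) for subcohort prevalences ``p_s_1, p_s_2``."""
    p1 = _check_prob(p_s_1, "p_s_1")
    p2 = _check_prob(p_s_2, "p_s_2")
    denom = p1 + p2 - p1 * p2
    if denom == 0.0:
        return 0.0
    return p1 * p2 / denom


def mz_state_probabilities(p_s: float) -> TwinStateProbabilities:
    """MZ pair-state probabilities: (p_s^2, 2 p_s (1-p_s), (1-p_s)^2)."""
    p = _check_prob(p_s, "p_s")
    q = 1.0 - p
    return TwinStateProbabilities(
        p_ss=p * p, p_sx=2 * p * q, p_xx=q * q, p_first_onset=p * (2.0 - p)
    )


def dz_state_probabilities(p_s: float, s_inher: float) -> TwinStateProbabilities:
    """DZ pair-state probabilities with cotwin susceptibility ``s_inher``."""
    p = _check_prob(p_s, "p_s")
    s = _check_prob(s_inher, "s_inher")
    p2 = s * p
    return TwinStateProbabilities(
        p_ss=p * p2,
        p_sx=p * (1 - p2) + p2 * (1 - p),
        p_xx=(1 - p) * (1 - p2),
        p_first_onset=1.0 - (1 - p) * (1 - p2),
    )


def mz_concordance(p_s: float) -> float:
    """MZ subcohort concordance C_M = p_s / (2 - p_s)."""
    p = _check_prob(p_s, "p_s")
    return p / (2.0 - p)


def invert_mz_concordance(c_m: float) -> float:
    """Susceptible prevalence from an observed MZ concordance: 2 C / (1 + C)."""
    c = _check_prob(c_m, "c_m")
    return 2.0 * c / (1.0 + c)


def dz_concordance(p_s: float, s_inher: float) -> float:
    """DZ subcohort concordance C_D = S p_s / (1 + S - S p_s).

    Monotone increasing in ``p_s``; plateaus at ``s_inher`` as p_s -> 1.
    """
    p = _check_prob(p_s, "p_s")
    s = _check_prob(s_inher, "s_inher")
    return s * p / (1.0 + s - s * p)


def s_inher_from_prevalence(c_d: float, p_s: float) -> float:
    """Invert C_D for S_inher given the prevalence: C_D / [p_s + (p_s - 1) C_D]."""
    c = _check_prob(c_d, "c_d")
    p = _check_prob(p_s, "p_s")
    denom = p + (p - 1.0) * c
    if denom <= 0:
        raise ValueError(
            f"cohort too young for observed DZ concordance (denominator {denom:g})"
        )
    return c / denom


def s_inher_from_concordances(c_m: float, c_d: float) -> float:
    """S_inher from the two observed concordances: (1+C_M)/(2C_M/C_D - 1 + C_M)."""
    c_m = _check_prob(c_m, "c_m")
    c_d = _check_prob(c_d, "c_d")
    if c_d == 0.0:
        return 0.0
    if c_m == 0.0:
        raise ValueError("S_inher undefined for c_m = 0 with c_d > 0")
    return (1.0 + c_m) / (2.0 * c_m / c_d - 1.0 + c_m)


def average_mz_concordance(
    params: ModelParams,
    t_L: float,
    t_H: float,
    weights: pd.DataFrame | np.ndarray | None = None,
) -> float:
    """Cohort-average MZ concordance over the age window ``[t_L, t_H]``.

    With no ``weights`` the cohort age distribution is uniform and the
    average is ``(1/(t_H - t_L)) * int C_M(P_s(t, r)) dt``.  ``weights`` may
    be a two-column (age, count) array or DataFrame, in which case the
    weighted sum ``sum C_M(t_a) n_a / N_T`` is returned.
    """
    if not t_L < t_H:
        raise ValueError(f"need t_L < t_H, got [{t_L}, {t_H}]")
    if weights is None:
        val, _ = quad(
            lambda t: mz_concordance(model.susceptible_prevalence(params, t)),
            t_L,
            t_H,
            epsabs=model.QUAD_ABS_TOL,
            epsrel=1e-10,
            limit=200,
        )
        return val / (t_H - t_L)
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight table")
    ages, counts = w[:, 0], w[:, 1]
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    c = np.array([mz_concordance(model.susceptible_prevalence(params, a)) for a in ages])
    return float(np.sum(c * counts) / counts.sum())


def equivalent_age(params: ModelParams, c_m_target: float) -> float:
    """Age at which the model's MZ concordance curve reaches ``c_m_target``.

    Solves ``C_M(P_s(t, r)) = c_m_target`` by bracketed root-finding on
    [0, 200] years; C_M is strictly increasing in t so the root is unique.
    """
    if not 0.0 < c_m_target < 1.0:
        raise ValueError(f"c_m_target must lie in (0, 1), got {c_m_target}")
    lo, hi = _AGE_BRACKET
    f = lambda t: mz_concordance(model.susceptible_prevalence(params, t)) - c_m_target
    if f(hi) < 0:
        raise SolverError(
            f"concordance {c_m_target} not reached by age {hi} (max {f(hi) + c_m_target:.4f})"
        )
    return float(brentq(f, lo, hi, xtol=model.AGE_TOL))


def clock_rate_from_concordance(
    params: ModelParams, age: float, c_m_observed: float
) -> float:
    """Clock rate r such that ``P_s(age, r)`` matches an observed concordance.

    The target prevalence is the inversion ``2 C / (1 + C)``; r is found by
    bracketed root-finding on [1e-3, 1e2] (P_s is strictly increasing in r).
    """
    if age <= 0:
        raise ValueError("age must be positive")
    if not 0.0 < c_m_observed < 1.0:
        raise ValueError("c_m_observed must lie in (0, 1)")
    target = invert_mz_concordance(c_m_observed)
    base = params.with_clock_rate(1.0)
    f = lambda r: model.susceptible_prevalence(base.with_clock_rate(r), age) - target
    lo, hi = _CLOCK_BRACKET
    if f(lo) > 0 or f(hi) < 0:
        raise SolverError(f"clock rate not bracketed on [{lo}, {hi}] for age {age}")
    return float(brentq(f, lo, hi, xtol=1e-9, rtol=8.9e-16))


def clock_rate_from_mean_age(
    params: ModelParams, t_L: float, t_H: float, t_bar_target: float
) -> float:
    """Clock rate r whose mean onset age over ``[t_L, t_H]`` equals the target.

    The windowed mean onset age is strictly decreasing in r (a faster clock
    pushes onsets toward the window's lower edge), so bracketed
    root-finding on [1e-3, 1e2] applies.
    """
    if not t_L < t_bar_target < t_H:
        raise ValueError(
            f"target mean {t_bar_target} must lie inside the window [{t_L}, {t_H}]"
        )
    base = params.with_clock_rate(1.0)
    # As r -> 0 the windowed density tends to the t^(m-1) limit and the mean
    # approaches its supremum from below; P_s can underflow there, so treat a
    # degenerate window as "mean at its slow-clock limit" when scanning.
    slow_limit = (
        params.m / (params.m + 1) * (t_H ** (params.m + 1) - t_L ** (params.m + 1))
        / (t_H**params.m - t_L**params.m)
    )

    def f(r: float) -> float:
        scaled = base.with_clock_rate(r)
        try:
            return model.mean_onset_age(scaled, t_L, t_H) - t_bar_target
        except model.DegenerateCohortError:
            # Fast clock: all onsets precede t_L, conditional mean -> t_L.
            if model.susceptible_prevalence(scaled, t_L) > 0.5:
                return t_L - t_bar_target
            return slow_limit - t_bar_target

    lo, hi = _CLOCK_BRACKET
    if f(hi) > 0 or f(lo) < 0:
        raise SolverError(f"target mean onset age {t_bar_target} not attainable")
    # f is strictly decreasing in r; locate a finite sign-change pair first.
    grid = np.geomspace(lo, hi, 61)
    vals = np.array([f(r) for r in grid])
    idx = np.nonzero((vals[:-1] >= 0) & (vals[1:] < 0))[0]
    if idx.size == 0:
        raise SolverError(f"target mean onset age {t_bar_target} not bracketed")
    a, b = grid[idx[0]], grid[idx[0] + 1]
    return float(brentq(f, a, b, xtol=1e-9, rtol=8.9e-16))


def fraction_unable(s_inher: float) -> float:
    """1 - S_inher: DZ cotwins incapable of ever developing the disease."""
    return 1.0 - _check_prob(s_inher, "s_inher")


def analyze_study(record: TwinStudyRecord, params: ModelParams) -> TwinDerived:
    """Derive (P_s, S_inher, r, equivalent age, mean onset age) for one study.

    The prevalence at concordance-match is the inversion of the observed MZ
    fraction; S_inher comes from the two concordances when DZ counts exist.
    Age calibration depends on what the study reports:

    * a cohort mean onset age -> r solves the mean-onset-age condition and
      the equivalent age solves ``P_s(t, r) = P_s`` on the rescaled curve;
    * an age range whose unscaled equivalent age falls outside it -> the
      range midpoint is taken as the representative census age and r solves
      ``P_s(age, r) = P_s`` (the curve must run on a different clock);
    * an age range containing the unscaled equivalent age -> r = 1.
    """
    c_m = record.mz_fraction
    p_s = invert_mz_concordance(c_m)
    c_d = record.dz_fraction
    s = s_inher_from_concordances(c_m, c_d) if c_d is not None else None
    unable = fraction_unable(s) if s is not None else None

    r = equiv = mean_age = None
    note = ""
    has_window = record.age_low is not None and record.age_high is not None
    base = params.with_clock_rate(1.0)
    if record.mean_onset_age is not None and has_window:
        r = clock_rate_from_mean_age(
            base, record.age_low, record.age_high, record.mean_onset_age
        )
        scaled = base.with_clock_rate(r)
        equiv = equivalent_age(scaled, c_m)
        mean_age = model.mean_onset_age(scaled, record.age_low, record.age_high)
        note = "clock rate from cohort mean onset age"
    elif has_window:
        t_unscaled = equivalent_age(base, c_m)
        if record.age_low <= t_unscaled <= record.age_high:
            r = 1.0
            equiv = t_unscaled
            mean_age = model.mean_onset_age(base, record.age_low, record.age_high)
            note = "unscaled curve consistent with cohort age range"
        else:
            mid = 0.5 * (record.age_low + record.age_high)
            r = clock_rate_from_concordance(base, mid, c_m)
            equiv = mid
            mean_age = model.mean_onset_age(
                base.with_clock_rate(r), record.age_low, record.age_high
            )
            note = "clock rate from concordance at the age-range midpoint"
    return TwinDerived(
        prevalence_at_match=p_s,
        s_inher=s,
        frac_unable=unable,
        clock_rate=r,
        equivalent_age=equiv,
        mean_onset_age=mean_age,
        note=note,
    )


def analyze_table(
    records: list[TwinStudyRecord], params: ModelParams
) -> tuple[pd.DataFrame, float]:
    """Run :func:`analyze_study` over a study table.

    Returns a tidy DataFrame (one row per study) and the pooled minimum
    ``frac_unable`` across studies — the headline lower bound on the
    fraction of DZ cotwins unable to develop the disease.  Per-study solver
    failures are recorded in the ``error`` column without aborting the batch.
    """
    rows = []
    for rec in records:
        row = {
            "investigator": rec.investigator,
            "year": rec.year,
            "country": rec.country,
            "mz_concordance": rec.mz_fraction,
            "dz_concordance": rec.dz_fraction,
        }
        try:
            d = analyze_study(rec, params)
            row.update(
                prevalence_at_match=d.prevalence_at_match,
                s_inher=d.s_inher,
                frac_unable=d.frac_unable,
                clock_rate=d.clock_rate,
                equivalent_age=d.equivalent_age,
                mean_onset_age=d.mean_onset_age,
                note=d.note,
                error="",
            )
        except (ValueError, SolverError) as exc:  # keep the batch going
            row.update(error=str(exc))
        rows.append(row)
    df = pd.DataFrame(rows)
    unable = df["frac_unable"].dropna() if "frac_unable" in df else pd.Series(dtype=float)
    pooled_min = float(unable.min()) if len(unable) else float("nan")
    return df, pooled_min


_FIXTURE = "twin_studies_pre1970.csv"


def load_twin_studies(path: str | Path | None = None) -> list[TwinStudyRecord]:
    """Load a twin-study CSV; with no path, the packaged pre-1970 table.

    Required columns: investigator, year, country, mz_concordant, mz_total,
    dz_concordant, dz_total; optional: age_low, age_high, mean_onset_age
    (blank allowed).
    """
    if path is None:
        src = resources.files("multimutation.data").joinpath(_FIXTURE)
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = ["investigator", "year", "country", "mz_concordant", "mz_total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"twin-study table missing columns: {missing}")

    def _opt(row, col, cast=float):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    records = []
    for _, row in df.iterrows():
        records.append(
            TwinStudyRecord(
                investigator=str(row["investigator"]),
                year=int(row["year"]),
                country=str(row["country"]),
                mz_concordant=int(row["mz_concordant"]),
                mz_total=int(row["mz_total"]),
                dz_concordant=_opt(row, "dz_concordant", int),
                dz_total=_opt(row, "dz_total", int),
                age_low=_opt(row, "age_low"),
                age_high=_opt(row, "age_high"),
                mean_onset_age=_opt(row, "mean_onset_age"),
            )
        )
    return records
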