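"""Synthetic cohorts and incidence tables with the model's exact structure.

Onset ages are sampled mechanistically: a susceptible individual's onset is
the time of the *last* required mutation, i.e. the maximum of ``m1``
Exp(r k1) waiting times and one Exp(r k2) waiting time.  The maximum of
independent exponentials has CDF equal to the product of their CDFs, so this
is an exact sampler for the model's onset distribution P_s(t, r) — no
numerical CDF inversion involved.

Incidence tables emulate the structure of first-admission registries:
age-binned cumulative counts per 100,000, monotone in age, optionally
sex-stratified.  Noise is multiplicative Gaussian (admission counts scale
with cohort size) followed by isotonic clipping via a running maximum, which
preserves the cumulative invariant.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import model, twins
from .fitting import IncidenceDataset
from .params import ModelParams

__all__ = [
    "SimulatedCohort",
    "simulate_onset_age",
    "simulate_incidence_dataset",
    "simulate_twin_cohort",
]

#: Default age grid for simulated incidence tables: 25 bins spanning the
#: 10-70 y range covered by first-admission registries.
DEFAULT_AGES = np.linspace(10.0, 70.0, 25)


def simulate_onset_age(params: ModelParams, rng: np.random.Generator, size=None):
    """Draw onset age(s) for susceptible individuals (max-of-exponentials)."""
    n = 1 if size is None else int(size)
    scale1 = 1.0 / (params.r * params.k1)
    scale2 = 1.0 / (params.r * params.k2)
    last = rng.exponential(scale2, size=n)
    if params.m1 > 0:
        draws = rng.exponential(scale1, size=(n, params.m1))
        last = np.maximum(draws.max(axis=1), last)
    return float(last[0]) if size is None else last


def simulate_incidence_dataset(
    params: ModelParams,
    ages: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sex_label: str = "synthetic",
) -> IncidenceDataset:
    """Cumulative incidence per 100,000 from the model curve plus noise.

    ``noise_sd`` is the standard deviation of the multiplicative Gaussian
    factor (0 gives the exact curve).  The noisy curve is clipped to be
    nondecreasing.  Identical seeds give identical datasets.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    ages = DEFAULT_AGES if ages is None else np.asarray(ages, dtype=float)
    curve = 1e5 * np.asarray(model.population_prevalence(params, ages))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        curve = curve * (1.0 + rng.normal(scale=noise_sd, size=curve.shape))
        curve = np.maximum.accumulate(np.maximum(curve, 0.0))
    return IncidenceDataset(ages=ages, cumulative_incidence=curve, sex_label=sex_label)


@dataclasses.dataclass(frozen=True)
class SimulatedCohort:
    """A simulated twin birth cohort observed cross-sectionally.

    Onset ages are pre-drawn for susceptible members (NaN for members
    incapable of developing the disease); a census at age ``t`` treats
    onsets beyond ``t`` as not-yet-ill.  ``subcohort_of_twin1`` records the
    random coin-flip assignment of each pair's first member to subcohort 1
    or 2.
    """

    zygosity: str
    n_pairs: int
    susceptible_twin1: np.ndarray
    susceptible_twin2: np.ndarray
    onset_age_twin1: np.ndarray
    onset_age_twin2: np.ndarray
    subcohort_of_twin1: np.ndarray
    seed: int

    def affected_by(self, census_age: float) -> tuple[np.ndarray, np.ndarray]:
        a1 = self.susceptible_twin1 & (self.onset_age_twin1 <= census_age)
        a2 = self.susceptible_twin2 & (self.onset_age_twin2 <= census_age)
        return a1, a2

    def state_counts(self, census_age: float) -> tuple[int, int, int]:
        """(both affected, exactly one, neither) at the census age."""
        a1, a2 = self.affected_by(census_age)
        both = int(np.sum(a1 & a2))
        one = int(np.sum(a1 ^ a2))
        neither = self.n_pairs - both - one
        return both, one, neither

    def concordance(self, census_age: float) -> float:
        """Empirical subcohort concordance: both / (both + exactly one)."""
        both, one, _ = self.state_counts(census_age)
        if both + one == 0:
            return float("nan")
        return both / (both + one)

    def discordance(self, census_age: float) -> float:
        both, one, _ = self.state_counts(census_age)
        if both + one == 0:
            return float("nan")
        return one / (both + one)

    def first_onset_fraction(self, census_age: float) -> float:
        """Fraction of pairs with at least one onset by the census age."""
        both, one, _ = self.state_counts(census_age)
        return (both + one) / self.n_pairs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "zygosity": self.zygosity,
                "pair": np.arange(self.n_pairs),
                "susceptible_twin1": self.susceptible_twin1,
                "susceptible_twin2": self.susceptible_twin2,
                "onset_age_twin1": self.onset_age_twin1,
                "onset_age_twin2": self.onset_age_twin2,
                "subcohort_of_twin1": self.subcohort_of_twin1,
            }
        )


def simulate_twin_cohort(
    params: ModelParams,
    n_pairs: int,
    zygosity: str = "MZ",
    s_inher: float = 1.0,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a twin birth cohort under the model's independence assumption.

    MZ: both members susceptible, onset ages independent draws from the
    onset distribution (independence given susceptibility is the model's
    core assumption).  DZ: twin 1 susceptible; twin 2 susceptible with
    probability ``s_inher``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    zygosity = zygosity.upper()
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    twins._check_prob(s_inher, "s_inher")
    rng = np.random.default_rng(seed)
    sus1 = np.ones(n_pairs, dtype=bool)
    if zygosity == "MZ":
        sus2 = np.ones(n_pairs, dtype=bool)
    else:
        sus2 = rng.random(n_pairs) < s_inher
    onset1 = simulate_onset_age(params, rng, size=n_pairs)
    onset2 = np.full(n_pairs, np.nan)
    n2 = int(sus2.sum())
    if n2:
        onset2[sus2] = simulate_onset_age(params, rng, size=n2)
    assign = rng.integers(1, 3, size=n_pairs)
    return SimulatedCohort(
        zygosity=zygosity,
        n_pairs=n_pairs,
        susceptible_twin1=sus1,
        susceptible_twin2=sus2,
        onset_age_twin1=onset1,
        onset_age_twin2=onset2,
        subcohort_of_twin1=assign,
        seed=seed,
    )
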