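"""Model parameters for the independent multimutation age-of-onset model.

The model assumes disease onset occurs when the last of ``m`` independent,
exponentially timed internal changes ("mutations", in the generic sense of
internally driven biological changes) has taken place.  The fitted family
uses exactly two distinct rates: ``m1 = m - 1`` changes share rate ``k1``
(per year) and the single remaining change occurs at rate ``k2``.  A
dimensionless clock factor ``r`` rescales both rates, speeding up (``r > 1``)
or slowing down (``r < 1``) the whole onset timeline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

__all__ = [
    "ModelParams",
    "USA_MALE",
    "USA_FEMALE",
    "USA_MALE_FEMALE",
    "USA_MALE_3PARAM",
    "load_params",
    "dump_params",
]


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Parameter vector of the two-rate multimutation model.

    Parameters
    ----------
    m1 : int
        Number of mutations occurring at rate ``k1`` (``m1 >= 0``); the
        total mutation count is ``m = m1 + 1``.
    k1, k2 : float
        Mutation rates, per year, strictly positive.  The degenerate
        3-parameter (single-rate) model is represented as ``k2 == k1``.
    f_s : float
        Lifetime susceptible fraction of the birth cohort, in ``[0, 1]``.
    r : float
        Dimensionless biological clock rate, ``> 0``; ``r = 1`` leaves the
        fitted timeline unchanged.
    """

    m1: int
    k1: float
    k2: float
    f_s: float = 1.0
    r: float = 1.0

    def __post_init__(self) -> None:
        if int(self.m1) != self.m1 or self.m1 < 0:
            raise ValueError(f"m1 must be a nonnegative integer, got {self.m1!r}")
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError(f"rates must be strictly positive, got k1={self.k1}, k2={self.k2}")
        if not 0.0 <= self.f_s <= 1.0:
            raise ValueError(f"f_s must lie in [0, 1], got {self.f_s}")
        if not self.r > 0:
            raise ValueError(f"clock rate r must be positive, got {self.r}")

    @property
    def m(self) -> int:
        """Total mutation count, ``m1 + 1``."""
        return self.m1 + 1

    def with_clock_rate(self, r: float) -> "ModelParams":
        """Return a copy with the clock rate replaced by ``r``."""
        return dataclasses.replace(self, r=r)

    def with_f_s(self, f_s: float) -> "ModelParams":
        return dataclasses.replace(self, f_s=f_s)

    def to_dict(self) -> dict:
        """Flat key-value form (keys ``m, m1, k1, k2, f_s, r``; rates per year)."""
        return {
            "m": self.m,
            "m1": self.m1,
            "k1": float(self.k1),
            "k2": float(self.k2),
            "f_s": float(self.f_s),
            "r": float(self.r),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        m1 = d.get("m1")
        if m1 is None:
            if "m" not in d:
                raise ValueError("parameter mapping needs 'm1' or 'm'")
            m1 = int(d["m"]) - 1
        if "m" in d and int(d["m"]) != int(m1) + 1:
            raise ValueError(f"inconsistent mutation counts: m={d['m']} but m1={m1}")
        return cls(
            m1=int(m1),
            k1=float(d["k1"]),
            k2=float(d.get("k2", d["k1"])),
            f_s=float(d.get("f_s", 1.0)),
            r=float(d.get("r", 1.0)),
        )


def load_params(path: str | Path) -> ModelParams:
    """Read a ModelParams from a flat YAML (or JSON — valid YAML) file."""
    with open(path, "r", encoding="utf-8") as fh:
        return ModelParams.from_dict(yaml.safe_load(fh))


def dump_params(params: ModelParams, path: str | Path) -> None:
    """Write a ModelParams to YAML (``.json`` extension writes JSON)."""
    p = Path(path)
    with open(p, "w", encoding="utf-8") as fh:
        if p.suffix == ".json":
            json.dump(params.to_dict(), fh, indent=2)
            fh.write("\n")
        else:
            yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


# Published least-squares fits to the USA first-hospital-admission cumulative
# incidence data (4-parameter model unless noted).  f_s here is the lifetime
# risk of *hospital admission*; population lifetime risk is ~0.01.
USA_MALE = ModelParams(m1=15, k1=0.11653, k2=0.028465, f_s=0.0015737)
USA_FEMALE = ModelParams(m1=15, k1=0.09859, k2=0.035728, f_s=0.0016428)
USA_MALE_FEMALE = ModelParams(m1=15, k1=0.10757, k2=0.029959, f_s=0.0016363)
# 3-parameter (single-rate) fit to the male data: m = 10 equal-rate steps.
USA_MALE_3PARAM = ModelParams(m1=9, k1=0.08172, k2=0.08172, f_s=0.00137)
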