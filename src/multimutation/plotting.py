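"""Quick qualitative plots of the model's curves (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from . import model, twins
from .params import ModelParams

__all__ = ["plot_prevalence", "plot_incidence", "plot_twin_curves"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_prevalence(params: ModelParams, t_max: float = 80.0, ax=None, **kw):
    """Susceptible prevalence P_s(t, r) versus age."""
    ax = _axes(ax)
    t = np.linspace(0, t_max, 400)
    ax.plot(t, model.susceptible_prevalence(params, t), **kw)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("susceptible prevalence $P_s(t, r)$")
    return ax

def plot_incidence(params: ModelParams, t_max: float = 80.0, ax=None, **kw):
    """Susceptible incidence rate IR_s(t) versus age."""
    ax = _axes(ax)
    t = np.linspace(0, t_max, 400)
    ax.plot(t, model.susceptible_incidence_rate(params, t), **kw)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("susceptible incidence rate (per year)")
    return ax

def plot_twin_curves(params: ModelParams, s_inher: float, t_max: float = 80.0, ax=None):
    """Prevalence, MZ concordance, and DZ concordance curves together."""
    ax = _axes(ax)
    t = np.linspace(0, t_max, 400)
    p = np.asarray(model.susceptible_prevalence(params, t))
    ax.plot(t, p, label="$P_s(t)$")
    ax.plot(t, p / (2 - p), label="$C_M(t)$")
    ax.plot(t, [twins.dz_concordance(pi, s_inher) for pi in p], label="$C_D(t)$")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("probability")
    ax.legend()
    return ax
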