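"""Simple line plots of the fitted schedules and projections.

Only the basic diagnostic views are offered: l_x/m_x/l_x*m_x, k_x/q_x with
the cumulative net predation, and the projected N(t)/P(t) (optionally on a
log10 axis, the conventional display for exponential growth).
"""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_survival_fecundity(results, ax=None):
    """l_x, m_x and the net maternity l_x*m_x against age."""
    ax = _get_ax(ax)
    ages = results.table.ages
    ax.plot(ages, results.table.l_x, label="$l_x$")
    ax2 = ax.twinx()
    ax2.plot(ages, results.table.m_x, color="C1", label="$m_x$")
    ax2.plot(ages, results.lxmx, color="C2", label="$l_x m_x$")
    ax.set_xlabel("age (d)")
    ax.set_ylabel("survival $l_x$")
    ax2.set_ylabel("eggs / day")
    handles, labels = ax.get_legend_handles_labels()
    h2, l2 = ax2.get_legend_handles_labels()
    ax.legend(handles + h2, labels + l2, loc="upper right")
    return ax


def plot_predation(results, ax=None):
    """k_x, q_x and the cumulative net predation rate against age."""
    ax = _get_ax(ax)
    k_x, q_x = results.table.k_x, results.table.q_x
    ages = np.arange(len(k_x))
    ax.plot(ages, k_x, label="$k_x$")
    ax.plot(ages, q_x, label="$q_x$")
    ax2 = ax.twinx()
    ax2.plot(ages, np.cumsum(q_x), color="C3", label="cumulative")
    ax.set_xlabel("age (d)")
    ax.set_ylabel("prey / day")
    ax2.set_ylabel("cumulative prey")
    ax.legend(loc="upper left")
    return ax


def plot_projection(result, ax=None, log10: bool = True):
    """Projected N(t) and P(t), with percentile bands when available."""
    ax = _get_ax(ax)
    t = np.arange(result.horizon + 1)

    def tf(v):
        return np.log10(np.maximum(v, 1e-12)) if log10 else v

    ax.plot(t, tf(result.N_t), label="N(t)")
    ax.plot(t, tf(result.P_t), label="P(t)")
    if result.lower is not None and result.upper is not None:
        ax.fill_between(t, tf(result.lower.N_t), tf(result.upper.N_t), alpha=0.2)
        ax.fill_between(t, tf(result.lower.P_t), tf(result.upper.P_t), alpha=0.2)
    ax.set_xlabel("day")
    ax.set_ylabel("log10 count" if log10 else "count")
    ax.legend()
    return ax
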