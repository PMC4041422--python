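"""Plotting helpers (matplotlib, Agg-safe): traces with fits, k_obs lines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .models import single_exponential  # noqa: E402

__all__ = ["plot_trace_with_fit", "plot_kobs_vs_concentration"]


def plot_trace_with_fit(trace, fit, path) -> Path:
    """Trace points, the fitted relaxation, and the residuals below."""
    fig, (ax, axr) = plt.subplots(2, 1, sharex=True, figsize=(6, 5),
                                  height_ratios=[3, 1])
    ax.plot(trace.times, trace.signal, ".", ms=2, alpha=0.5, label="data")
    if fit.model == "single":
        y = single_exponential(trace.times, fit.amplitudes[0], fit.rates[0], fit.offset)
    else:
        from .models import double_exponential

        y = double_exponential(trace.times, fit.amplitudes[0], fit.rates[0],
                               fit.amplitudes[1], fit.rates[1], fit.offset)
    ax.plot(trace.times, y, "-", lw=1.5,
            label=f"{fit.model} fit, k_obs = {fit.k_obs:.3g} s$^{{-1}}$")
    ax.set_ylabel(trace.signal_kind)
    ax.legend(frameon=False)
    axr.plot(trace.times, fit.residuals, ".", ms=2)
    axr.axhline(0, color="k", lw=0.5)
    axr.set_xlabel("time (s)")
    axr.set_ylabel("residual")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_kobs_vs_concentration(report, path) -> Path:
    """k_obs against titrant concentration, one line per condition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, ca in sorted(report.conditions.items()):
        r = ca.rates
        ax.plot(ca.concentrations_uM, ca.k_obs, "o",
                label=f"Mn$^{{2+}}$ {cond:g} uM")
        xs = [0, max(ca.concentrations_uM)]
        ax.plot(xs, [r.k_off + r.k_on * x for x in xs], "-", color=ax.lines[-1].get_color(), lw=1)
    ax.set_xlabel("titrant concentration (uM)")
    ax.set_ylabel(r"$k_{obs}$ (s$^{-1}$)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
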