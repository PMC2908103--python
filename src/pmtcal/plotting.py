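"""Optional fit plots: data, fitted curve, and the background-free line."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .fitting import ScanObservation
from .model import ScannerResponseModel, ideal_signal, predict_signal


def plot_fit(observations: Sequence[ScanObservation],
             model: ScannerResponseModel,
             path: str | Path) -> None:
    """Two-panel figure (log-log and linear) of spots, fit, and the
    autofluorescence-free ideal response."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = [(ob.x_nominal, ob.signal) for ob in observations
           if ob.x_nominal is not None and ob.x_nominal > 0]
    if not pts:
        raise ValueError("no spots with positive nominal density to plot")
    x_obs, s_obs = map(np.asarray, zip(*pts))
    grid = np.logspace(np.log10(x_obs.min()), np.log10(x_obs.max()), 300)

    fig, (ax_log, ax_lin) = plt.subplots(1, 2, figsize=(10, 4))
    for ax in (ax_log, ax_lin):
        ax.plot(x_obs, s_obs, ".", ms=3, alpha=0.5, label="spots")
        ax.plot(grid, predict_signal(grid, model), "m-", label="fit B·xᵃ+g")
        ax.plot(grid, ideal_signal(grid, model), "g--", label="ideal B·xᵃ")
        ax.axhline(model.g, color="grey", lw=0.8, ls=":",
                   label=f"g = {model.g:.3g}")
        ax.set_xlabel("surface density (fluorophores/µm²)")
        ax.set_ylabel("signal (counts)")
    ax_log.set_xscale("log")
    ax_log.set_yscale("log")
    ax_log.set_title("log-log")
    ax_lin.set_title("linear")
    ax_log.legend(fontsize=8)
    fig.suptitle(f"{model.channel} gain {model.pmt_gain}: "
                 f"B={model.B:.4g}, a={model.a:.3f}, g={model.g:.4g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
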