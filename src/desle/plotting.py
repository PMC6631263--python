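"""Optional convenience plots (phase diagrams); not part of the tested core."""

from __future__ import annotations

import numpy as np

from .phase_diagram import BinarySystem, branch_temperatures, eutectic_point

__all__ = ["plot_phase_diagram"]


def plot_phase_diagram(system: BinarySystem, n: int = 400, ax=None):
    """Plot both liquidus branches and mark the eutectic point.

    Returns the matplotlib Axes. Infeasible composition ranges are simply
    absent from the curves.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.linspace(1e-4, 1 - 1e-4, n)
    for branch, style in ((1, "-"), (2, "--")):
        T = branch_temperatures(system, branch, x)
        label = system.name1 if branch == 1 else system.name2
        ax.plot(x, T, style, label=f"liquidus {label}")
    try:
        eut = eutectic_point(system)
        ax.plot([eut.x1_e], [eut.Te], "ko", label=f"eutectic ({eut.Te:.1f} K)")
    except Exception:
        pass
    ax.set_xlabel(f"x({system.name1})")
    ax.set_ylabel("T / K")
    ax.legend(frameon=False, fontsize=8)
    return ax
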