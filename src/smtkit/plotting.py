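"""State-array histogram plotting."""

from __future__ import annotations

import numpy as np


def plot_state_array(marginal, diffusion, ax=None, label=None, **kwargs):
    """Occupation vs log-diffusion-coefficient histogram for one FOV.

    Returns the matplotlib axes; creates a figure if ``ax`` is None.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(np.asarray(diffusion), np.asarray(marginal), label=label, **kwargs)
    ax.set_xscale("log")
    ax.set_xlabel(r"diffusion coefficient ($\mu m^2$/s)")
    ax.set_ylabel("occupation")
    if label:
        ax.legend(frameon=False)
    return ax
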