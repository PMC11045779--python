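"""Plots for saliency profiles and motif matrices (matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_saliency", "plot_motif_matrix"]


def plot_saliency(profile, region_cfg=None, ax=None):
    """Line plot of a positionwise mean-importance profile.

    Marks the TSS, spacer and TTS boundaries when a region configuration is
    given.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.5))
    y = np.asarray(profile.mean_per_position)
    ax.plot(np.arange(y.size), y, lw=0.8, color="#1f4e79")
    ax.axhline(0, color="0.7", lw=0.5)
    if region_cfg is not None:
        for pos, label in [(region_cfg.tss_index(), "TSS"),
                           (region_cfg.upstream_len, "spacer"),
                           (region_cfg.tts_index(), "TTS")]:
            ax.axvline(pos, color="0.6", ls=":", lw=0.8)
            ax.text(pos, ax.get_ylim()[1], label, ha="center", va="bottom",
                    fontsize=7, color="0.4")
    ax.set_xlabel("position in fused input (nt)")
    ax.set_ylabel("mean importance")
    return ax


def plot_motif_matrix(epm, which="pwm", ax=None):
    """Heatmap of an EPM's PWM (base frequencies) or CWM (signed scores)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(2, epm.width / 3), 1.6))
    mat = (epm.pwm if which == "pwm" else epm.cwm).T
    cmap = "Blues" if which == "pwm" else "RdBu_r"
    vmax = np.abs(mat).max() or 1.0
    kw = {"vmin": 0, "vmax": 1} if which == "pwm" else {"vmin": -vmax, "vmax": vmax}
    ax.imshow(mat, aspect="auto", cmap=cmap, **kw)
    ax.set_yticks(range(4), list("ACGT"))
    ax.set_xlabel(f"{epm.name}  ({epm.consensus})")
    return ax
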