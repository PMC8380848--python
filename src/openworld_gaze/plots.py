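"""Diagnostic plots: saccade main sequence and angle distribution."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_main_sequence(main_sequence: pd.DataFrame, ax=None):
    """Log-log amplitude vs peak-velocity scatter of QC-passed saccades."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(main_sequence["amplitude_deg"],
              main_sequence["peak_vel_deg_s"], ".", ms=2, alpha=0.4)
    ax.set_xlabel("saccade amplitude (deg)")
    ax.set_ylabel("peak velocity (deg/s)")
    ax.set_title("Saccade main sequence")
    return ax


def plot_angle_hist(angle_hist: pd.DataFrame, ax=None):
    """Polar histogram (1-degree bins) of saccade directions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.deg2rad(angle_hist["angle_deg"].to_numpy())
    ax.bar(theta, angle_hist["count"].to_numpy(),
           width=np.deg2rad(1.0), bottom=0.0)
    ax.set_title("Saccade angle distribution")
    return ax
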