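"""Optional matplotlib figures (hourly profiles, wavelet spectra).

matplotlib is an optional dependency (``pip install reeftrack[plots]``);
imports are deferred so the analysis stack works without it.
"""

from __future__ import annotations

import numpy as np


def plot_hourly_profile(profiles: dict, ax=None, path: str | None = None):
    """Mean detections (+/- SE) per hour-of-day, one line per label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for label, prof in profiles.items():
        prof = prof.sort_values("hour")
        ax.errorbar(prof["hour"], prof["mean"], yerr=prof["se"], label=label,
                    marker="o", capsize=2)
    ax.set_xlabel("hour of day (local)")
    ax.set_ylabel("mean detections per hourly bin")
    ax.set_xticks(range(0, 24, 3))
    ax.legend()
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_spectrum(spectrum, ax=None, path: str | None = None):
    """Time x period power map with significance contours and the COI."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    t = spectrum.times / 24.0  # days
    ax.pcolormesh(t, spectrum.periods, np.log2(spectrum.power + 1e-12),
                  shading="auto", cmap="viridis")
    if spectrum.significance_mask is not None and spectrum.significance_mask.any():
        ax.contour(t, spectrum.periods, spectrum.significance_mask.astype(float),
                   levels=[0.5], colors="k", linewidths=1.2)
    ax.plot(t, spectrum.coi_period, color="w", lw=1.0)
    ax.axhline(24.0, color="w", ls="--", lw=0.8)
    ax.set_yscale("log", base=2)
    ax.set_ylim(spectrum.periods.min(), spectrum.periods.max())
    ax.invert_yaxis()
    ax.set_xlabel("time (days)")
    ax.set_ylabel("period (h)")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
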