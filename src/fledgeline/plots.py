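"""Static diagnostic plots: fitted proportion curves and exceedance profiles."""

from __future__ import annotations

import numpy as np

from .climate import ExceedanceResult
from .phenology import PosteriorDraws, proportion_curve


def plot_proportion_curves(
    draws: PosteriorDraws,
    elevations=(1650.0, 1850.0, 2050.0),
    doy_grid=None,
    raw_bins=None,
    ax=None,
):
    """Modelled fledged-proportion curves with 95% bands per elevation.

    Optionally overlays the raw binned proportions (midpoint of each bin)
    from :func:`fledgeline.atlas.binned_raw_proportions`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    if doy_grid is None:
        lo = draws.standardizer.mean_doy - 2.5 * draws.standardizer.sd_doy
        hi = draws.standardizer.mean_doy + 2.5 * draws.standardizer.sd_doy
        doy_grid = np.linspace(lo, hi, 120)
    for elev in elevations:
        curve = proportion_curve(draws, elev, doy_grid)
        (line,) = ax.plot(curve["doy"], curve["p_median"], label=f"{elev:.0f} m")
        ax.fill_between(
            curve["doy"], curve["p_low"], curve["p_high"],
            alpha=0.15, color=line.get_color(),
        )
    if raw_bins is not None:
        mid = (raw_bins["bin_start_doy"] + raw_bins["bin_end_doy"]) / 2.0
        # boundary bins (k=0 or k=n) have posterior intervals offset from
        # the degenerate point estimate; clip bar lengths at zero
        lower = np.clip(raw_bins["p_hat"] - raw_bins["ci_low"], 0, None)
        upper = np.clip(raw_bins["ci_high"] - raw_bins["p_hat"], 0, None)
        ax.errorbar(
            mid, raw_bins["p_hat"], yerr=[lower, upper],
            fmt="o", ms=3, color="grey", alpha=0.6, label="raw bins",
        )
    ax.set_xlabel("day of year")
    ax.set_ylabel("proportion certainly fledged")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_exceedance_profile(results: list[ExceedanceResult], ax=None):
    """Median band difference per threshold, with per-year spread and trend."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for res in results:
        years_vals = [v for v in res.yearly_difference.values() if np.isfinite(v)]
        ax.plot([res.threshold] * len(years_vals), years_vals, ".", color="0.7", ms=3)
    thr = [r.threshold for r in results]
    med = [r.median_difference for r in results]
    ax.plot(thr, med, "k-o", ms=4, label="median difference")
    trend = [r.trend_per_decade for r in results]
    ax2 = ax.twinx()
    ax2.plot(thr, trend, "r.", ms=5, label="trend (days/decade)")
    ax2.set_ylabel("trend (days/decade)", color="r")
    ax.set_xlabel("temperature threshold (°C)")
    ax.set_ylabel("exceedance-day difference high − low (days)")
    ax.legend(frameon=False, loc="upper left")
    return ax
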