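"""Diagnostic figures: the per-recording "fourplot" and the binned-CI
family plot.

The fourplot is a one-page QC summary of a recording, arranged 2x2:

A. estimated unit positions, each labelled with its unit number
   (coincident labels reveal units sharing a position);
B. population firing rate in 1 s bins averaged over the array —
   periodic elevations followed by silence are the signature of waves;
C. spike raster, unit 1 at the bottom;
D. correlation index against inter-unit distance, log y axis.

Every figure also has a machine-readable export of exactly the numbers
plotted, so tests compare data, not pixels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from .format_io import Recording, compute_summary, get_unit_spikes
from .spike_stats import DEFAULT_DT, ci_map, population_rate


def _log_floor(values: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Replace zeros with half the smallest positive value for log axes.

    Returns (plottable values, floor used, mask of floored entries).
    """
    vals = np.asarray(values, dtype=np.float64)
    pos = vals[np.isfinite(vals) & (vals > 0)]
    floor = float(pos.min()) / 2.0 if len(pos) else 1e-3
    floored = np.isfinite(vals) & (vals == 0)
    out = vals.copy()
    out[floored] = floor
    return out, floor, floored


def fourplot(
    rec: Recording,
    out: Union[str, Path],
    dt: float = DEFAULT_DT,
    export: Optional[Union[str, Path]] = None,
) -> dict:
    """Render the four-panel QC figure for one recording.

    Writes the figure to ``out`` (format by extension) and returns the
    plotted data as a dict; if ``export`` is given the dict is also
    written there as JSON.  With fewer than two units panel D is
    annotated as unavailable instead of plotted.
    """
    if rec.summary is None:
        rec.summary = compute_summary(rec)
    n = rec.n_units
    title = rec.name or rec.meta.key

    edges, rates = population_rate(rec, binwidth=1.0)
    raster = [get_unit_spikes(rec, j) for j in range(1, n + 1)]

    data: dict = {
        "title": title,
        "positions": rec.epos.tolist(),
        "pop_rate": {"bin_left_s": edges.tolist(), "rate_hz": rates.tolist()},
        "raster": [t.tolist() for t in raster],
    }

    fig = Figure(figsize=(10, 8))
    axs = fig.subplots(2, 2)
    fig.suptitle(title)

    ax = axs[0, 0]
    for j in range(n):
        ax.text(
            rec.epos[j, 0], rec.epos[j, 1], str(j + 1),
            ha="center", va="center", fontsize=7,
        )
    pad_x = 0.05 * (np.ptp(rec.epos[:, 0]) or 1.0)
    pad_y = 0.05 * (np.ptp(rec.epos[:, 1]) or 1.0)
    ax.set_xlim(rec.epos[:, 0].min() - pad_x, rec.epos[:, 0].max() + pad_x)
    ax.set_ylim(rec.epos[:, 1].min() - pad_y, rec.epos[:, 1].max() + pad_y)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title("A: unit positions")

    ax = axs[0, 1]
    ax.step(edges, rates, where="post", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean rate (Hz)")
    ax.set_title("B: population rate, 1 s bins")

    ax = axs[1, 0]
    for j, t in enumerate(raster, start=1):
        if len(t):
            ax.vlines(t, j - 0.4, j + 0.4, lw=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("unit")
    ax.set_title("C: raster")

    ax = axs[1, 1]
    if n >= 2:
        pairs = ci_map(rec, dt=dt)
        finite = pairs.dropna(subset=["ci"])
        ci_plot, floor, floored = _log_floor(finite["ci"].to_numpy())
        ax.plot(finite["distance_um"], ci_plot, ".", ms=3, alpha=0.6)
        ax.set_yscale("log")
        ax.set_xlabel("distance (µm)")
        ax.set_ylabel("correlation index")
        ax.set_title(f"D: correlation index (dt={dt * 1e3:.0f} ms)")
        data["ci"] = {
            "distance_um": finite["distance_um"].tolist(),
            "ci": finite["ci"].tolist(),
            "log_floor": floor,
            "floored": floored.tolist(),
        }
    else:
        ax.text(0.5, 0.5, "CI unavailable\n(fewer than 2 units)",
                ha="center", va="center", transform=ax.transAxes)
        ax.set_axis_off()
        data["ci"] = None

    fig.tight_layout()
    fig.savefig(out)

    if export is not None:
        Path(export).write_text(json.dumps(data))
    return data


def ci_family_plot(
    groups: Mapping[str, list[pd.DataFrame]],
    out: Union[str, Path],
    export: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """One mean-CI-vs-distance line per recording, coloured by group.

    ``groups`` maps a label (e.g. genotype) to a list of binned-CI
    tables (one per recording, as produced by
    :func:`mearec.spike_stats.bin_ci_by_distance`).  Returns the
    long-format table of plotted points (label, member, bin_centre,
    mean_ci); written as CSV when ``export`` is given.
    """
    if not groups:
        raise ValueError("no groups to plot")

    fig = Figure(figsize=(7, 5))
    ax = fig.subplots()
    cmap = dict(zip(groups, ("C0", "C1", "C2", "C3", "C4", "C5", "C6", "C7")))
    rows = []
    for label, members in groups.items():
        for m_idx, binned in enumerate(members):
            ci_plot, _, _ = _log_floor(binned["mean_ci"].to_numpy())
            ax.plot(
                binned["bin_centre"], ci_plot,
                color=cmap.get(label, "C8"),
                label=label if m_idx == 0 else None,
                lw=1,
            )
            for _, r in binned.iterrows():
                rows.append(
                    {
                        "label": label,
                        "member": m_idx,
                        "bin_centre": float(r["bin_centre"]),
                        "mean_ci": float(r["mean_ci"]),
                        "n_pairs": int(r["n_pairs"]),
                    }
                )
    ax.set_yscale("log")
    ax.set_xlabel("distance (µm)")
    ax.set_ylabel("mean correlation index")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out)

    table = pd.DataFrame(rows)
    if export is not None:
        table.to_csv(export, index=False)
    return table
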