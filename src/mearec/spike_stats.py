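"""Pairwise correlation-index analysis and firing-rate time series.

Retinal waves correlate the firing of neighbouring retinal ganglion
cells.  The classic statistic for this is the *correlation index*: for
two spike trains a and b recorded for T seconds, count the spike pairs
that fall within ±dt of each other and normalise by the count expected
if the trains were independent::

    CI(a, b) = N_ab(dt) * T / (N_a * N_b * 2 * dt)

where ``N_ab(dt)`` is the number of pairs (s in a, t in b) with
``|s - t| <= dt``, and N_a, N_b the train sizes.  Independent trains
give CI ~= 1; co-active trains give CI >> 1.  The conventional window is
dt = 50 ms.  Plotting CI against the distance separating the two units
on the array reveals the spatial footprint of the waves: nearby pairs
are strongly correlated, distant pairs approach independence.

This module computes CI for all unit pairs of a recording, bins the
pairs by inter-unit distance (100 um bins by default), and provides the
1-second-binned population firing rate used in the QC fourplot.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .format_io import Recording, compute_summary, get_unit_spikes

DEFAULT_DT = 0.05  # s; the conventional +/-50 ms coincidence window


def _check_sorted(x: np.ndarray, label: str) -> None:
    if len(x) > 1 and np.any(np.diff(x) < 0):
        raise ValueError(f"spike train {label} must be sorted ascending")


def coincidence_count(
    a: np.ndarray, b: np.ndarray, dt: float, *, assume_sorted: bool = False
) -> int:
    """Number of ordered spike pairs (s in a, t in b) with |s - t| <= dt.

    The window is closed at both ends.  Uses vectorised bisection on
    the sorted trains, so cost grows as ``|a| log |b|`` rather than the
    ``|a| * |b|`` of brute-force enumeration.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        return 0
    if not assume_sorted:
        _check_sorted(a, "a")
        _check_sorted(b, "b")
    hi = np.searchsorted(b, a + dt, side="right")
    lo = np.searchsorted(b, a - dt, side="left")
    return int(np.sum(hi - lo))


def correlation_index(
    a: np.ndarray,
    b: np.ndarray,
    dt: float = DEFAULT_DT,
    T: float = None,
    *,
    assume_sorted: bool = False,
) -> float:
    """Correlation index of two sorted spike trains over duration ``T``.

    Returns NaN when either train is empty (the statistic is undefined,
    and 0 would fake anti-correlation).
    """
    if T is None or T <= 0:
        raise ValueError("recording duration T must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    nab = coincidence_count(a, b, dt, assume_sorted=assume_sorted)
    return nab * T / (len(a) * len(b) * 2.0 * dt)


def ci_map(rec: Recording, dt: float = DEFAULT_DT) -> pd.DataFrame:
    """Correlation index and distance for every unordered unit pair.

    Returns a DataFrame with columns ``i``, ``j`` (1-based unit
    numbers, i < j), ``distance_um`` (Euclidean, in the electrode
    plane) and ``ci``.  All N(N-1)/2 pairs are present, including
    zero-distance pairs (units sharing an array location); pairs
    involving an empty train carry ``ci = NaN``.  T is taken from the
    summary cache (the whole-second recording duration).
    """
    n = rec.n_units
    if n < 2:
        raise ValueError("need at least two units to form pairs")
    summary = rec.summary if rec.summary is not None else compute_summary(rec)
    T = float(summary.duration)

    trains = [get_unit_spikes(rec, j) for j in range(1, n + 1)]
    dists = pdist(rec.epos)  # same (i<j) pair order as the loop below
    ii, jj, cis = [], [], []
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            ii.append(i + 1)
            jj.append(j + 1)
            cis.append(
                correlation_index(trains[i], trains[j], dt, T, assume_sorted=True)
            )
            k += 1
    return pd.DataFrame(
        {
            "i": np.array(ii, dtype=np.int64),
            "j": np.array(jj, dtype=np.int64),
            "distance_um": dists,
            "ci": np.array(cis, dtype=np.float64),
        }
    )


def bin_ci_by_distance(pairs: pd.DataFrame, width: float = 100.0) -> pd.DataFrame:
    """Mean correlation index in contiguous distance bins.

    Bins are left-closed right-open ``[k*width, (k+1)*width)``.  NaN
    pairs (empty trains) are excluded from the means; bins containing
    no pairs are omitted.  Returns columns ``bin_left``, ``bin_centre``,
    ``mean_ci``, ``n_pairs``.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if len(pairs) == 0:
        raise ValueError("no pairs to bin")
    ok = pairs.dropna(subset=["ci"])
    idx = np.floor(ok["distance_um"].to_numpy() / width).astype(np.int64)
    grouped = (
        pd.DataFrame({"bin": idx, "ci": ok["ci"].to_numpy()})
        .groupby("bin")["ci"]
        .agg(["mean", "size"])
        .reset_index()
        .sort_values("bin")
    )
    return pd.DataFrame(
        {
            "bin_left": grouped["bin"] * width,
            "bin_centre": (grouped["bin"] + 0.5) * width,
            "mean_ci": grouped["mean"],
            "n_pairs": grouped["size"].astype(np.int64),
        }
    ).reset_index(drop=True)


def population_rate(
    rec: Recording, binwidth: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Array-averaged firing rate in fixed time bins.

    Bins cover ``[0, duration)``; each bin's value is the total spike
    count across all units divided by ``N * binwidth``, i.e. the mean
    per-unit rate in Hz.  Returns ``(bin_left_edges, rates)``.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    summary = rec.summary if rec.summary is not None else compute_summary(rec)
    duration = summary.duration
    nbins = int(np.ceil(duration / binwidth))
    edges = np.arange(nbins + 1) * binwidth
    counts, _ = np.histogram(rec.spikes, bins=edges)
    rates = counts / (rec.n_units * binwidth)
    return edges[:-1], rates


def unit_firing_rates(rec: Recording) -> np.ndarray:
    """Per-unit firing rate in Hz: sCount / duration.

    Recomputed from the spike data (identical to the stored
    ``/summary/frate``); exposed as a cross-check for cached files.
    """
    summary = compute_summary(rec) if rec.summary is None else rec.summary
    return rec.scount.astype(np.float64) / summary.duration
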