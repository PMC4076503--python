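"""Synthetic MEA recordings: array layouts, retinal waves, Poisson nulls.

The generator produces schema-conformant recordings whose statistics
mimic spontaneous activity in developing retina, so the whole analysis
pipeline can be exercised at desk scale:

* episodic waves — population-rate peaks separated by near-silence;
* distance-decaying pairwise correlation index;
* per-unit bursts riding on sparse background firing.

The wave model is deliberately minimal.  Wave initiation events form a
homogeneous Poisson process in time (rate ``wave_rate``) with origins
uniform on the array's bounding box.  Each wave expands as a circular
front at constant speed ``speed``; when the front reaches a unit the
unit emits a Poisson burst (rate ``burst_rate`` for ``burst_duration``
seconds) unless it is still within ``refractory`` seconds of its last
activation.  Independent background spiking at ``background_rate``
runs throughout.  Waves have unbounded extent and do not interact —
the point is to produce the right pairwise statistics, not retinal
biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .format_io import Metadata, Recording, with_summary

LAYOUT_NAMES = (
    "MCS_8x8_100um",
    "MCS_8x8_200um",
    "APS_64x64_42um",
    "hex_60um_61",
    "hex_60um_512",
)


def _square_lattice(side: int, spacing: float, drop_corners: bool) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64) * spacing
    if drop_corners:
        m = side - 1
        corners = {(0.0, 0.0), (0.0, m * spacing), (m * spacing, 0.0),
                   (m * spacing, m * spacing)}
        keep = [tuple(p) not in corners for p in pts]
        pts = pts[np.array(keep)]
    return pts


def _hex_lattice(n_sites: int, spacing: float) -> np.ndarray:
    # Triangular lattice (60 um nearest neighbours), trimmed to the
    # n_sites points closest to the patch centre -> roughly hexagonal.
    half = int(np.ceil(np.sqrt(n_sites))) + 2
    pts = []
    for row in range(-half, half + 1):
        y = row * spacing * np.sqrt(3) / 2
        xoff = (row % 2) * spacing / 2
        for col in range(-half, half + 1):
            pts.append((col * spacing + xoff, y))
    pts = np.array(pts, dtype=np.float64)
    d2 = np.sum(pts**2, axis=1)
    order = np.lexsort((pts[:, 0], pts[:, 1], np.round(d2, 6)))
    pts = pts[order][:n_sites]
    pts -= pts.min(axis=0)  # positions are non-negative um
    return pts


def make_layout(name: str) -> np.ndarray:
    """Electrode positions (um) for a named MEA layout.

    Supported layouts: ``MCS_8x8_100um`` / ``MCS_8x8_200um`` (8x8
    square lattices at 100/200 um spacing with the four corner sites
    absent, 60 electrodes), ``APS_64x64_42um`` (full 64x64 lattice at
    42 um, 4096 electrodes), and ``hex_60um_61`` / ``hex_60um_512``
    (triangular lattices with 60 um nearest-neighbour spacing trimmed
    to 61 / 512 sites).
    """
    if name == "MCS_8x8_100um":
        return _square_lattice(8, 100.0, drop_corners=True)
    if name == "MCS_8x8_200um":
        return _square_lattice(8, 200.0, drop_corners=True)
    if name == "APS_64x64_42um":
        return _square_lattice(64, 42.0, drop_corners=False)
    if name == "hex_60um_61":
        return _hex_lattice(61, 60.0)
    if name == "hex_60um_512":
        return _hex_lattice(512, 60.0)
    raise ValueError(
        f"unknown layout {name!r}; supported: {', '.join(LAYOUT_NAMES)}"
    )


@dataclass(frozen=True)
class WaveSimParams:
    """Parameters of the propagating-wave generative model.

    Defaults emulate a half-hour recording of early postnatal retinal
    waves on a standard 60-electrode array: a wave every ~50 s on
    average, sweeping the array at 200 um/s, driving ~30 spikes per
    unit per wave over sparse 0.05 Hz background firing.
    """

    seed: int
    layout: str = "MCS_8x8_100um"
    duration: float = 1800.0  # T, s
    wave_rate: float = 0.02  # waves/s, Poisson in time
    speed: float = 200.0  # wavefront speed, um/s
    burst_rate: float = 30.0  # within-burst firing rate, Hz
    burst_duration: float = 1.0  # s
    background_rate: float = 0.05  # Hz
    refractory: float = 5.0  # min gap between activations of one unit, s

    def __post_init__(self) -> None:
        positive = {
            "duration": self.duration,
            "speed": self.speed,
            "burst_rate": self.burst_rate,
            "burst_duration": self.burst_duration,
            "refractory": self.refractory,
        }
        for k, v in positive.items():
            if v <= 0:
                raise ValueError(f"{k} must be positive, got {v}")
        if self.wave_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be non-negative")


def _poisson_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_waves(params: WaveSimParams) -> Recording:
    """Simulate one recording of propagating-wave activity.

    The returned recording passes validation, carries metadata
    ``key="synthetic", species="synthetic", age=0`` and a computed
    summary.  Identical parameters (including seed) give identical
    output; the generator owns all randomness.
    """
    rng = np.random.default_rng(params.seed)
    epos = make_layout(params.layout)
    n = len(epos)
    T = params.duration

    # Wave initiation: Poisson in time, uniform origin on bounding box.
    t_waves = _poisson_times(rng, params.wave_rate, 0.0, T)
    lo, hi = epos.min(axis=0), epos.max(axis=0)
    origins = rng.uniform(lo, hi, size=(len(t_waves), 2))

    trains: list[np.ndarray] = [
        _poisson_times(rng, params.background_rate, 0.0, T) for _ in range(n)
    ]
    last_activation = np.full(n, -np.inf)
    for t0, origin in zip(t_waves, origins):
        arrival = t0 + np.linalg.norm(epos - origin, axis=1) / params.speed
        for u in np.flatnonzero(arrival < T):
            if arrival[u] - last_activation[u] < params.refractory:
                continue
            last_activation[u] = arrival[u]
            burst = _poisson_times(
                rng,
                params.burst_rate,
                arrival[u],
                arrival[u] + params.burst_duration,
            )
            trains[u] = np.concatenate([trains[u], burst])

    for u in range(n):
        t = np.sort(trains[u], kind="stable")
        trains[u] = t[(t >= 0) & (t < T)]

    rec = Recording(
        epos=epos,
        spikes=np.concatenate(trains) if trains else np.empty(0),
        scount=np.array([len(t) for t in trains], dtype=np.int64),
        array=params.layout,
        meta=Metadata(key="synthetic", species="synthetic", age=0),
        name=f"waves_{params.layout}_seed{params.seed}",
    )
    return with_summary(rec)


def simulate_poisson(
    rate: float, duration: float, layout: str = "MCS_8x8_100um", seed: int = 0
) -> Recording:
    """Independent homogeneous Poisson trains on a named layout.

    The null model for the correlation index: independent trains have
    expected CI of 1 at any window.  ``rate`` is per-unit, in Hz.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    epos = make_layout(layout)
    trains = [_poisson_times(rng, rate, 0.0, duration) for _ in range(len(epos))]
    rec = Recording(
        epos=epos,
        spikes=np.concatenate(trains) if trains else np.empty(0),
        scount=np.array([len(t) for t in trains], dtype=np.int64),
        array=layout,
        meta=Metadata(key="synthetic", species="synthetic", age=0),
        name=f"poisson_{layout}_seed{seed}",
    )
    return with_summary(rec)
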