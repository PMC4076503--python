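"""Read, write and validate HDF5 multielectrode-array (MEA) spike recordings.

One recording of spontaneous retinal activity is stored in a single HDF5
file.  The root of the file holds the principal data:

``epos``
    N x 2 matrix of (x, y) unit positions in micrometres, one row per
    spike train.
``sCount``
    length-N vector; ``sCount[i]`` is the number of spikes in train *i*.
``spikes``
    length-S vector of spike times in seconds, where S = sum(sCount).
    All trains are concatenated into this one vector; within each train
    the times are sorted ascending.
``array``
    string label naming the MEA layout (an open vocabulary).
``names``
    optional length-N vector of unit-name strings.

Metadata live under ``/meta`` (key, species, age, genotype, cond) and a
cache of derived quantities under ``/summary`` (N, duration, frate,
totalspikes).  ``duration`` is the maximum spike time rounded up to the
nearest whole second, and ``frate[i] = sCount[i] / duration``.

This module provides the :class:`Recording` container, the summary
computation, strict writer / tolerant reader, and a validator that
reports schema violations with stable codes.
"""

from __future__ import annotations

import math
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np

logger = logging.getLogger("mearec")

# Default age sentinel for adult animals (postnatal days).
ADULT_AGE = 500

# Seed vocabularies for metadata labels.  These are OPEN sets: unseen
# labels are legal (the validator logs a warning only), since conditions
# in particular are free text.
KNOWN_ARRAYS = frozenset(
    {
        "MCS_8x8_100um",
        "MCS_8x8_200um",
        "APS_64x64_42um",
        "litke_hex_60um",
        "EJC1_hex_60um",
        "stanford_hex_60um",
        "hex_60um_61",
        "hex_60um_512",
        "synthetic",
    }
)
KNOWN_SPECIES = frozenset({"mouse", "ferret", "synthetic"})

_META_REQUIRED = ("key", "species", "age")
_ROOT_REQUIRED = ("epos", "sCount", "spikes", "array")


class SchemaError(ValueError):
    """A file does not conform to the HDF5 recording schema."""


@dataclass(frozen=True)
class Metadata:
    """Minimal per-recording metadata (stored under ``/meta``).

    Parameters
    ----------
    key
        Study identifier, typically first-author surname plus year
        (e.g. ``"Wong1993"``).
    species
        Species name (e.g. ``"mouse"``, ``"ferret"``).
    age
        Postnatal age in days.  Zero is the day of birth, negative
        values denote embryonic ages, and the sentinel ``500`` marks
        adult recordings.
    genotype
        Genotype label; ``"wt"`` (wild type) when absent.
    cond
        Recording condition; ``"ctl"`` (control) when absent.
    """

    key: str
    species: str
    age: int
    genotype: str = "wt"
    cond: str = "ctl"


@dataclass(frozen=True)
class SummaryBlock:
    """Cached per-recording summary (stored under ``/summary``)."""

    n: int
    duration: int
    frate: np.ndarray
    totalspikes: int

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryBlock):
            return NotImplemented
        return (
            self.n == other.n
            and self.duration == other.duration
            and self.totalspikes == other.totalspikes
            and np.array_equal(self.frate, other.frate)
        )


@dataclass
class Recording:
    """In-memory mirror of one HDF5 recording file."""

    epos: np.ndarray
    spikes: np.ndarray
    scount: np.ndarray
    array: str
    meta: Metadata
    names: Optional[Sequence[str]] = None
    summary: Optional[SummaryBlock] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.epos = np.asarray(self.epos, dtype=np.float64)
        self.spikes = np.asarray(self.spikes, dtype=np.float64)
        self.scount = np.asarray(self.scount, dtype=np.int64)
        if self.names is not None:
            self.names = [str(s) for s in self.names]

    @property
    def n_units(self) -> int:
        return len(self.scount)

    def unit_spikes(self, j: int) -> np.ndarray:
        """Spike times of unit ``j`` (1-based, matching the on-disk
        concatenation convention)."""
        return get_unit_spikes(self, j)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            np.array_equal(self.epos, other.epos)
            and np.array_equal(self.spikes, other.spikes)
            and np.array_equal(self.scount, other.scount)
            and self.array == other.array
            and self.meta == other.meta
            and (self.names is None) == (other.names is None)
            and (self.names is None or list(self.names) == list(other.names))
            and self.summary == other.summary
        )


@dataclass(frozen=True)
class Violation:
    """One validation failure: a stable machine code plus a message."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code}: {self.message}"


# ---------------------------------------------------------------------------
# Indexing into the concatenated spike vector
# ---------------------------------------------------------------------------

def unit_slice(scount: Sequence[int], j: int) -> tuple[int, int]:
    """1-based inclusive element range (a, b) of unit ``j`` in ``spikes``.

    The spikes of train j occupy elements a..b of the concatenated
    vector with ``a = 1 + sum(sCount[:j-1])`` and
    ``b = a + sCount[j] - 1``.  An empty train yields ``b < a``.

    Raises
    ------
    IndexError
        If ``j`` is outside ``1..N``.
    """
    scount = np.asarray(scount)
    n = len(scount)
    if not 1 <= j <= n:
        raise IndexError(f"unit index {j} out of range 1..{n}")
    a = 1 + int(np.sum(scount[: j - 1]))
    b = a + int(scount[j - 1]) - 1
    return a, b


def get_unit_spikes(rec: Recording, j: int) -> np.ndarray:
    """Spike-time vector of unit ``j`` (1-based), length ``sCount[j]``."""
    a, b = unit_slice(rec.scount, j)
    return rec.spikes[a - 1 : b]  # 1-based inclusive -> 0-based half-open


# ---------------------------------------------------------------------------
# Summary cache
# ---------------------------------------------------------------------------

def compute_summary(
    rec: Recording, duration: Optional[int] = None
) -> SummaryBlock:
    """Compute the ``/summary`` block from the spike data.

    ``duration`` is the maximum spike time rounded up to the nearest
    second.  With zero spikes the duration is undefined; supply an
    explicit ``duration`` override or a :class:`SchemaError` is raised.
    """
    total = int(np.sum(rec.scount))
    if duration is None:
        if total == 0:
            raise SchemaError(
                "duration undefined for a recording with no spikes; "
                "pass an explicit duration"
            )
        duration = int(math.ceil(float(np.max(rec.spikes))))
        duration = max(duration, 1)  # all spikes at t=0 still occupy 1 s
    duration = int(duration)
    if duration <= 0:
        raise SchemaError("duration must be a positive whole number of seconds")
    frate = rec.scount.astype(np.float64) / duration
    return SummaryBlock(
        n=rec.n_units, duration=duration, frate=frate, totalspikes=total
    )


def with_summary(rec: Recording, duration: Optional[int] = None) -> Recording:
    """Return a copy of ``rec`` with a freshly computed summary attached."""
    return replace(rec, summary=compute_summary(rec, duration=duration))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _validate_in_memory(rec: Recording) -> list[Violation]:
    v: list[Violation] = []
    epos, scount, spikes = rec.epos, rec.scount, rec.spikes

    if epos.ndim != 2 or epos.shape[1] != 2:
        v.append(
            Violation("EPOS_SHAPE", f"epos must be N x 2, got {epos.shape}")
        )
    elif epos.shape[0] != len(scount):
        v.append(
            Violation(
                "EPOS_LEN_MISMATCH",
                f"epos has {epos.shape[0]} rows but sCount has "
                f"{len(scount)} entries",
            )
        )
    if not np.all(np.isfinite(epos)):
        v.append(Violation("EPOS_NONFINITE", "epos contains non-finite values"))

    if np.any(scount < 0):
        v.append(Violation("SCOUNT_NEGATIVE", "sCount has negative entries"))

    total = int(np.sum(scount))
    if total != len(spikes):
        v.append(
            Violation(
                "SPIKES_LEN_MISMATCH",
                f"sum(sCount)={total} but len(spikes)={len(spikes)}",
            )
        )
    if len(spikes) and not np.all(np.isfinite(spikes)):
        v.append(
            Violation("SPIKES_NONFINITE", "spike times contain non-finite values")
        )
    elif len(spikes) and float(np.min(spikes)) < 0:
        v.append(Violation("SPIKES_NEGATIVE", "spike times must be >= 0"))

    if total == len(spikes) and not np.any(scount < 0):
        offs = np.concatenate(([0], np.cumsum(scount)))
        for j in range(len(scount)):
            seg = spikes[offs[j] : offs[j + 1]]
            if len(seg) > 1 and np.any(np.diff(seg) < 0):
                v.append(
                    Violation(
                        "TRAIN_UNSORTED",
                        f"spike train {j + 1} is not sorted ascending",
                    )
                )

    if rec.names is not None and len(rec.names) != len(scount):
        v.append(
            Violation(
                "NAMES_LEN_MISMATCH",
                f"names has {len(rec.names)} entries for {len(scount)} trains",
            )
        )

    # Metadata
    if not rec.meta.key:
        v.append(Violation("META_MISSING_KEY", "meta key is empty"))
    if not rec.meta.species:
        v.append(Violation("META_MISSING_SPECIES", "meta species is empty"))
    if not isinstance(rec.meta.age, (int, np.integer)):
        v.append(
            Violation("META_AGE_NOT_INT", f"age must be an integer, got {rec.meta.age!r}")
        )
    if rec.meta.species and rec.meta.species not in KNOWN_SPECIES:
        logger.warning("unrecognised species label %r", rec.meta.species)
    if rec.array and rec.array not in KNOWN_ARRAYS:
        logger.warning("unrecognised array label %r", rec.array)
    if not rec.array:
        v.append(Violation("ARRAY_MISSING", "array label is empty"))

    # Summary consistency, if a summary is attached.
    s = rec.summary
    if s is not None and total > 0 and total == len(spikes):
        expect_dur = max(1, int(math.ceil(float(np.max(spikes)))))
        if s.duration != expect_dur:
            v.append(
                Violation(
                    "SUMMARY_DURATION_WRONG",
                    f"stored duration {s.duration} != ceil(max spike) "
                    f"{expect_dur}",
                )
            )
        if s.n != len(scount):
            v.append(
                Violation(
                    "SUMMARY_N_WRONG",
                    f"stored N {s.n} != number of trains {len(scount)}",
                )
            )
        if s.totalspikes != total:
            v.append(
                Violation(
                    "SUMMARY_TOTALSPIKES_WRONG",
                    f"stored totalspikes {s.totalspikes} != sum(sCount) {total}",
                )
            )
        if s.duration > 0 and (
            len(s.frate) != len(scount)
            or not np.allclose(
                np.asarray(s.frate) * s.duration, scount, rtol=0, atol=1e-9
            )
        ):
            v.append(
                Violation(
                    "SUMMARY_FRATE_WRONG",
                    "stored frate inconsistent with sCount / duration",
                )
            )
    return v


def validate_recording(rec_or_path: Union[Recording, str, Path]) -> list[Violation]:
    """Check a recording (in memory or on disk) against all invariants.

    Returns an empty list iff every invariant of the container, its
    metadata and its summary cache holds.  Unseen vocabulary labels
    (array, species) are logged as warnings, not returned as
    violations.  An unreadable file raises :class:`OSError` rather than
    returning violations, so I/O trouble is never mistaken for a
    schema problem.
    """
    if isinstance(rec_or_path, Recording):
        return _validate_in_memory(rec_or_path)
    path = Path(rec_or_path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rec = read_recording(path)
    except SchemaError as e:
        return [Violation("SCHEMA_ERROR", str(e))]
    return _validate_in_memory(rec)


# ---------------------------------------------------------------------------
# HDF5 reader / writer
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _read_scalar_str(g: h5py.Group, name: str) -> str:
    raw = g[name][()]
    if isinstance(raw, bytes):
        return raw.decode("utf-8")
    if isinstance(raw, np.ndarray):  # stored as length-1 vector
        raw = raw.reshape(-1)[0]
        if isinstance(raw, bytes):
            return raw.decode("utf-8")
    return str(raw)


def read_recording(path: Union[str, Path]) -> Recording:
    """Load one HDF5 recording.

    Tolerant on input: a ``(2, N)`` epos (column-major writers) is
    transposed to ``N x 2`` (an ambiguous 2x2 is taken as-is); absent
    genotype/cond materialise as their defaults; an absent ``/summary``
    is recomputed.  Missing required datasets raise
    :class:`SchemaError` naming the dataset.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for ds in _ROOT_REQUIRED:
            if ds not in f:
                raise SchemaError(f"missing required dataset: {ds}")
        if "meta" not in f:
            raise SchemaError("missing required group: /meta")
        meta_g = f["meta"]
        for ds in _META_REQUIRED:
            if ds not in meta_g:
                raise SchemaError(f"missing required dataset: /meta/{ds}")

        epos = np.asarray(f["epos"], dtype=np.float64)
        scount = np.asarray(f["sCount"], dtype=np.int64).reshape(-1)
        spikes = np.asarray(f["spikes"], dtype=np.float64).reshape(-1)
        if epos.ndim != 2:
            raise SchemaError(f"epos must be 2-D, got shape {epos.shape}")
        n = len(scount)
        if epos.shape == (2, n) and n != 2:
            epos = epos.T  # column-major writer; normalise to N x 2

        array = _read_scalar_str(f, "array")
        names = None
        if "names" in f:
            raw = np.asarray(f["names"]).reshape(-1)
            names = [
                s.decode("utf-8") if isinstance(s, bytes) else str(s)
                for s in raw
            ]

        meta = Metadata(
            key=_read_scalar_str(meta_g, "key"),
            species=_read_scalar_str(meta_g, "species"),
            age=int(np.asarray(meta_g["age"][()]).reshape(-1)[0]),
            genotype=_read_scalar_str(meta_g, "genotype")
            if "genotype" in meta_g
            else "wt",
            cond=_read_scalar_str(meta_g, "cond") if "cond" in meta_g else "ctl",
        )

        summary = None
        if "summary" in f:
            sg = f["summary"]
            try:
                summary = SummaryBlock(
                    n=int(np.asarray(sg["N"][()]).reshape(-1)[0]),
                    duration=int(np.asarray(sg["duration"][()]).reshape(-1)[0]),
                    frate=np.asarray(sg["frate"], dtype=np.float64).reshape(-1),
                    totalspikes=int(
                        np.asarray(sg["totalspikes"][()]).reshape(-1)[0]
                    ),
                )
            except KeyError as e:
                raise SchemaError(f"incomplete /summary group: {e}") from e

    rec = Recording(
        epos=epos,
        spikes=spikes,
        scount=scount,
        array=array,
        meta=meta,
        names=names,
        summary=summary,
        name=path.stem,
    )
    if rec.summary is None and int(np.sum(scount)) > 0:
        rec.summary = compute_summary(rec)
    return rec


def write_recording(rec: Recording, path: Union[str, Path]) -> None:
    """Write a validated recording to ``path`` in the HDF5 schema.

    Refuses to write an invalid recording, reporting every violation.
    Spike times and firing rates are stored as 64-bit IEEE floats,
    counts and ages as 64-bit integers, strings as variable-length
    UTF-8 — so a write/read round trip is bit-exact.
    """
    if rec.summary is None:
        rec = with_summary(rec)
    violations = _validate_in_memory(rec)
    if violations:
        msgs = "; ".join(str(x) for x in violations)
        raise SchemaError(f"refusing to write invalid recording: {msgs}")

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("epos", data=rec.epos.astype(np.float64))
        f.create_dataset("sCount", data=rec.scount.astype(np.int64))
        f.create_dataset("spikes", data=rec.spikes.astype(np.float64))
        f.create_dataset("array", data=rec.array, dtype=_STR)
        if rec.names is not None:
            f.create_dataset(
                "names", data=np.asarray(list(rec.names), dtype=object), dtype=_STR
            )
        mg = f.create_group("meta")
        mg.create_dataset("key", data=rec.meta.key, dtype=_STR)
        mg.create_dataset("species", data=rec.meta.species, dtype=_STR)
        mg.create_dataset("age", data=np.int64(rec.meta.age))
        mg.create_dataset("genotype", data=rec.meta.genotype, dtype=_STR)
        mg.create_dataset("cond", data=rec.meta.cond, dtype=_STR)
        sg = f.create_group("summary")
        sg.create_dataset("N", data=np.int64(rec.summary.n))
        sg.create_dataset("duration", data=np.int64(rec.summary.duration))
        sg.create_dataset("frate", data=rec.summary.frate.astype(np.float64))
        sg.create_dataset("totalspikes", data=np.int64(rec.summary.totalspikes))
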