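"""Repository-level inventory over directories of recording files.

Scans a directory tree of HDF5 recordings and tabulates one row per
file (metadata plus the cached summary), from which contingency tables
— recordings per species, per study and age, per genotype, per
condition, per array — and the log-log overview of recording size
(number of spike trains vs duration) are built.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .format_io import compute_summary, read_recording

logger = logging.getLogger("mearec")

CATALOG_FIELDS = ("key", "species", "age", "genotype", "cond", "array")

_COLUMNS = [
    "path", "key", "species", "age", "genotype", "cond", "array",
    "n", "duration_s", "totalspikes", "mean_rate_hz", "bytes",
]


def scan_repository(
    directory: Union[str, Path], on_error: str = "skip"
) -> pd.DataFrame:
    """Catalogue every ``*.h5`` file under ``directory`` (recursive).

    Returns one row per readable file, ordered lexicographically by
    path.  Summary values come from the file's ``/summary`` cache
    (recomputed if absent).  Unreadable files are skipped with a
    logged warning when ``on_error="skip"`` or re-raised with
    ``on_error="fail"``.
    """
    if on_error not in ("skip", "fail"):
        raise ValueError("on_error must be 'skip' or 'fail'")
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")

    rows = []
    for path in sorted(directory.rglob("*.h5")):
        try:
            rec = read_recording(path)
            s = rec.summary if rec.summary is not None else compute_summary(rec)
        except Exception as e:
            if on_error == "fail":
                raise
            logger.warning("skipping unreadable file %s: %s", path, e)
            continue
        rows.append(
            {
                "path": str(path),
                "key": rec.meta.key,
                "species": rec.meta.species,
                "age": rec.meta.age,
                "genotype": rec.meta.genotype,
                "cond": rec.meta.cond,
                "array": rec.array,
                "n": s.n,
                "duration_s": s.duration,
                "totalspikes": s.totalspikes,
                "mean_rate_hz": float(np.mean(s.frate)) if s.n else 0.0,
                "bytes": path.stat().st_size,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def count_by(rows: pd.DataFrame, fields: Sequence[str]) -> pd.DataFrame:
    """Contingency table of recordings per unique metadata combination.

    ``fields`` must be drawn from ``key, species, age, genotype, cond,
    array``.  With one field the result is a one-column count table;
    with two, a cross-tabulation (e.g. study x age).  Cell counts
    always sum to ``len(rows)``.  Age columns sort ascending, with the
    adult sentinel (500) naturally last.
    """
    fields = list(fields)
    for f in fields:
        if f not in CATALOG_FIELDS:
            raise ValueError(
                f"unknown field {f!r}; choose from {', '.join(CATALOG_FIELDS)}"
            )
    if not fields:
        raise ValueError("need at least one field")
    if len(fields) == 2:
        tab = pd.crosstab(rows[fields[0]], rows[fields[1]])
        return tab.sort_index(axis=0).sort_index(axis=1)
    counted = rows.groupby(fields, sort=True).size().to_frame("n").reset_index()
    return counted


def overview_stats(rows: pd.DataFrame) -> dict:
    """Scatter data for the repository overview: (N, duration) per file.

    Returns the per-recording pairs (for a log-log scatter of the
    number of spike trains against recording duration) plus the total
    file count and total bytes on disk.
    """
    if len(rows) == 0:
        raise ValueError("no recordings to summarise")
    return {
        "n_trains": rows["n"].to_numpy(),
        "duration_s": rows["duration_s"].to_numpy(),
        "total_recordings": int(len(rows)),
        "total_bytes": int(rows["bytes"].sum()),
    }
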