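"""Persist and reload per-chromosome window profiles as CSV tables.

Canonical dialect: comma-separated, '.' decimal point, Unix line endings,
'#'-prefixed metadata lines followed by one header row.  Percentages are
rounded to 3 decimals on write (lossless in practice for window sizes up
to 10 kbp); missing values are serialized as the literal ``NA`` so that
assembly gaps are distinguishable from true 0% windows.

Layout: ``<directory>/<assembly>/<record_id>.w<window_size>.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Union

import pandas as pd

from . import __version__
from .errors import FormatError, InputError
from .window_profiler import WindowProfile, WindowRecord

PathLike = Union[str, Path]

COLUMNS = (
    "index",
    "start_bp",
    "gc_pct",
    "rep_pct",
    "gc_pct_masked",
    "gc_pct_unmasked",
    "counted_bases",
)

_PCT_DECIMALS = 3


@dataclass(frozen=True)
class ProfileTable:
    """Handle to one written per-chromosome profile CSV."""

    path: Path
    record_id: str
    record_length: int
    window_size: int
    assembly: str
    n_rows: int


def _fmt_pct(value: Optional[float]) -> str:
    if value is None:
        return "NA"
    return format(round(value, _PCT_DECIMALS), f".{_PCT_DECIMALS}f")


def write_profile(
    profile: WindowProfile,
    directory: PathLike,
    assembly: str = "assembly",
    overwrite: bool = False,
) -> ProfileTable:
    """Write one profile as ``<directory>/<assembly>/<id>.w<w>.csv``.

    Refuses to clobber an existing file unless ``overwrite`` is set.
    The file is written to a temporary name and renamed into place so a
    failed write never leaves a truncated table behind.
    """
    outdir = Path(directory) / assembly
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{profile.record_id}.w{profile.window_size}.csv"
    if path.exists() and not overwrite:
        raise InputError(f"refusing to overwrite existing profile: {path}")
    tmp = path.with_suffix(".csv.tmp")
    with open(tmp, "w", encoding="ascii", newline="\n") as out:
        out.write(f"# record_id={profile.record_id}\n")
        out.write(f"# record_length={profile.record_length}\n")
        out.write(f"# window_size={profile.window_size}\n")
        out.write(f"# assembly={assembly}\n")
        out.write(f"# tool=cytocomp {__version__}\n")
        out.write(",".join(COLUMNS) + "\n")
        for r in profile.records:
            out.write(
                f"{r.index},{r.start_bp},{_fmt_pct(r.gc_pct)},{_fmt_pct(r.rep_pct)},"
                f"{_fmt_pct(r.gc_pct_masked)},{_fmt_pct(r.gc_pct_unmasked)},"
                f"{r.counted_bases}\n"
            )
    tmp.rename(path)
    return ProfileTable(
        path=path,
        record_id=profile.record_id,
        record_length=profile.record_length,
        window_size=profile.window_size,
        assembly=assembly,
        n_rows=len(profile.records),
    )


def _parse_metadata(path: Path) -> dict:
    meta = {}
    with open(path, "r", encoding="ascii") as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_profile(path: PathLike) -> WindowProfile:
    """Reload a profile written by :func:`write_profile`.

    ``NA`` fields become missing values, never zeros.  Missing or renamed
    columns raise a :class:`FormatError` naming the expected set.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"profile file does not exist: {p}")
    meta = _parse_metadata(p)
    try:
        frame = pd.read_csv(
            p, comment="#", na_values=["NA"], keep_default_na=False
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse profile table {p}: {exc}") from exc
    if tuple(frame.columns) != COLUMNS:
        raise FormatError(
            f"profile table {p} has columns {tuple(frame.columns)}; "
            f"expected {COLUMNS}"
        )
    try:
        record_length = int(meta["record_length"])
        window_size = int(meta["window_size"])
        record_id = meta["record_id"]
    except KeyError as exc:
        raise FormatError(f"profile table {p} lacks metadata line {exc}") from exc
    import math

    expected_rows = math.ceil(record_length / window_size)
    if len(frame) != expected_rows:
        raise FormatError(
            f"profile table {p} is truncated or padded: {len(frame)} rows, "
            f"expected {expected_rows} for length {record_length} at "
            f"w={window_size}"
        )
    profile = WindowProfile(
        record_id=record_id, record_length=record_length, window_size=window_size
    )
    def opt(value) -> Optional[float]:
        return None if pd.isna(value) else float(value)

    for idx, start_bp, gc, rep, gc_m, gc_u, counted in zip(
        *(frame[c] for c in COLUMNS)
    ):
        profile.records.append(
            WindowRecord(
                index=int(idx),
                start_bp=int(start_bp),
                gc_pct=opt(gc),
                rep_pct=opt(rep),
                gc_pct_masked=opt(gc_m),
                gc_pct_unmasked=opt(gc_u),
                counted_bases=int(counted),
            )
        )
    return profile


def order_by_size(tables: Iterable[ProfileTable]) -> List[ProfileTable]:
    """Sort tables by data-row count, descending; ties by record_id.

    This is the panel order used for plotting: largest chromosome first.
    """
    return sorted(tables, key=lambda t: (-t.n_rows, t.record_id))
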