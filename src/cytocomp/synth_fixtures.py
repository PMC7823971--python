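"""Deterministic synthetic soft-masked assemblies with controlled
GC and repeat architecture.

Chromosomes are built from exact-length segments, each with a per-base
GC probability, a mask state (lowercase = repeat) and optionally a run
of N characters.  Segment boundaries sit at exact bp offsets, so the
expected window-level GC% and rep% of a generated genome are computable
in closed form — the basis of every end-to-end parameter-recovery test
in the suite.

Within the GC and AT classes, base choice is uniform (G:C and A:T each
50:50); strand asymmetry is not modelled, and no repeat consensus
sequences are used — only case/composition structure matters here.

Presets realise the repeat architectures seen along real fish and
mammal chromosomes: repeat blocks at both chromosome ends (acrocentric
pattern), clearly delineated interstitial blocks, dispersed intermingled
repeats, repeat-poor compact genomes, and a mammal-like pattern of
GC-rich unique peaks over a homogeneous AT-rich background.  Fish-like
presets give repeats a GC probability at or above the unmasked
background, reproducing repeat-driven GC homogenization; the mammal-like
preset inverts that contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ParameterError
from .fasta_io import MaskedSequenceRecord, write_assembly

PathLike = Union[str, Path]

_UPPER = np.frombuffer(b"ATGC", dtype=np.uint8)
_LOWER = np.frombuffer(b"atgc", dtype=np.uint8)


@dataclass(frozen=True)
class SegmentSpec:
    """One exact-length segment of a synthetic chromosome."""

    length: int
    gc_prob: float = 0.5
    masked: bool = False
    n_run: bool = False

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ParameterError(f"segment length must be >= 0, got {self.length}")
        if not (0.0 <= self.gc_prob <= 1.0):
            raise ParameterError(f"gc_prob must be in [0, 1], got {self.gc_prob}")


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes of (id, segments); same spec+seed -> same bytes."""

    chromosomes: Tuple[Tuple[str, Tuple[SegmentSpec, ...]], ...]
    seed: int = 0


def _render_segment(seg: SegmentSpec, rng: np.random.Generator) -> np.ndarray:
    if seg.n_run:
        return np.full(seg.length, ord("N"), dtype=np.uint8)
    is_gc = rng.random(seg.length) < seg.gc_prob
    pick = rng.integers(0, 2, size=seg.length)  # which base within the class
    idx = is_gc.astype(np.int64) * 2 + pick
    table = _LOWER if seg.masked else _UPPER
    return table[idx]


def generate_records(spec: GenomeSpec) -> List[MaskedSequenceRecord]:
    """Materialise the chromosomes of a GenomeSpec as sequence records."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for chrom_id, segments in spec.chromosomes:
        parts = [_render_segment(seg, rng) for seg in segments]
        residues = (
            np.concatenate(parts).tobytes().decode("ascii") if parts else ""
        )
        records.append(
            MaskedSequenceRecord(id=chrom_id, description=chrom_id, residues=residues)
        )
    return records


def generate_genome(spec: GenomeSpec, path: PathLike) -> Path:
    """Write the synthetic assembly as FASTA (gzip if path ends in .gz)."""
    records = generate_records(spec)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    write_assembly(records, p)
    return p


def expected_rep_fraction(
    segments: Sequence[SegmentSpec], window_size: int
) -> np.ndarray:
    """Exact expected rep% per window for a segment list.

    The mask state is deterministic, so this is not an expectation but
    the exact value profiling will recover (windows with no counted
    bases yield NaN).  Used to verify mask-structure recovery.
    """
    import math

    total = sum(s.length for s in segments)
    n_windows = math.ceil(total / window_size)
    masked = np.zeros(n_windows)
    counted = np.zeros(n_windows)
    pos = 0
    for seg in segments:
        if seg.length == 0:
            continue
        # distribute this segment's bases over the windows it spans
        start, end = pos, pos + seg.length
        w0, w1 = start // window_size, (end - 1) // window_size
        for w in range(w0, w1 + 1):
            lo = max(start, w * window_size)
            hi = min(end, (w + 1) * window_size)
            span = hi - lo
            if not seg.n_run:
                counted[w] += span
                if seg.masked:
                    masked[w] += span
        pos = end
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counted > 0, 100.0 * masked / counted, np.nan)


# ---------------------------------------------------------------------------
# Preset architectures
# ---------------------------------------------------------------------------

#: GC probability of unmasked (unique) DNA in fish-like presets.
FISH_BACKGROUND_GC = 0.41
#: Fish-like repeats are at least as GC-rich as the background
#: (the homogenization effect).
FISH_REPEAT_GC = 0.45

PRESET_NAMES = (
    "acrocentric_telomeric",
    "interstitial_blocks",
    "dispersed",
    "compact_low_repeat",
    "mammal_like",
)


def _kb(n: float) -> int:
    return int(n * 1000)


def _acrocentric(scale: float) -> Tuple[Tuple[str, Tuple[SegmentSpec, ...]], ...]:
    chroms = []
    for i, mb in enumerate([3.0, 2.5, 2.0, 1.5], start=1):
        length = _kb(mb * 1000 * scale)
        telo = _kb(100 * scale)
        body = length - 2 * telo
        chroms.append(
            (
                f"chr{i}",
                (
                    SegmentSpec(telo, FISH_REPEAT_GC, masked=True),
                    SegmentSpec(body, FISH_BACKGROUND_GC, masked=False),
                    SegmentSpec(telo, FISH_REPEAT_GC, masked=True),
                ),
            )
        )
    return tuple(chroms)


def _interstitial(scale: float) -> Tuple[Tuple[str, Tuple[SegmentSpec, ...]], ...]:
    chroms = []
    length = _kb(2000 * scale)
    block = _kb(50 * scale)
    for i in range(1, 4):
        segs: List[SegmentSpec] = []
        # blocks at 25 / 50 / 75% of the chromosome, boundaries on kb grid
        cuts = [length // 4, length // 2, 3 * length // 4]
        pos = 0
        for cut in cuts:
            segs.append(SegmentSpec(cut - pos, FISH_BACKGROUND_GC, masked=False))
            segs.append(SegmentSpec(block, FISH_REPEAT_GC, masked=True))
            pos = cut + block
        segs.append(SegmentSpec(length - pos, FISH_BACKGROUND_GC, masked=False))
        chroms.append((f"chr{i}", tuple(segs)))
    return tuple(chroms)


def _dispersed(scale: float) -> Tuple[Tuple[str, Tuple[SegmentSpec, ...]], ...]:
    chroms = []
    masked_len = _kb(5 * scale)
    unmasked_len = _kb(3 * scale)
    n_cycles = int(250 * scale) or 1
    for i in range(1, 3):
        segs = []
        for _ in range(n_cycles):
            segs.append(SegmentSpec(masked_len, FISH_REPEAT_GC, masked=True))
            segs.append(SegmentSpec(unmasked_len, FISH_BACKGROUND_GC, masked=False))
        chroms.append((f"chr{i}", tuple(segs)))
    return tuple(chroms)


def _compact(scale: float) -> Tuple[Tuple[str, Tuple[SegmentSpec, ...]], ...]:
    # sparse repeats: 20 kb of repeat per 400 kb cycle = 5% masked
    chroms = []
    cycle_unmasked = _kb(380 * scale)
    cycle_masked = _kb(20 * scale)
    for i in range(1, 4):
        segs = []
        for _ in range(4):
            segs.append(SegmentSpec(cycle_unmasked, 0.45, masked=False))
            segs.append(SegmentSpec(cycle_masked, 0.45, masked=True))
        chroms.append((f"chr{i}", tuple(segs)))
    return tuple(chroms)


def _mammal(scale: float) -> Tuple[Tuple[str, Tuple[SegmentSpec, ...]], ...]:
    # AT-rich homogeneous background (unique 0.40 / repeats 0.38) with
    # sharp unmasked GC-rich peaks (0.60) — isochore-like contrast.
    chroms = []
    background_u = SegmentSpec(_kb(180 * scale), 0.40, masked=False)
    background_m = SegmentSpec(_kb(120 * scale), 0.38, masked=True)
    peak = SegmentSpec(_kb(100 * scale), 0.60, masked=False)
    for i in range(1, 3):
        segs: List[SegmentSpec] = []
        for _ in range(5):
            segs.extend([background_u, background_m])
            segs.append(peak)
        chroms.append((f"chr{i}", tuple(segs)))
    return tuple(chroms)


_PRESETS = {
    "acrocentric_telomeric": _acrocentric,
    "interstitial_blocks": _interstitial,
    "dispersed": _dispersed,
    "compact_low_repeat": _compact,
    "mammal_like": _mammal,
}


def preset_architectures(
    name: str, seed: int = 0, scale: float = 1.0
) -> GenomeSpec:
    """A GenomeSpec realising a named repeat/GC architecture.

    ``scale`` multiplies all segment lengths (1.0 = desk-scale defaults,
    chromosomes of 1.5-3 Mbp).  Segment boundaries stay on the 1 kb grid
    for any scale that is a multiple of 0.001.
    """
    if name not in _PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    if scale <= 0:
        raise ParameterError("scale must be positive")
    return GenomeSpec(chromosomes=_PRESETS[name](scale), seed=seed)


# ---------------------------------------------------------------------------
# Designed GC-repeat correlation
# ---------------------------------------------------------------------------


def correlated_windows_genome(
    rho: float,
    n_windows: int,
    window_size: int = 1000,
    seed: int = 0,
    chrom_id: str = "chr1",
    gc_mean: float = 0.45,
    gc_sd: float = 0.04,
    rep_mean: float = 0.5,
    rep_sd: float = 0.15,
) -> MaskedSequenceRecord:
    """A chromosome whose per-window GC and repeat fractions are drawn
    with a designed Pearson correlation ``rho``.

    Each window gets a GC probability and a repeat fraction from a
    bivariate normal (clipped to valid ranges); the first
    ``round(rep_i * window_size)`` bases of window i are masked.  The
    realised window GC% carries binomial noise of about
    ``sqrt(0.25/window_size)``, which attenuates the observed correlation
    by a few percent relative to ``rho`` — well inside the recovery
    tolerance used in the tests.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ParameterError(f"rho must be in [-1, 1], got {rho}")
    if n_windows < 1 or window_size < 1:
        raise ParameterError("n_windows and window_size must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], size=n_windows
    )
    gc_prob = np.clip(gc_mean + gc_sd * z[:, 0], 0.05, 0.95)
    rep_frac = np.clip(rep_mean + rep_sd * z[:, 1], 0.0, 1.0)
    masked_per_window = np.rint(rep_frac * window_size).astype(np.int64)

    n = n_windows * window_size
    per_base_gc = np.repeat(gc_prob, window_size)
    is_gc = rng.random(n) < per_base_gc
    pick = rng.integers(0, 2, size=n)
    idx = is_gc.astype(np.int64) * 2 + pick
    pos_in_window = np.arange(n, dtype=np.int64) % window_size
    mask = pos_in_window < np.repeat(masked_per_window, window_size)
    residues = np.where(mask, _LOWER[idx], _UPPER[idx]).tobytes().decode("ascii")
    return MaskedSequenceRecord(id=chrom_id, description=chrom_id, residues=residues)
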