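"""Dual-mode chromosome profile plots with percentage color scales.

Two plot modes mirror complementary cytogenetic stainings:

* ``gc_on_y`` (default): GC% on the y axis, each window a point colored
  by its repeat fraction — red for no repeats, orange for ~50%, green
  for fully repetitive.
* ``rep_on_y`` (the "virtual CMA3" mode): rep% on the y axis, points
  colored by GC% on a green→red scale (AT-rich green, GC-rich red),
  mimicking CMA3/CDD fluorescence banding.

Panels are laid out largest chromosome first, each panel's width
proportional to chromosome length (a shared bp-per-pixel scale), so
chromosome sizes are visually comparable within one assembly.

Every render also writes a machine-readable point-list sidecar
(x, y, R, G, B per plotted window) per panel — the deterministic,
testable artifact; the raster PNG is cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .errors import ContractViolation, ParameterError
from .window_profiler import WindowProfile

PathLike = Union[str, Path]
RGB = Tuple[int, int, int]


@dataclass(frozen=True)
class ColorScale:
    """Piecewise-linear percentage -> RGB mapping with fixed anchors.

    Anchors are (percentage, (R, G, B)) with strictly increasing
    percentages; values outside the anchor span clamp to the end colors.
    """

    anchors: Tuple[Tuple[float, RGB], ...]
    orientation: str = "repeat-scale"  # or "gc-scale"

    def __post_init__(self) -> None:
        pcts = [p for p, _ in self.anchors]
        if len(pcts) < 2 or any(b <= a for a, b in zip(pcts, pcts[1:])):
            raise ParameterError(
                "color scale anchors must be >= 2 and strictly increasing"
            )


# Fig-semantics defaults: red = no repeats, orange ~ 50%, green = 100%
# repetitive.  RGB values are this package's fixed constants (overridable).
REPEAT_SCALE = ColorScale(
    anchors=((0.0, (255, 0, 0)), (50.0, (255, 165, 0)), (100.0, (0, 170, 0))),
    orientation="repeat-scale",
)

# CMA3-mimicking GC scale: AT-rich green at <=30% GC, GC-rich red at
# >=60% GC, linear between.  Bounds reflect the ~30-60% GC range typical
# of fish chromosome windows.
GC_SCALE = ColorScale(
    anchors=((30.0, (0, 170, 0)), (60.0, (255, 0, 0))),
    orientation="gc-scale",
)


def map_color(scale: ColorScale, pct: float) -> RGB:
    """Map a percentage to an RGB triple by linear interpolation.

    Exact anchor hits return the anchor color; values outside the anchor
    span clamp to the nearest end color.
    """
    if not (0.0 <= pct <= 100.0):
        raise ContractViolation(f"percentage {pct} outside [0, 100]")
    anchors = scale.anchors
    if pct <= anchors[0][0]:
        return anchors[0][1]
    if pct >= anchors[-1][0]:
        return anchors[-1][1]
    for (p0, c0), (p1, c1) in zip(anchors, anchors[1:]):
        if p0 <= pct <= p1:
            t = (pct - p0) / (p1 - p0)
            return tuple(
                int(round(a + t * (b - a))) for a, b in zip(c0, c1)
            )  # type: ignore[return-value]
    raise AssertionError("unreachable: anchors cover the clamped range")


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options for one assembly's profile plot."""

    mode: str = "gc_on_y"  # or "rep_on_y"
    window_size: int = 1000
    bp_per_pixel: Optional[float] = None  # None: derive from max_width_px
    max_width_px: int = 10_000
    color_scale: Optional[ColorScale] = None  # None: mode default
    panel_height_px: int = 300
    dpi: int = 100
    point_size: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("gc_on_y", "rep_on_y"):
            raise ParameterError(f"unknown plot mode: {self.mode!r}")
        if self.bp_per_pixel is not None and self.bp_per_pixel <= 0:
            raise ParameterError("bp_per_pixel must be positive")

    def effective_scale(self) -> ColorScale:
        if self.color_scale is not None:
            return self.color_scale
        return REPEAT_SCALE if self.mode == "gc_on_y" else GC_SCALE


def extract_points(
    profile: WindowProfile, spec: PlotSpec
) -> List[Tuple[int, float, RGB]]:
    """The plotted point list of one panel: (start_bp, y_pct, color).

    One point per window whose y measure and color measure are both
    non-missing; plotting never mutates the profile.
    """
    scale = spec.effective_scale()
    points = []
    for rec in profile.records:
        y = rec.gc_pct if spec.mode == "gc_on_y" else rec.rep_pct
        c = rec.rep_pct if spec.mode == "gc_on_y" else rec.gc_pct
        if y is None or c is None:
            continue
        points.append((rec.start_bp, y, map_color(scale, c)))
    return points


def panel_geometry(
    profiles: Sequence[WindowProfile], spec: PlotSpec
) -> List[Tuple[str, float]]:
    """Per-panel (record_id, width_px) under the spec's bp-per-pixel scale.

    All panels of one assembly share a single scale, so panel widths are
    directly proportional to chromosome lengths.  When ``bp_per_pixel``
    is unset it is derived so the longest chromosome spans
    ``max_width_px``.
    """
    if not profiles:
        raise ParameterError("panel_geometry needs at least one profile")
    longest = max(p.record_length for p in profiles)
    bp_per_px = spec.bp_per_pixel or max(longest / spec.max_width_px, 1.0)
    return [(p.record_id, p.record_length / bp_per_px) for p in profiles]


def _write_sidecar(path: Path, points: Sequence[Tuple[int, float, RGB]]) -> None:
    with open(path, "w", encoding="ascii", newline="\n") as out:
        out.write("x_bp\ty_pct\tred\tgreen\tblue\n")
        for x, y, (r, g, b) in points:
            out.write(f"{x}\t{y:.3f}\t{r}\t{g}\t{b}\n")


def render_assembly(
    profiles: Sequence[WindowProfile],
    spec: PlotSpec,
    output: PathLike,
    assembly: str = "assembly",
) -> List[Path]:
    """Render one multi-panel image for an assembly's profiles.

    Panels appear in the given order (callers order largest-first via
    :func:`cytocomp.profile_store.order_by_size` or
    :func:`order_profiles`); panel widths share one bp-per-pixel scale.
    Returns the written sidecar paths (one per panel); the PNG path is
    ``output``.

    A panel with zero plottable points is rendered empty with a warning
    on stderr, not an error.
    """
    import sys

    if not profiles:
        raise ParameterError("render_assembly needs at least one profile")
    window_sizes = {p.window_size for p in profiles}
    if len(window_sizes) != 1:
        raise ParameterError(
            f"profiles mix window sizes {sorted(window_sizes)}; one is required"
        )
    output = Path(output)
    output.parent.mkdir(parents=True, exist_ok=True)

    longest = max(p.record_length for p in profiles)
    bp_per_px = spec.bp_per_pixel or max(longest / spec.max_width_px, 1.0)

    fig_w_px = max(int(round(longest / bp_per_px)), 1)
    # Raster dimensions are capped for practicality; the sidecar files
    # are the exact artifact.
    fig_w_in = min(fig_w_px, 20_000) / spec.dpi
    fig_h_in = (spec.panel_height_px * len(profiles)) / spec.dpi
    fig = plt.figure(figsize=(max(fig_w_in, 1.0), max(fig_h_in, 1.0)))

    # Each panel's drawn width is proportional to its chromosome length
    # (one shared bp-per-pixel scale for the whole assembly).
    left, avail_w = 0.05, 0.90
    n_panels = len(profiles)
    panel_h = 0.9 / n_panels
    sidecars: List[Path] = []
    y_label = "GC %" if spec.mode == "gc_on_y" else "rep %"
    last_ax = None
    for i, profile in enumerate(profiles):
        width_frac = avail_w * profile.record_length / longest
        bottom = 0.05 + (n_panels - 1 - i) * panel_h
        ax = fig.add_axes([left, bottom + 0.15 * panel_h, max(width_frac, 1e-3),
                           panel_h * 0.7])
        last_ax = ax
        points = extract_points(profile, spec)
        sidecar = output.parent / (
            f"{profile.record_id}.w{profile.window_size}.{spec.mode}.points.tsv"
        )
        _write_sidecar(sidecar, points)
        sidecars.append(sidecar)
        if points:
            xs = np.array([p[0] for p in points])
            ys = np.array([p[1] for p in points])
            cols = np.array([p[2] for p in points], dtype=float) / 255.0
            ax.scatter(xs, ys, c=cols, s=spec.point_size, marker=".", linewidths=0)
        else:
            print(
                f"cytocomp: warning: no plottable windows in {profile.record_id}",
                file=sys.stderr,
            )
        ax.set_xlim(0, profile.record_length)
        ax.set_ylim(0, 100)
        ax.set_ylabel(y_label, fontsize=7)
        ax.set_title(profile.record_id, loc="left", fontsize=8)
        ax.tick_params(labelsize=6)
    if last_ax is not None:
        last_ax.set_xlabel("position (bp)", fontsize=7)
    _add_scale_legend(fig, spec)
    fig.suptitle(assembly)
    fig.savefig(output, dpi=spec.dpi)
    plt.close(fig)
    return sidecars


def render_swapped(
    profiles: Sequence[WindowProfile],
    spec: PlotSpec,
    output: PathLike,
    assembly: str = "assembly",
) -> List[Path]:
    """Render the virtual-CMA3 mode: rep% on y, points colored by GC%."""
    return render_assembly(
        profiles, replace(spec, mode="rep_on_y"), output, assembly
    )


def _add_scale_legend(fig, spec: PlotSpec) -> None:
    """A thin horizontal color bar showing the active percentage scale."""
    scale = spec.effective_scale()
    ax = fig.add_axes([0.35, 0.005, 0.3, 0.01])
    pcts = np.linspace(0, 100, 101)
    colors = np.array([map_color(scale, p) for p in pcts], dtype=float) / 255.0
    ax.imshow(colors[np.newaxis, :, :], aspect="auto", extent=(0, 100, 0, 1))
    ax.set_yticks([])
    ax.set_xticks([0, 50, 100])
    label = "rep %" if scale.orientation == "repeat-scale" else "GC %"
    ax.set_xlabel(label, fontsize=6)
    ax.tick_params(labelsize=6)


def order_profiles(profiles: Sequence[WindowProfile]) -> List[WindowProfile]:
    """Largest chromosome first (by window count, ties by record id)."""
    return sorted(profiles, key=lambda p: (-len(p.records), p.record_id))
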