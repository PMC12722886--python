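"""Chest-wall volumetry from a grid of trunk-surface markers.

Breathing volumes are estimated optoelectronic-plethysmography style: markers
arranged in horizontal rings around the trunk (default 4 rings x 8 columns =
32 markers) define a closed triangulated surface whose enclosed volume is
computed per frame by the divergence theorem (signed tetrahedra to the mesh
centroid).  Rows are split at two boundary rings into three compartments —
upper thoracic, lower thoracic and abdominal — and each compartment band is
closed by centroid-fan caps at its boundary rings.  Because adjacent bands
share their boundary ring and the two facing caps cancel in the signed sum,
the total volume is *defined* as the sum of the three compartment volumes,
making compartment additivity exact by construction.

Volumes are returned in litres (1 L = 1e6 mm^3).  The "respiratory volume"
used downstream is the total-volume signal relative to the trial's first
valid frame; absolute trunk volume is also carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mocap_io import MarkerTrajectorySet

__all__ = [
    "ChestWallGrid",
    "VolumeSeries",
    "build_grid",
    "canonical_layout",
    "frame_volume",
    "volume_series",
]

COMPARTMENTS = ("upper_thoracic", "lower_thoracic", "abdominal")

MM3_PER_L = 1e6

#: Tracking gaps of at most this many samples are filled by cubic
#: interpolation before volumetry; longer gaps invalidate the frame.
MAX_GAP_SAMPLES = 10


class GridError(ValueError):
    """Raised for an inconsistent chest-wall grid layout."""


@dataclass(frozen=True)
class ChestWallGrid:
    """Validated rectangular marker layout on the trunk surface.

    ``layout`` maps each marker label to ``(row, col)``; rows are ordered
    cranial (0) to caudal (R-1), columns circumferentially as a closed loop
    (counterclockwise viewed from above, starting at the sternal midline).
    ``compartment_bounds = (r1, r2)`` split the rows into the bands
    rows[0..r1], rows[r1..r2], rows[r2..R-1]; boundary rings are shared.
    """

    layout: dict[str, tuple[int, int]]
    rows: int
    cols: int
    compartment_bounds: tuple[int, int] | None

    @property
    def labels(self) -> list[str]:
        """Labels in row-major grid order."""
        inv = {rc: lab for lab, rc in self.layout.items()}
        return [inv[(r, c)] for r in range(self.rows) for c in range(self.cols)]

    def band_rows(self) -> list[tuple[int, int]]:
        """Row spans of the volume bands; a single span if no split is set."""
        if self.compartment_bounds is None:
            return [(0, self.rows - 1)]
        r1, r2 = self.compartment_bounds
        return [(0, r1), (r1, r2), (r2, self.rows - 1)]


def canonical_layout(rows: int = 4, cols: int = 8, prefix: str = "CW") -> dict:
    """Default grid spec: labels ``{prefix}_{row}_{col}``, bands split at the
    xiphoid and 10th-rib rings (rows 1 and 2 of the 4-ring model)."""
    return {
        "rows": rows,
        "cols": cols,
        "cells": {f"{prefix}_{r}_{c}": [r, c] for r in range(rows) for c in range(cols)},
        "compartment_rows": [max(1, rows // 4), max(2, rows // 2)],
    }


def build_grid(labels: list[str], layout_spec: dict) -> ChestWallGrid:
    """Validate a layout spec against the available marker labels.

    ``layout_spec`` carries ``rows``, ``cols``, ``cells`` (label -> [row, col])
    and ``compartment_rows`` ([r1, r2]).  Every grid cell must be occupied by
    exactly one available label; errors name the offending cell or label.
    """
    rows, cols = int(layout_spec["rows"]), int(layout_spec["cols"])
    cells = layout_spec["cells"]
    comp_rows = layout_spec.get("compartment_rows", (1, 2) if rows >= 4 else None)
    bounds: tuple[int, int] | None
    if comp_rows is None:
        bounds = None
    else:
        r1, r2 = (int(v) for v in comp_rows)
        if not (0 < r1 < r2 < rows):
            raise GridError(
                f"compartment rows ({r1}, {r2}) must satisfy 0 < r1 < r2 < {rows}"
            )
        bounds = (r1, r2)
    available = set(labels)
    occupancy: dict[tuple[int, int], str] = {}
    layout: dict[str, tuple[int, int]] = {}
    for label, (r, c) in cells.items():
        if label not in available:
            raise GridError(f"layout names marker {label!r} absent from the trial")
        rc = (int(r), int(c))
        if not (0 <= rc[0] < rows and 0 <= rc[1] < cols):
            raise GridError(f"marker {label!r} assigned outside the {rows}x{cols} grid: {rc}")
        if rc in occupancy:
            raise GridError(f"cell {rc} assigned to both {occupancy[rc]!r} and {label!r}")
        occupancy[rc] = label
        layout[label] = rc
    for r in range(rows):
        for c in range(cols):
            if (r, c) not in occupancy:
                raise GridError(f"grid cell (row {r}, col {c}) has no marker")
    return ChestWallGrid(layout=layout, rows=rows, cols=cols, compartment_bounds=bounds)


@dataclass
class VolumeSeries:
    """Total and per-compartment chest-wall volume time series (litres)."""

    time: np.ndarray
    total: np.ndarray
    compartments: dict[str, np.ndarray]
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        self.compartments = {k: np.asarray(v, dtype=float) for k, v in self.compartments.items()}
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.total)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    def respiratory_signal(self) -> np.ndarray:
        """Total volume relative to the first valid frame (litres)."""
        first = np.flatnonzero(self.valid_mask)
        if first.size == 0:
            raise ValueError("no valid frames")
        return self.total - self.total[first[0]]


# ---------------------------------------------------------------------------
# mesh volume
# ---------------------------------------------------------------------------


def _signed_band_volume(rings: np.ndarray) -> float:
    """Signed enclosed volume (mm^3) of the band spanned by ``rings``.

    ``rings`` has shape (n_rings, cols, 3), ordered top to bottom.  The
    lateral surface triangulates each quad cell; the top and bottom rings are
    capped by centroid fans.  The sign is positive for counterclockwise rings
    (viewed from above) stacked top-down.
    """
    n_rings, cols, _ = rings.shape
    centroid = rings.reshape(-1, 3).mean(axis=0)
    p = rings - centroid  # translate for numerical stability
    tris = []
    for r in range(n_rings - 1):
        a, b = p[r], p[r + 1]
        a2, b2 = np.roll(a, -1, axis=0), np.roll(b, -1, axis=0)
        # quad (a, a2, b2, b) split along one diagonal, outward winding
        tris.append(np.stack([a, b, b2], axis=1))
        tris.append(np.stack([a, b2, a2], axis=1))
    for ring, top in ((p[0], True), (p[-1], False)):
        c = ring.mean(axis=0)
        nxt = np.roll(ring, -1, axis=0)
        if top:
            tris.append(np.stack([np.broadcast_to(c, ring.shape), ring, nxt], axis=1))
        else:
            tris.append(np.stack([np.broadcast_to(c, ring.shape), nxt, ring], axis=1))
    t = np.concatenate(tris, axis=0)
    return float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2]))) / 6.0


def _ring_areas(rings: np.ndarray) -> np.ndarray:
    """Signed horizontal-projection (shoelace) area of each ring."""
    x, y = rings[..., 0], rings[..., 1]
    x2, y2 = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
    return 0.5 * np.sum(x * y2 - x2 * y, axis=1)


def frame_volume(
    frame: np.ndarray | dict[str, np.ndarray], grid: ChestWallGrid
) -> tuple[float, dict[str, float]]:
    """Total and per-compartment volume (L) of one frame of chest markers.

    ``frame`` is either an array of grid markers in row-major grid order with
    shape ``(rows*cols, 3)`` (mm) or a mapping label -> (3,) position.
    Returns ``(nan, {...nan})`` for a degenerate mesh (NaN positions, or
    self-intersecting rings detected via inconsistent signed ring areas)
    rather than raising — the frame is meant to be flagged invalid upstream.
    """
    if isinstance(frame, dict):
        pts = np.array([frame[l] for l in grid.labels], dtype=float)
    else:
        pts = np.asarray(frame, dtype=float)
    if pts.shape != (grid.rows * grid.cols, 3):
        raise ValueError(f"expected {(grid.rows * grid.cols, 3)} positions, got {pts.shape}")
    band_names = COMPARTMENTS if grid.compartment_bounds is not None else ("band_0",)
    nanres = (float("nan"), {k: float("nan") for k in band_names})
    if not np.all(np.isfinite(pts)):
        return nanres
    rings = pts.reshape(grid.rows, grid.cols, 3)
    areas = _ring_areas(rings)
    if np.any(areas == 0) or not (np.all(areas > 0) or np.all(areas < 0)):
        return nanres
    signed = [
        _signed_band_volume(rings[r0 : r1 + 1]) for r0, r1 in grid.band_rows()
    ]
    if signed[0] < 0:  # clockwise layout: flip once, consistently
        signed = [-v for v in signed]
    if min(signed) <= 0:
        return nanres
    vols = {k: v / MM3_PER_L for k, v in zip(band_names, signed)}
    return sum(vols.values()), vols


# ---------------------------------------------------------------------------
# per-trial series
# ---------------------------------------------------------------------------


def _fill_short_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Cubic interpolation across NaN runs of at most ``max_gap`` samples."""
    from scipy.interpolate import CubicSpline

    out = x.copy()
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = out[:, j]
        bad = ~np.isfinite(col)
        if not bad.any() or bad.all():
            continue
        good_idx = np.flatnonzero(~bad)
        if good_idx.size < 4:
            continue
        spline = CubicSpline(good_idx, col[good_idx])
        # locate NaN runs
        edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
        for start, end in zip(edges[::2], edges[1::2]):
            interior = start > 0 and end < n  # never extrapolate past the ends
            if end - start <= max_gap and interior:
                col[start:end] = spline(np.arange(start, end))
    return out


def volume_series(
    markers: MarkerTrajectorySet,
    grid: ChestWallGrid,
    min_coverage: float = 0.8,
    max_gap_samples: int = MAX_GAP_SAMPLES,
) -> VolumeSeries:
    """Per-frame chest-wall volumes for a whole trial.

    Gaps up to ``max_gap_samples`` are filled by cubic interpolation before
    meshing; frames still missing a grid marker (or with a degenerate mesh)
    are flagged invalid and excluded from breath analysis downstream.  If
    fewer than ``min_coverage`` of frames are valid the trial is rejected
    with a per-marker coverage report.
    """
    chest = markers.subset(grid.labels)
    pos = chest.positions.reshape(chest.n_frames, -1)
    filled = _fill_short_gaps(pos, max_gap_samples).reshape(chest.n_frames, len(grid.labels), 3)

    band_names = COMPARTMENTS if grid.compartment_bounds is not None else ("band_0",)
    totals = np.empty(chest.n_frames)
    comps = {k: np.empty(chest.n_frames) for k in band_names}
    for i in range(chest.n_frames):
        total, by_comp = frame_volume(filled[i], grid)
        totals[i] = total
        for k in band_names:
            comps[k][i] = by_comp[k]
    valid = np.isfinite(totals)
    coverage = valid.mean() if valid.size else 0.0
    if coverage < min_coverage:
        per_marker = {
            lab: float(np.isfinite(filled[:, i]).all(axis=1).mean())
            for i, lab in enumerate(grid.labels)
        }
        worst = sorted(per_marker.items(), key=lambda kv: kv[1])[:5]
        raise ValueError(
            f"only {coverage:.0%} of frames usable for volumetry "
            f"(need {min_coverage:.0%}); worst markers: "
            + ", ".join(f"{lab} {cov:.0%}" for lab, cov in worst)
        )
    return VolumeSeries(time=chest.time, total=totals, compartments=comps, valid_mask=valid)
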