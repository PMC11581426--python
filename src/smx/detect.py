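"""Diffraction-limited spot detection and trace extraction.

``find_spots`` reproduces ImageJ "Find Maxima" semantics: a local maximum
is reported when its height above the highest saddle connecting it to any
higher maximum (its topographic prominence) strictly exceeds the prominence
parameter.  Connectivity is 8-way; plateaus and equal maxima are broken by
row-major scan order, first pixel wins.

``extract_traces`` then measures each detected spot in every frame of the
stack inside a small square aperture (3x3 mean by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpotList", "IntensityTrace", "find_spots", "extract_traces"]


@dataclass
class SpotList:
    """Detected spots: integer (x, y) pixel coordinates, intensity-sorted."""

    coords: np.ndarray            # (N, 2) int, columns (x, y)
    channel: str = ""
    prominence: float = 0.0
    peak_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self):
        return len(self.coords)

    def __iter__(self):
        return iter(self.coords)


@dataclass
class IntensityTrace:
    """Per-spot intensity versus frame."""

    values: np.ndarray
    x_px: int = 0
    y_px: int = 0
    aperture_radius: int = 1
    clipped: bool = False

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self):
        return len(self.values)


def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        parent[i], i = root, parent[i]
    return root


def find_spots(image, prominence: float, channel: str = "") -> SpotList:
    """Detect local maxima with topographic prominence > ``prominence``.

    Pixels are processed in descending intensity (ties by row-major scan
    order) with a union-find: each pixel either starts a new peak or joins
    a neighboring component; when two components meet, the meeting pixel is
    the saddle and the lower peak's prominence is fixed there.  Peaks never
    overtaken keep ``peak - image_min`` as their prominence (so a constant
    image yields no spots).

    Returns spots sorted by descending peak intensity; coordinates are
    (x, y) = (column, row).
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("find_spots expects a 2-D image")
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    h, w = img.shape
    flat = img.ravel()
    order = np.argsort(-flat, kind="stable")  # desc intensity, row-major ties

    parent = np.arange(flat.size)
    peak_of = np.arange(flat.size)        # per-root: flat index of its peak
    visited = np.zeros(flat.size, bool)
    prominences = {}                       # peak flat index -> prominence

    rank = np.empty(flat.size, np.int64)  # processing order, for tie-breaks
    rank[order] = np.arange(flat.size)

    neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for p in order:
        r, c = divmod(int(p), w)
        roots = []
        for dr, dc in neigh:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                q = rr * w + cc
                if visited[q]:
                    root = _find(parent, q)
                    if root not in roots:
                        roots.append(root)
        visited[p] = True
        if not roots:
            continue  # p is its own root / new peak
        # winner: component whose peak is highest; ties by earliest peak
        roots.sort(key=lambda rt: (-flat[peak_of[rt]], rank[peak_of[rt]]))
        win = roots[0]
        for lose in roots[1:]:
            prominences[int(peak_of[lose])] = float(flat[peak_of[lose]] - flat[p])
            parent[lose] = win
        parent[p] = win

    # peaks never merged into a higher component
    seen_roots = set()
    for p in order:
        root = _find(parent, int(p))
        if root not in seen_roots:
            seen_roots.add(root)
    imin = float(flat.min())
    for root in seen_roots:
        pk = int(peak_of[root])
        prominences.setdefault(pk, float(flat[pk] - imin))

    keep = [pk for pk, prom in prominences.items() if prom > prominence]
    keep.sort(key=lambda pk: (-flat[pk], rank[pk]))
    coords = np.array([[pk % w, pk // w] for pk in keep], int).reshape(-1, 2)
    return SpotList(coords=coords, channel=channel, prominence=float(prominence),
                    peak_values=flat[keep] if keep else np.empty(0))


def extract_traces(stack, spots, aperture_radius: int = 1, stat: str = "mean",
                   allow_clip: bool = True):
    """Measure each spot in every frame of the stack.

    The trace value at frame *t* is the mean (or sum) of the pixels within
    the square aperture of half-width ``aperture_radius`` centered on the
    spot.  Spots whose aperture crosses the image edge are measured over
    in-bounds pixels only and flagged ``clipped`` (or rejected when
    ``allow_clip=False``).
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, H, W) array")
    coords = spots.coords if isinstance(spots, SpotList) else np.atleast_2d(np.asarray(spots, int))
    _, h, w = stack.shape
    reducer = {"mean": np.mean, "sum": np.sum}[stat]
    traces = []
    for x, y in coords:
        x0, x1 = x - aperture_radius, x + aperture_radius + 1
        y0, y1 = y - aperture_radius, y + aperture_radius + 1
        clipped = x0 < 0 or y0 < 0 or x1 > w or y1 > h
        if clipped and not allow_clip:
            raise ValueError(f"spot ({x},{y}) aperture crosses image bounds")
        win = stack[:, max(y0, 0):min(y1, h), max(x0, 0):min(x1, w)]
        traces.append(IntensityTrace(values=reducer(win, axis=(1, 2)),
                                     x_px=int(x), y_px=int(y),
                                     aperture_radius=aperture_radius,
                                     clipped=bool(clipped)))
    return traces
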