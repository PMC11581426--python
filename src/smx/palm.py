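"""SMLM localization processing: ingest, blink consolidation, clustering,
stoichiometry, pairwise distances, and FRC resolution.

Localization tables are pandas DataFrames with columns
``x_nm, y_nm, frame, precision_nm`` (the output of standard SMLM fitting
software, one row per blink).  Blinks are consolidated into fluorophore
objects with a greedy, precision-sorted merge; objects closer than the
linkage radius (160 nm by default) are grouped into supercomplex clusters
by single-linkage connected components, and per-cluster object counts give
the stoichiometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Cluster",
    "FRCResult",
    "ingest_localizations",
    "consolidate_blinks",
    "cluster_objects",
    "stoichiometry_fractions",
    "stoichiometry_summary",
    "dimer_distances",
    "frc_resolution",
]

REQUIRED_COLUMNS = ("x_nm", "y_nm", "frame", "precision_nm")


def ingest_localizations(table: pd.DataFrame, precision_max_nm: float = 40.0,
                         pixel_size_nm: float | None = None) -> pd.DataFrame:
    """Validate and filter a localization table.

    Rows with precision above ``precision_max_nm`` are dropped (the usual
    quality cut applied when fitting PALM data); drop counts are reported
    via a warning.  Tables in pixel units (columns ``x_px, y_px``) are
    converted to nm with ``pixel_size_nm``.
    """
    df = table.copy()
    if pixel_size_nm is not None and "x_px" in df.columns:
        df["x_nm"] = df["x_px"] * pixel_size_nm
        df["y_nm"] = df["y_px"] * pixel_size_nm
        df = df.drop(columns=["x_px", "y_px"])
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"localization table missing required column {col!r}")
    if len(df) == 0:
        warnings.warn("empty localization table")
        return df.reset_index(drop=True)
    if (df["precision_nm"] <= 0).any():
        raise ValueError("localization precision must be > 0")
    bad = ~np.isfinite(df[["x_nm", "y_nm"]]).all(axis=1)
    if bad.any():
        raise ValueError("non-finite coordinates in localization table")
    n0 = len(df)
    df = df[df["precision_nm"] <= precision_max_nm]
    if len(df) < n0:
        warnings.warn(f"dropped {n0 - len(df)} localization(s) with "
                      f"precision > {precision_max_nm} nm")
    return df.reset_index(drop=True)


def consolidate_blinks(locs: pd.DataFrame, radius_rule: str = "seed",
                       seed_order: str = "best_first",
                       radius_factor: float = 1.0) -> pd.DataFrame:
    """Merge repeated blinks of one fluorophore into single objects.

    Localizations are sorted by precision (most precise first by default;
    ties broken by x, then y, then frame so the result is independent of
    input row order).  A greedy pass claims each unclaimed localization as
    a seed and absorbs every unclaimed localization within the seed's
    precision radius (``radius_rule="symmetric_max"`` uses the larger of
    the two precisions instead).  Object position is the inverse-variance
    weighted mean of its members and object precision the propagated error
    of that mean; ``n_merged`` counts members.

    ``radius_factor`` scales the merge radius.  At the literal factor of 1
    the radius equals one localization precision, yet the distance between
    two blinks of the same fluorophore is Rayleigh with mode ``precision *
    sqrt(2)``, so most repeat blinks fall outside it; a factor of 2-3
    captures the bulk of repeat blinks at the cost of merging genuinely
    distinct molecules closer than that radius.

    The greedy pass is repeated until no further merges occur, so the
    operation is idempotent by construction; inverse-variance weights make
    repeated merging associative (a merged object carries the combined
    weight of its members), hence the fixpoint equals a direct weighted
    mean over the original localizations.

    Returns a DataFrame ``x_nm, y_nm, precision_nm, n_merged`` whose
    ``n_merged`` sums to the input row count.
    """
    if len(locs) == 0:
        return pd.DataFrame(columns=["x_nm", "y_nm", "precision_nm", "n_merged"])
    df = locs.copy()
    if "n_merged" not in df.columns:
        df = df.assign(n_merged=1)
    ascending = seed_order == "best_first"
    while True:
        df = df.sort_values(["precision_nm", "x_nm", "y_nm"],
                            ascending=ascending, kind="stable").reset_index(drop=True)
        xy = df[["x_nm", "y_nm"]].to_numpy(float)
        prec = df["precision_nm"].to_numpy(float)
        nmg = df["n_merged"].to_numpy(int)
        tree = cKDTree(xy)
        claimed = np.zeros(len(df), bool)
        rows = []
        for i in range(len(df)):
            if claimed[i]:
                continue
            r = radius_factor * prec[i]
            members = [j for j in tree.query_ball_point(xy[i], r)
                       if not claimed[j]]
            if radius_rule == "symmetric_max":
                extra = [j for j in tree.query_ball_point(
                            xy[i], radius_factor * prec.max())
                         if not claimed[j]
                         and np.hypot(*(xy[j] - xy[i]))
                         <= radius_factor * max(prec[i], prec[j])]
                members = sorted(set(members) | set(extra))
            claimed[members] = True
            wsum = np.sum(1.0 / prec[members] ** 2)
            pos = np.sum(xy[members] / prec[members, None] ** 2, axis=0) / wsum
            rows.append((pos[0], pos[1], float(1.0 / np.sqrt(wsum)),
                         int(nmg[members].sum())))
        out = pd.DataFrame(rows, columns=["x_nm", "y_nm", "precision_nm",
                                          "n_merged"])
        if len(out) == len(df):
            return out
        df = out


@dataclass
class Cluster:
    """A supercomplex: objects linked at less than the clustering radius."""

    member_indices: np.ndarray
    coords: np.ndarray            # (k, 2) nm
    precisions: np.ndarray

    @property
    def stoichiometry(self) -> int:
        return len(self.member_indices)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def mean_precision(self) -> float:
        return float(self.precisions.mean())


def cluster_objects(objects: pd.DataFrame, radius_nm: float = 160.0,
                    linkage: str = "single") -> list[Cluster]:
    """Group objects into clusters at pairwise distance < ``radius_nm``.

    Single linkage (default) takes connected components of the graph whose
    edges join object pairs strictly closer than the radius, so chains are
    transitively grouped; objects at exactly the radius stay separate.
    ``linkage="complete"`` instead requires every within-cluster pair to be
    closer than the radius (scipy complete-linkage dendrogram cut), for
    sensitivity analysis.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be > 0")
    xy = objects[["x_nm", "y_nm"]].to_numpy(float)
    prec = (objects["precision_nm"].to_numpy(float)
            if "precision_nm" in objects.columns else np.zeros(len(objects)))
    n = len(xy)
    if n == 0:
        return []
    if linkage == "complete" and n > 1:
        from scipy.cluster.hierarchy import fcluster, linkage as _lk
        lab = fcluster(_lk(xy, method="complete"),
                       t=np.nextafter(radius_nm, 0), criterion="distance")
    else:
        parent = np.arange(n)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        tree = cKDTree(xy)
        for i, j in tree.query_pairs(r=radius_nm):
            if np.hypot(*(xy[i] - xy[j])) < radius_nm:  # strict inequality
                parent[find(i)] = find(j)
        lab = np.array([find(i) for i in range(n)])
    clusters = []
    for lbl in pd.unique(lab):
        idx = np.flatnonzero(lab == lbl)
        clusters.append(Cluster(member_indices=idx, coords=xy[idx],
                                precisions=prec[idx]))
    return clusters


def stoichiometry_fractions(clusters) -> tuple[float, float, float]:
    """Fractions of clusters with 1, 2, and >2 member objects."""
    sizes = np.array([c.stoichiometry if hasattr(c, "stoichiometry") else int(c)
                      for c in clusters])
    if len(sizes) == 0:
        raise ValueError("no clusters")
    n = len(sizes)
    return (float((sizes == 1).sum() / n), float((sizes == 2).sum() / n),
            float((sizes > 2).sum() / n))


def stoichiometry_summary(replicates) -> pd.DataFrame:
    """Mean +/- SD of (monomer, dimer, multimer) fractions over replicates.

    ``replicates`` is an iterable of cluster lists, one per biological
    repeat.  Returns a DataFrame indexed by class with columns
    ``mean, sd`` (SD is NaN for a single replicate).
    """
    fracs = np.array([stoichiometry_fractions(rep) for rep in replicates])
    if fracs.size == 0:
        raise ValueError("no replicates")
    sd = fracs.std(axis=0, ddof=1) if len(fracs) > 1 else np.full(3, np.nan)
    return pd.DataFrame({"mean": fracs.mean(axis=0), "sd": sd},
                        index=["1", "2", ">2"])


def dimer_distances(clusters) -> np.ndarray:
    """Euclidean member separation (nm) of each two-object cluster."""
    out = []
    for c in clusters:
        if c.stoichiometry != 2:
            raise ValueError("dimer_distances requires clusters of stoichiometry 2")
        out.append(float(np.hypot(*(c.coords[0] - c.coords[1]))))
    return np.asarray(out)


@dataclass
class FRCResult:
    """Fourier ring correlation curve and threshold-crossing resolution."""

    spatial_freq: np.ndarray      # 1/nm, ring centers
    frc: np.ndarray
    resolution_nm: float          # NaN when the curve never validly crosses
    status: str                   # "ok" | "no_crossing" | "no_correlation"
    threshold: float


def frc_resolution(locs: pd.DataFrame, render_pixel_nm: float = 10.0,
                   threshold: float = 1.0 / 7.0, split: str = "odd_even") -> FRCResult:
    """Estimate image resolution by Fourier ring correlation.

    The localizations are split into two statistically independent halves
    (odd/even frames by default, ``split="random_half"`` for a random
    split), each half is rendered as a 2-D histogram at
    ``render_pixel_nm``, and the FRC curve is the ring-wise normalized
    cross-correlation of the two Fourier transforms.  The resolution is
    the inverse of the first spatial frequency where the curve drops below
    the fixed 1/7 threshold.

    When the curve never drops below the threshold the resolution is
    finer than the rendering Nyquist limit (``status="no_crossing"``);
    when it is already below threshold at the lowest rings the halves are
    uncorrelated and no resolution is defined
    (``status="no_correlation"``).  Both report ``resolution_nm = NaN``.
    """
    if len(locs) < 4:
        raise ValueError("too few localizations for FRC")
    frames = locs["frame"].to_numpy()
    if split == "odd_even":
        mask = (frames % 2) == 0
    elif split == "random_half":
        rng = np.random.default_rng(0)
        mask = rng.random(len(locs)) < 0.5
    else:
        raise ValueError("split must be 'odd_even' or 'random_half'")
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each half must contain at least 2 localizations")

    xy = locs[["x_nm", "y_nm"]].to_numpy(float)
    lo = xy.min(axis=0)
    span = float(max(xy.max(axis=0) - lo)) + render_pixel_nm
    npix = int(np.ceil(span / render_pixel_nm))
    npix += npix % 2  # even size
    edges = np.arange(npix + 1) * render_pixel_nm

    def render(sub):
        h, _, _ = np.histogram2d(sub[:, 1] - lo[1], sub[:, 0] - lo[0],
                                 bins=[edges, edges])
        return h

    f1 = np.fft.fftshift(np.fft.fft2(render(xy[mask])))
    f2 = np.fft.fftshift(np.fft.fft2(render(xy[~mask])))

    c = npix // 2
    yy, xx = np.indices((npix, npix))
    rad = np.round(np.hypot(yy - c, xx - c)).astype(int)
    nrings = npix // 2
    num = np.bincount(rad.ravel(), weights=np.real(f1 * np.conj(f2)).ravel(),
                      minlength=nrings + 1)[1:nrings + 1]
    p1 = np.bincount(rad.ravel(), weights=(np.abs(f1) ** 2).ravel(),
                     minlength=nrings + 1)[1:nrings + 1]
    p2 = np.bincount(rad.ravel(), weights=(np.abs(f2) ** 2).ravel(),
                     minlength=nrings + 1)[1:nrings + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = num / np.sqrt(p1 * p2)
    freq = np.arange(1, nrings + 1) / (npix * render_pixel_nm)

    # the two halves must actually correlate at low frequency; independent
    # noise fields fluctuate about zero from the first rings
    lead = frc[:4][np.isfinite(frc[:4])]
    if lead.size == 0 or lead.mean() < 0.5:
        return FRCResult(freq, frc, float("nan"), "no_correlation", threshold)
    # moving-average smoothing tames per-ring noise before the crossing search
    kernel = np.ones(3) / 3.0
    sm = np.convolve(np.nan_to_num(frc, nan=0.0), kernel, mode="same")
    sm[0], sm[-1] = frc[0], frc[-1]
    below = np.isfinite(sm) & (sm < threshold)
    if not below.any():
        return FRCResult(freq, frc, float("nan"), "no_crossing", threshold)
    first = int(np.flatnonzero(below)[0])
    if first == 0:
        return FRCResult(freq, frc, float("nan"), "no_correlation", threshold)
    # linear interpolation of the crossing between ring first-1 and first
    f0, f1v = sm[first - 1], sm[first]
    x0, x1 = freq[first - 1], freq[first]
    fc = x0 + (f0 - threshold) / (f0 - f1v) * (x1 - x0)
    return FRCResult(freq, frc, float(1.0 / fc), "ok", threshold)
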