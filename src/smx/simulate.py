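"""Ground-truth-annotated synthetic single-molecule data.

Every generator in this module is a pure function of its parameters and a
seed, and returns both the observable (trace, localization table, spot
lists, image) and the ground truth needed to score a downstream analysis:
planted bleach steps, fluorophore positions and blink assignments, planted
dimer separations, and planted two-channel coincidences.

The defaults emulate the measurement conditions of single-molecule TIRF /
PALM imaging of protein supercomplexes adsorbed to a coverslip:

* photobleaching movies of 25 s at 50 ms exposure (500 frames), single
  fluorophore step heights of ~1000 camera counts on a small residual
  background;
* localization precision drawn from a truncated normal with mean 21.8 nm
  and SD 6.5 nm, truncated to [5, 40] nm (40 nm being the usual precision
  cut applied at ingest);
* a camera pixel of 103 nm;
* supercomplex stoichiometry weights of (0.63, 0.24, 0.13) over 1 / 2 / >2
  fluorophores for bleaching experiments and (0.76, 0.12, 0.12) for
  heterozygously tagged PALM experiments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_PIXEL_NM",
    "EGFP_STOICHIOMETRY_WEIGHTS",
    "MEOS2_STOICHIOMETRY_WEIGHTS",
    "TraceGroundTruth",
    "FieldGroundTruth",
    "TruncatedNormalPrecision",
    "generate_bleach_trace",
    "generate_trace_set",
    "generate_localization_field",
    "generate_dimer_field",
    "generate_two_channel_spots",
    "render_image",
    "render_stack",
    "generate_region_cohort",
    "DEFAULT_REGION_MIXED_MEANS",
]

#: camera pixel pitch, nm
DEFAULT_PIXEL_NM = 103.0

#: stoichiometry weights over (1, 2, >2) fluorophores per supercomplex,
#: matching the homozygously eGFP-tagged bleaching experiments
EGFP_STOICHIOMETRY_WEIGHTS = (0.63, 0.24, 0.13)

#: stoichiometry weights for heterozygously mEos2-tagged PALM experiments
MEOS2_STOICHIOMETRY_WEIGHTS = (0.76, 0.12, 0.12)


def _child_rng(seed, *key):
    """Deterministic child generator for a (seed, key) pair.

    Keys are folded in with a process-independent hash so the same seed
    reproduces bitwise across interpreter sessions.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    ss = np.random.SeedSequence(
        [int(seed)] + [zlib.crc32(str(k).encode()) for k in key])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# photobleaching traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceGroundTruth:
    """Planted parameters of one photobleaching trace.

    ``step_frames[i]`` is the first frame at which fluorophore *i* is dark;
    the trace value at frame ``t`` is ``baseline`` plus the heights of all
    fluorophores with ``step_frames > t``, plus Gaussian camera noise.
    """

    n_steps: int
    step_frames: tuple = ()
    step_heights: tuple = ()
    baseline: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if len(self.step_frames) != self.n_steps or len(self.step_heights) != self.n_steps:
            raise ValueError("step_frames and step_heights must have length n_steps")
        frames = np.asarray(self.step_frames)
        if self.n_steps and (np.diff(frames) <= 0).any():
            raise ValueError("step_frames must be strictly increasing")
        if self.n_steps and frames.min() < 0:
            raise ValueError("step_frames must be >= 0")
        if any(h <= 0 for h in self.step_heights):
            raise ValueError("step_heights must be > 0")


def generate_bleach_trace(truth: TraceGroundTruth, n_frames: int, seed=0) -> np.ndarray:
    """Render one stepwise-photobleaching intensity trace.

    Parameters
    ----------
    truth
        Planted step positions/heights, baseline and noise level.
    n_frames
        Movie length; must exceed every planted step frame.
    seed
        Integer seed or ``numpy.random.Generator``; identical seeds give
        bitwise-identical traces.

    Returns
    -------
    ndarray of shape (n_frames,) with the noisy trace.
    """
    if truth.n_steps and max(truth.step_frames) >= n_frames:
        raise ValueError("step frame outside trace range")
    t = np.arange(n_frames)
    trace = np.full(n_frames, float(truth.baseline))
    for frame, height in zip(truth.step_frames, truth.step_heights):
        trace += np.where(t < frame, float(height), 0.0)
    if truth.noise_sd > 0:
        rng = _child_rng(seed, "trace")
        trace = trace + rng.normal(0.0, truth.noise_sd, size=n_frames)
    return trace


def _draw_separated_frames(rng, k, lo, hi, min_separation):
    """k sorted frames in [lo, hi) with pairwise gaps >= min_separation."""
    span = (hi - lo) - (k - 1) * min_separation
    if span < k:
        raise ValueError("trace too short for requested steps/separation")
    base = np.sort(rng.choice(span, size=k, replace=False))
    return base + lo + np.arange(k) * min_separation


def generate_trace_set(
    stoichiometry_weights=EGFP_STOICHIOMETRY_WEIGHTS,
    n_traces: int = 1000,
    n_frames: int = 500,
    step_height: float = 1000.0,
    step_height_cv: float = 0.1,
    baseline: float = 200.0,
    noise_sd: float = 0.0,
    min_separation: int = 24,
    edge_margin: int = 12,
    seed=0,
):
    """Generate a population of bleaching traces with planted stoichiometry.

    ``stoichiometry_weights[k-1]`` is the probability that a trace carries
    ``k`` fluorophores (k = 1..K).  Bleach frames are drawn uniformly over
    the movie subject to a minimum separation (default twice the
    Chung-Kennedy window: two bleach events within the filter's response
    time are unresolvable in principle, and between events closer than
    2 x window both shuttling windows straddle a step and the filter
    cannot settle) and an edge margin.  See docs/methods.md.

    Returns a list of ``(trace, TraceGroundTruth)`` pairs.
    """
    w = np.asarray(stoichiometry_weights, float)
    if (w < 0).any():
        raise ValueError("stoichiometry weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("stoichiometry weights must sum to 1")
    rng = _child_rng(seed, "trace_set")
    counts = rng.choice(np.arange(1, len(w) + 1), size=int(n_traces), p=w)
    out = []
    for k in counts:
        frames = _draw_separated_frames(rng, int(k), edge_margin,
                                        n_frames - edge_margin, min_separation)
        if step_height_cv > 0:
            heights = step_height * rng.lognormal(
                -0.5 * np.log1p(step_height_cv**2),
                np.sqrt(np.log1p(step_height_cv**2)), size=int(k))
        else:
            heights = np.full(int(k), float(step_height))
        truth = TraceGroundTruth(
            n_steps=int(k),
            step_frames=tuple(int(f) for f in frames),
            step_heights=tuple(float(h) for h in heights),
            baseline=float(baseline),
            noise_sd=float(noise_sd),
        )
        trace = generate_bleach_trace(truth, n_frames, seed=rng)
        out.append((trace, truth))
    return out


# ---------------------------------------------------------------------------
# localization fields
# ---------------------------------------------------------------------------

@dataclass
class TruncatedNormalPrecision:
    """Localization-precision model: truncated normal in nm.

    Defaults match a measured per-localization precision of
    21.8 +/- 6.5 nm (mean +/- SD), truncated at 5 nm and at the 40 nm
    precision threshold applied at ingest.
    """

    mean_nm: float = 21.8
    sd_nm: float = 6.5
    lo_nm: float = 5.0
    hi_nm: float = 40.0

    def draw(self, rng, size):
        a = (self.lo_nm - self.mean_nm) / self.sd_nm
        b = (self.hi_nm - self.mean_nm) / self.sd_nm
        vals = stats.truncnorm.rvs(a, b, loc=self.mean_nm, scale=self.sd_nm,
                                   size=size, random_state=rng)
        if np.any(np.asarray(vals) <= 0):
            raise ValueError("precision model yielded non-positive values")
        return np.asarray(vals, float)


@dataclass
class _ConstantPrecision:
    """Degenerate precision model (scalar nm); 0 plants exact positions."""

    value_nm: float

    def draw(self, rng, size):
        return np.full(size, float(self.value_nm))


@dataclass
class FieldGroundTruth:
    """Ground truth of a synthetic localization or two-channel spot field."""

    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)
    fluorophores: pd.DataFrame = field(default_factory=pd.DataFrame)
    localization_fluor_id: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    dimer_separation_nm: float | None = None
    coincident_fraction: float | None = None
    coincident_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))


def _dart_throw_centers(rng, n, field_size, min_separation, max_tries=200):
    centers = np.empty((0, 2))
    tries = 0
    while len(centers) < n:
        cand = rng.uniform(0, field_size, size=2)
        if len(centers) == 0 or np.min(np.hypot(*(centers - cand).T)) > min_separation:
            centers = np.vstack([centers, cand])
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                raise ValueError("field too small for requested non-overlapping clusters")
    return centers


def generate_localization_field(
    n_clusters: int = 100,
    stoichiometry_weights=MEOS2_STOICHIOMETRY_WEIGHTS,
    field_size_nm: float = 20000.0,
    min_cluster_separation_nm: float = 600.0,
    fluorophore_spread_nm: float = 40.0,
    blink_mean: float = 2.0,
    precision_model: TruncatedNormalPrecision | None = None,
    detection_efficiency: float = 1.0,
    n_frames: int = 15000,
    seed=0,
):
    """Generate an SMLM localization table with planted clusters.

    Each cluster carries 1..K fluorophores (K = len(weights); the last
    weight covers ">K-1" and plants exactly K).  Fluorophores sit uniformly
    in a disc of radius ``fluorophore_spread_nm`` around the cluster
    center; each emits a geometric(mean=``blink_mean``) number of blinks
    (>=1) and every blink is displaced isotropically by Gaussian noise of
    SD equal to its drawn precision.

    ``detection_efficiency`` < 1 optionally drops fluorophores before
    blinking, emulating incomplete fluorescent-protein maturation/folding;
    clusters losing every fluorophore are removed from the ground truth.

    Returns ``(table, FieldGroundTruth)`` where ``table`` is a DataFrame
    with columns ``x_nm, y_nm, frame, precision_nm``.
    """
    if precision_model is None:
        precision_model = TruncatedNormalPrecision()
    elif not hasattr(precision_model, "draw"):
        value = float(precision_model)
        if value < 0:
            raise ValueError("precision model yielded non-positive values")
        precision_model = _ConstantPrecision(value)
    rng = _child_rng(seed, "field")
    centers = _dart_throw_centers(rng, n_clusters, field_size_nm, min_cluster_separation_nm)
    kmax = len(tuple(stoichiometry_weights))
    counts = rng.choice(np.arange(1, kmax + 1), size=n_clusters,
                        p=np.asarray(stoichiometry_weights, float))

    fl_rows, loc_rows, loc_fluor = [], [], []
    fid = 0
    kept_clusters = []
    for cid, (center, k) in enumerate(zip(centers, counts)):
        n_kept = 0
        for _ in range(int(k)):
            if detection_efficiency < 1.0 and rng.random() > detection_efficiency:
                continue
            r = fluorophore_spread_nm * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            pos = center + r * np.array([np.cos(th), np.sin(th)])
            n_blinks = int(rng.geometric(1.0 / max(blink_mean, 1.0)))
            prec = precision_model.draw(rng, n_blinks)
            offs = rng.normal(0, 1, size=(n_blinks, 2)) * prec[:, None]
            frames = np.sort(rng.integers(0, n_frames, size=n_blinks))
            for j in range(n_blinks):
                loc_rows.append((pos[0] + offs[j, 0], pos[1] + offs[j, 1],
                                 int(frames[j]), prec[j]))
                loc_fluor.append(fid)
            fl_rows.append((fid, cid, pos[0], pos[1], n_blinks))
            fid += 1
            n_kept += 1
        kept_clusters.append((cid, center[0], center[1], int(k), n_kept))

    table = pd.DataFrame(loc_rows, columns=["x_nm", "y_nm", "frame", "precision_nm"])
    truth = FieldGroundTruth(
        clusters=pd.DataFrame(kept_clusters,
                              columns=["cluster_id", "x_nm", "y_nm",
                                       "n_fluorophores", "n_detected"]),
        fluorophores=pd.DataFrame(fl_rows, columns=["fluor_id", "cluster_id",
                                                    "x_nm", "y_nm", "n_blinks"]),
        localization_fluor_id=np.asarray(loc_fluor, int),
    )
    return table, truth


def generate_dimer_field(
    n_dimers: int = 1000,
    separation_nm: float = 12.7,
    precision_nm: float = 4.0,
    position_noise: bool = True,
    field_size_nm: float = 50000.0,
    min_cluster_separation_nm: float = 600.0,
    blink_mean: float = 1.0,
    n_frames: int = 15000,
    seed=0,
):
    """Generate a field of two-fluorophore clusters at a planted separation.

    Every cluster holds exactly two fluorophores ``separation_nm`` apart at
    a random orientation.  ``precision_nm`` can be a scalar or a
    :class:`TruncatedNormalPrecision`; with ``position_noise=False`` the
    localizations sit exactly on the true positions (precision is then only
    carried as the rendering width for class averaging).

    Returns ``(table, FieldGroundTruth)``.
    """
    rng = _child_rng(seed, "dimer_field")
    centers = _dart_throw_centers(rng, n_dimers, field_size_nm, min_cluster_separation_nm)
    theta = rng.uniform(0, 2 * np.pi, size=n_dimers)
    half = 0.5 * separation_nm * np.column_stack([np.cos(theta), np.sin(theta)])

    loc_rows, loc_fluor, fl_rows, cl_rows = [], [], [], []
    fid = 0
    for cid in range(n_dimers):
        for s in (-1.0, 1.0):
            pos = centers[cid] + s * half[cid]
            n_blinks = int(rng.geometric(1.0 / max(blink_mean, 1.0)))
            if isinstance(precision_nm, TruncatedNormalPrecision):
                prec = precision_nm.draw(rng, n_blinks)
            else:
                if precision_nm < 0:
                    raise ValueError("precision must be >= 0")
                prec = np.full(n_blinks, float(precision_nm))
            offs = (rng.normal(0, 1, size=(n_blinks, 2)) * prec[:, None]
                    if position_noise else np.zeros((n_blinks, 2)))
            frames = rng.integers(0, n_frames, size=n_blinks)
            for j in range(n_blinks):
                loc_rows.append((pos[0] + offs[j, 0], pos[1] + offs[j, 1],
                                 int(frames[j]), prec[j]))
                loc_fluor.append(fid)
            fl_rows.append((fid, cid, pos[0], pos[1], n_blinks))
            fid += 1
        cl_rows.append((cid, centers[cid, 0], centers[cid, 1], 2, 2))

    table = pd.DataFrame(loc_rows, columns=["x_nm", "y_nm", "frame", "precision_nm"])
    truth = FieldGroundTruth(
        clusters=pd.DataFrame(cl_rows, columns=["cluster_id", "x_nm", "y_nm",
                                                "n_fluorophores", "n_detected"]),
        fluorophores=pd.DataFrame(fl_rows, columns=["fluor_id", "cluster_id",
                                                    "x_nm", "y_nm", "n_blinks"]),
        localization_fluor_id=np.asarray(loc_fluor, int),
        dimer_separation_nm=float(separation_nm),
    )
    return table, truth


# ---------------------------------------------------------------------------
# two-channel spot fields
# ---------------------------------------------------------------------------

def generate_two_channel_spots(
    n_a: int,
    n_b: int,
    coincident_fraction: float,
    jitter_sd: float = 0.3,
    field_shape=(2048, 2048),
    seed=0,
):
    """Plant a two-color spot field with a known coincident fraction.

    A fraction ``coincident_fraction`` of channel-A spots receive a
    channel-B partner displaced by isotropic Gaussian jitter of SD
    ``jitter_sd`` pixels (channel-registration residual); the remaining
    channel-B spots are uniform and independent.  Coordinates are rounded
    to integer pixels, as produced by maximum finding on camera images.

    Returns ``(spots_a, spots_b, FieldGroundTruth)`` where the spot arrays
    are integer ``(N, 2)`` arrays of (x, y) pixels and
    ``truth.coincident_pairs[:, 0]/[:, 1]`` index A/B rows of planted pairs.
    """
    if not 0.0 <= coincident_fraction <= 1.0:
        raise ValueError("coincident_fraction must be in [0, 1]")
    n_pairs = int(round(coincident_fraction * n_a))
    if n_pairs > n_b:
        raise ValueError("n_b too small for requested coincident fraction")
    h, w = field_shape
    rng = _child_rng(seed, "two_channel")
    a = rng.uniform([1.0, 1.0], [w - 2.0, h - 2.0], size=(n_a, 2))
    partners = a[:n_pairs] + rng.normal(0, jitter_sd, size=(n_pairs, 2))
    extra = rng.uniform([1.0, 1.0], [w - 2.0, h - 2.0], size=(n_b - n_pairs, 2))
    b = np.vstack([partners, extra])
    b = np.clip(b, 0, [w - 1, h - 1])
    spots_a = np.round(a).astype(int)
    spots_b = np.round(b).astype(int)
    truth = FieldGroundTruth(
        coincident_fraction=float(coincident_fraction),
        coincident_pairs=np.column_stack([np.arange(n_pairs), np.arange(n_pairs)]),
    )
    return spots_a, spots_b, truth


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _render_frame(img, xy, amps, psf_sigma):
    h, w = img.shape
    half = max(1, int(np.ceil(4 * psf_sigma)))
    for (x, y), a in zip(xy, amps):
        if a == 0:
            continue
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        xs = np.arange(max(x0, 0), min(x1, w))
        ys = np.arange(max(y0, 0), min(y1, h))
        if len(xs) == 0 or len(ys) == 0:
            continue
        gx = np.exp(-0.5 * ((xs - x) / psf_sigma) ** 2)
        gy = np.exp(-0.5 * ((ys - y) / psf_sigma) ** 2)
        img[np.ix_(ys, xs)] += a * np.outer(gy, gx)


def render_image(
    spots,
    intensities=None,
    shape=(512, 512),
    psf_sigma: float = 1.5,
    background: float = 100.0,
    noise: str = "none",
    read_noise_sd: float = 0.0,
    seed=0,
):
    """Render diffraction-limited spots as 2-D Gaussians on one frame.

    Each spot becomes an isotropic Gaussian of SD ``psf_sigma`` pixels and
    *peak* amplitude equal to its intensity, on a constant background.
    ``noise`` is ``"none"`` or ``"poisson"`` (shot noise on the whole
    image); Gaussian read noise of SD ``read_noise_sd`` is added on top.
    Spots outside the image are clipped with a warning.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    spots = np.atleast_2d(np.asarray(spots, float))
    if spots.size and spots.shape[1] != 2:
        raise ValueError("spots must be (N, 2) (x, y)")
    h, w = shape
    if spots.size:
        oob = (spots[:, 0] < 0) | (spots[:, 0] >= w) | (spots[:, 1] < 0) | (spots[:, 1] >= h)
        if oob.any():
            import warnings
            warnings.warn(f"{int(oob.sum())} spot(s) outside image bounds; clipped")
            spots = spots[~oob]
            if intensities is not None:
                intensities = np.asarray(intensities, float)[~oob]
    if intensities is None:
        intensities = np.full(len(spots), 1000.0)
    img = np.full(shape, float(background))
    _render_frame(img, spots, np.asarray(intensities, float), psf_sigma)
    rng = _child_rng(seed, "render")
    if noise == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}")
    if read_noise_sd > 0:
        img = img + rng.normal(0, read_noise_sd, size=img.shape)
    return img


def render_stack(
    spots,
    traces,
    shape=(512, 512),
    psf_sigma: float = 1.5,
    background: float = 100.0,
    noise: str = "none",
    read_noise_sd: float = 0.0,
    seed=0,
):
    """Render a photobleaching movie: one frame per column of ``traces``.

    ``traces`` is ``(n_spots, n_frames)``; frame ``t`` renders spot *i*
    with peak amplitude ``traces[i, t]`` (the background in ``traces`` is
    expected to be zero; the constant camera background is added here).
    """
    spots = np.atleast_2d(np.asarray(spots, float))
    traces = np.atleast_2d(np.asarray(traces, float))
    if len(spots) != len(traces):
        raise ValueError("one trace per spot required")
    n_frames = traces.shape[1]
    rng = _child_rng(seed, "render_stack")
    stack = np.empty((n_frames,) + tuple(shape))
    for t in range(n_frames):
        frame = np.full(shape, float(background))
        _render_frame(frame, spots, traces[:, t], psf_sigma)
        if noise == "poisson":
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
        if read_noise_sd > 0:
            frame = frame + rng.normal(0, read_noise_sd, size=frame.shape)
        stack[t] = frame
    return stack


# ---------------------------------------------------------------------------
# region cohorts (turnover statistics)
# ---------------------------------------------------------------------------

#: Synthetic per-region mean mixed-supercomplex fractions for a day-7
#: pulse-chase cohort.  Isocortex (0.19) and olfactory bulb (0.04) follow
#: measured values; the other three regions are plausible intermediates
#: (synthetic stand-ins -- the source study does not print them).
DEFAULT_REGION_MIXED_MEANS = {
    "isocortex": 0.19,
    "hippocampus": 0.12,
    "olfactory bulb": 0.04,
    "cerebellum": 0.08,
    "subcortex": 0.10,
}


def generate_region_cohort(
    region_mixed_means=None,
    mixed_sd: float = 0.03,
    a_only_mean: float = 0.56,
    a_only_sd: float = 0.06,
    n_mice: int = 6,
    seed=0,
) -> pd.DataFrame:
    """Simulate a per-mouse, per-region population-fraction table.

    Each mouse x region row carries (a_only, b_only, mixed) fractions that
    sum to 1: the mixed fraction is Gaussian per region around the supplied
    means, the old-protein-only (a_only) fraction is Gaussian with no
    region effect, and b_only absorbs the remainder.  Output is tidy:
    ``mouse_id, region, frac_a_only, frac_b_only, frac_mixed``.
    """
    means = dict(DEFAULT_REGION_MIXED_MEANS if region_mixed_means is None
                 else region_mixed_means)
    rng = _child_rng(seed, "cohort")
    rows = []
    for m in range(int(n_mice)):
        for region, mu in means.items():
            mixed = float(np.clip(rng.normal(mu, mixed_sd), 0.0, 1.0))
            a_only = float(np.clip(rng.normal(a_only_mean, a_only_sd), 0.0, 1.0 - mixed))
            rows.append((f"mouse{m}", region, a_only, 1.0 - a_only - mixed, mixed))
    return pd.DataFrame(rows, columns=["mouse_id", "region", "frac_a_only",
                                       "frac_b_only", "frac_mixed"])
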