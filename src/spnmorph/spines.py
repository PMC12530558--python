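"""Dendritic spine density model, membrane-area correction and spine statistics.

Spine density along SPN dendrites rises sigmoidally with path distance x from
the soma (near zero over the first ~25 μm, maximal from ~50 μm on):

    S(x) = a / (1 + exp((b − x) / c))

with plateau density ``a`` (spines/μm), half-rise distance ``b`` (μm) and
slope scale ``c`` (μm).  Because spines are not meshed in compartment models,
their membrane is folded into the shaft via the factor

    F(x) = 1 + (F_spines − 1) · S(x)/a,      F_spines = A_total / A_shaft,

multiplying C_m and dividing R_m, which leaves the membrane time constant
unchanged while scaling the effective membrane area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import Reconstruction
from .morphometry import FitError, Segment, partition_segments


@dataclass(frozen=True)
class SpineDensityModel:
    """Sigmoid spine linear density S(x) = a / (1 + e^((b−x)/c))."""

    a: float   # plateau density, spines/μm
    b: float   # half-rise distance, μm
    c: float   # slope scale, μm

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0:
            raise ValueError("sigmoid parameters a and c must be positive")

    def __call__(self, x) -> np.ndarray:
        return spine_density(x, self)


def spine_density(x, model: SpineDensityModel):
    """S(x) in spines/μm at path distance(s) x from the soma."""
    x = np.asarray(x, dtype=float)
    out = model.a / (1.0 + np.exp(np.clip((model.b - x) / model.c, -700, 700)))
    return out if out.ndim else float(out)


def fit_spine_density(bin_centers, spine_counts, bin_lengths,
                      ) -> SpineDensityModel:
    """Weighted nonlinear least-squares sigmoid fit to binned spine densities.

    Each bin contributes density = count / dendritic length in the bin,
    weighted by the dendritic length sampled in the bin (longer-sampled bins
    constrain the fit more).
    """
    x = np.asarray(bin_centers, dtype=float)
    counts = np.asarray(spine_counts, dtype=float)
    length = np.asarray(bin_lengths, dtype=float)
    ok = length > 0
    x, counts, length = x[ok], counts[ok], length[ok]
    if len(x) < 4:
        raise FitError("sigmoid fit needs at least 4 bins with dendrite in them")
    dens = counts / length
    if not np.any(dens > 0):
        raise FitError("all spine counts are zero; nothing to fit")

    a0 = float(dens.max())
    half = x[dens >= a0 / 2]
    b0 = float(half.min()) if len(half) else float(np.median(x))
    p0 = (a0, b0, 10.0)

    def model(xx, a, b, c):
        return a / (1.0 + np.exp(np.clip((b - xx) / c, -700, 700)))

    sigma = 1.0 / np.sqrt(length)   # weights ∝ dendritic length per bin
    try:
        popt, _ = optimize.curve_fit(
            model, x, dens, p0=p0, sigma=sigma,
            bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    return SpineDensityModel(float(popt[0]), float(popt[1]), float(popt[2]))


def bin_spine_counts(distances, dendrite_lengths, bin_width: float = 10.0,
                     max_distance: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin spine path distances into half-open [lo, hi) bins anchored at the soma.

    ``dendrite_lengths`` is either a scalar/array of dendrite path lengths (the
    sampled dendrites are assumed to run from the soma to their tip) from which
    per-bin sampled length is computed, or a precomputed per-bin length array.

    Returns (bin centres, spine counts, dendritic length per bin).
    """
    distances = np.asarray(distances, dtype=float)
    lens = np.atleast_1d(np.asarray(dendrite_lengths, dtype=float))
    if max_distance is None:
        max_distance = float(lens.max())
    n_bins = int(np.ceil(max_distance / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(distances, bins=edges)
    # dendritic length sampled within each bin
    lo, hi = edges[:-1], edges[1:]
    bin_len = np.zeros(n_bins)
    for L in lens:
        bin_len += np.clip(np.minimum(hi, L) - lo, 0.0, bin_width)
    centers = (lo + hi) / 2
    return centers, counts.astype(float), bin_len


# ---------------------------------------------------------------------------
# membrane-area correction


def f_spines(a_spines, a_shaft) -> float | tuple[float, float]:
    """F_spines = (A_spines + A_shaft)/A_shaft.

    Scalar inputs give the factor for one dendrite; array inputs give the
    cohort (mean, SD) over dendrites.
    """
    a_spines = np.asarray(a_spines, dtype=float)
    a_shaft = np.asarray(a_shaft, dtype=float)
    if np.any(a_shaft <= 0):
        raise ValueError("A_shaft must be positive")
    if np.any(a_spines < 0):
        raise ValueError("A_spines must be non-negative")
    factors = (a_spines + a_shaft) / a_shaft
    if factors.ndim == 0:
        return float(factors)
    return float(factors.mean()), float(factors.std(ddof=1))


def spine_correction(x, model: SpineDensityModel, f_spines_factor: float):
    """Membrane-area correction F(x) = 1 + (F_spines − 1)·S(x)/a ∈ [1, F_spines]."""
    if f_spines_factor < 1:
        raise ValueError("F_spines must be ≥ 1")
    s = np.asarray(spine_density(x, model), dtype=float)
    out = 1.0 + (f_spines_factor - 1.0) * s / model.a
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# expected counts on a reconstruction


@dataclass
class SpineCountEstimate:
    total: float
    per_segment: np.ndarray          # expected count per segment
    terminal_fraction: float


def expected_spine_counts(recon: Reconstruction, model: SpineDensityModel,
                          segments: list[Segment] | None = None
                          ) -> SpineCountEstimate:
    """Expected spine counts per segment as the path integral ∫ S(x) dx.

    Integrated by the trapezoid rule on the reconstruction's own nodes (use a
    resampled reconstruction for a uniform quadrature step).  The terminal
    fraction is the share of the total expected count carried by terminal
    segments.
    """
    if segments is None:
        segments = partition_segments(recon)
    pd_arr = recon.path_distances()
    counts = np.zeros(len(segments))
    for i, seg in enumerate(segments):
        x = pd_arr[seg.node_path]
        counts[i] = float(np.trapezoid(spine_density(x, model), x))
    total = float(counts.sum())
    term = float(sum(c for c, s in zip(counts, segments) if s.is_terminal))
    return SpineCountEstimate(
        total=total, per_segment=counts,
        terminal_fraction=term / total if total > 0 else 0.0)


# ---------------------------------------------------------------------------
# spine geometry statistics


SPINE_COLUMNS = ["dendrite_id", "distance_um", "area_um2", "head_area_um2",
                 "neck_length_um", "neck_diameter_um"]


@dataclass
class SpineGeometryStats:
    n: int
    mean_area: float
    sd_area: float
    mean_head_area: float | None
    mean_neck_length: float | None
    mean_neck_diameter: float | None
    n_missing_optional: int
    profile: pd.DataFrame            # per-10-μm bin: mean, sem, n
    spearman_r: float
    spearman_p: float


def spine_geometry_stats(spines: pd.DataFrame, bin_width: float = 10.0
                         ) -> SpineGeometryStats:
    """Summaries of a spine inventory plus the area-vs-distance profile.

    ``spines`` needs columns ``distance_um`` and ``area_um2``; the optional
    head/neck columns are summarised when present (rows with missing values
    are excluded from those summaries and counted).
    """
    if len(spines) < 3:
        raise ValueError("need at least 3 spine records")
    x = spines["distance_um"].to_numpy(dtype=float)
    area = spines["area_um2"].to_numpy(dtype=float)
    if np.ptp(area) == 0 or np.ptp(x) == 0:
        r, p = 0.0, 1.0        # constant input: no monotone association
    else:
        r, p = stats.spearmanr(area, x)
    edges = bin_width * np.arange(int(np.ceil(x.max() / bin_width)) + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append({
            "bin_lo_um": edges[b], "bin_hi_um": edges[b + 1], "n": n,
            "mean_area_um2": float(area[sel].mean()),
            "sem_area_um2": float(area[sel].std(ddof=1) / np.sqrt(n))
            if n > 1 else 0.0,
        })

    def _opt(col):
        if col not in spines.columns:
            return None, len(spines)
        vals = spines[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        return (float(vals[ok].mean()) if ok.any() else None,
                int((~ok).sum()))

    head, miss_h = _opt("head_area_um2")
    neck_l, miss_l = _opt("neck_length_um")
    neck_d, miss_d = _opt("neck_diameter_um")
    return SpineGeometryStats(
        n=len(spines),
        mean_area=float(area.mean()),
        sd_area=float(area.std(ddof=1)),
        mean_head_area=head,
        mean_neck_length=neck_l,
        mean_neck_diameter=neck_d,
        n_missing_optional=miss_h + miss_l + miss_d,
        profile=pd.DataFrame(rows),
        spearman_r=float(r),
        spearman_p=float(p),
    )
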