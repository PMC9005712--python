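"""Contact probability vs genomic distance, P(s): log-binned curve (ten bins
per decade), its log-log slope, and two-phase feature detection.

Phase I is the TAD-scale U-shape of the slope: it dips toward -1 near the
characteristic TAD length and recovers.  Phase II is the subsequent local
maximum followed by a sharp drop of the slope below -1 at the territory-shape
distance (~3 Mb in insect-scale genomes).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic_core import BinnedContactMap

BINS_PER_DECADE = 10


@dataclass
class ScalingCurve:
    distance_bin_edges: np.ndarray   # bp, logarithmic
    distance_mid: np.ndarray         # bp, geometric midpoints
    p_of_s: np.ndarray               # normalized to sum 1 over populated bins
    n_pairs: np.ndarray
    bin_size: int


@dataclass
class PhaseFeatures:
    slope_min_distance: float | None
    slope_min_value: float | None
    phase2_max_distance: float | None
    phase2_max_value: float | None
    drop_distance: float | None


def contact_scaling(
    cmap: BinnedContactMap,
    bins_per_decade: int = BINS_PER_DECADE,
    min_dist_bp: int | None = None,
) -> ScalingCurve:
    """Mean balanced contact per logarithmic distance bin, pooled over
    chromosomes weighted by pair counts, normalized to sum 1.

    Distances below 2 bins (self/adjacent ligation artifacts) are excluded.
    """
    b = cmap.binning
    bal = cmap.balanced()
    good = ~cmap.bad_bins
    min_dist = max(2 * b.bin_size, min_dist_bp or 0)
    max_dist = max(b.chrom_lengths)
    lo, hi = np.log10(min_dist), np.log10(max_dist)
    n_edges = int(np.ceil((hi - lo) * bins_per_decade)) + 1
    edges = 10 ** (lo + np.arange(n_edges + 1) / bins_per_decade)

    sums = np.zeros(n_edges)
    cnts = np.zeros(n_edges)
    logd_sums = np.zeros(n_edges)
    for chrom in b.chrom_names:
        s = b.chrom_slice(chrom)
        g = good[s]
        idx = np.where(g)[0]
        if idx.size < 3:
            continue
        block = bal[s, s][np.ix_(idx, idx)]
        d = np.abs(idx[:, None] - idx[None, :]) * b.bin_size
        iu = np.triu_indices(idx.size, k=1)
        dist = d[iu].astype(float)
        vals = block[iu]
        fin = np.isfinite(vals) & (dist >= min_dist)
        which = np.digitize(dist[fin], edges) - 1
        ok = (which >= 0) & (which < n_edges)
        sums += np.bincount(which[ok], weights=vals[fin][ok], minlength=n_edges)
        cnts += np.bincount(which[ok], minlength=n_edges)
        logd_sums += np.bincount(which[ok], weights=np.log10(dist[fin][ok]), minlength=n_edges)
    if (cnts > 0).sum() < 2:
        raise ValueError("fewer than 2 populated distance bins")
    with np.errstate(invalid="ignore"):
        p = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    total = np.nansum(p)
    if total > 0:
        p = p / total
    # realized pair-weighted mean log-distance per bin: removes the
    # discreteness/truncation bias of geometric edge midpoints
    with np.errstate(invalid="ignore"):
        mids = np.where(cnts > 0, 10 ** (logd_sums / np.maximum(cnts, 1)),
                        np.sqrt(edges[:-1] * edges[1:]))
    return ScalingCurve(distance_bin_edges=edges, distance_mid=mids, p_of_s=p,
                        n_pairs=cnts, bin_size=b.bin_size)


def scaling_slope(curve: ScalingCurve, smooth_bins: int = 0) -> np.ndarray:
    """Centered finite difference of log10 P vs log10 s; NaN where P is
    missing or zero; optional running-mean smoothing."""
    if curve.p_of_s.size < 3:
        raise ValueError("need at least 3 distance bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log10(curve.p_of_s)
        logs = np.log10(curve.distance_mid)
    logp[~np.isfinite(logp)] = np.nan
    n = logp.size
    slope = np.full(n, np.nan)
    for i in range(1, n - 1):
        if np.isfinite(logp[i - 1]) and np.isfinite(logp[i + 1]):
            slope[i] = (logp[i + 1] - logp[i - 1]) / (logs[i + 1] - logs[i - 1])
    if smooth_bins > 1:
        sm = np.full(n, np.nan)
        h = smooth_bins // 2
        for i in range(n):
            win = slope[max(0, i - h) : i + h + 1]
            fin = np.isfinite(win)
            if fin.any():
                sm[i] = win[fin].mean()
        sm[~np.isfinite(slope)] = np.nan
        slope = sm
    return slope


def detect_phases(
    curve: ScalingCurve,
    slope: np.ndarray,
    phase_bound_bp: float = 1_000_000,
) -> PhaseFeatures:
    """Phase-I slope minimum below ``phase_bound_bp``, the subsequent local
    slope maximum (phase II), and the first distance after it where the slope
    falls below -1 (the drop).  Undetected features are returned as None."""
    mids = curve.distance_mid
    fin = np.isfinite(slope)
    pop = mids[curve.n_pairs > 0]
    if pop.size < 2 or np.log10(pop[-1] / pop[0]) < 2 - 1e-9:
        raise ValueError("curve must cover at least 2 decades of distance")
    if not fin.any():
        return PhaseFeatures(None, None, None, None, None)
    search = fin & (mids <= phase_bound_bp)
    if not search.any():
        return PhaseFeatures(None, None, None, None, None)
    i_min = int(np.nanargmin(np.where(search, slope, np.inf)))
    res = dict(
        slope_min_distance=float(mids[i_min]),
        slope_min_value=float(slope[i_min]),
        phase2_max_distance=None,
        phase2_max_value=None,
        drop_distance=None,
    )
    # local maximum after the phase-I minimum
    i_max = None
    best = -np.inf
    for i in range(i_min + 1, slope.size):
        if not np.isfinite(slope[i]):
            continue
        if slope[i] > best:
            best = slope[i]
            i_max = i
        elif best > slope[i_min] and slope[i] < best - 1e-12:
            break
    if i_max is not None and best > slope[i_min]:
        res["phase2_max_distance"] = float(mids[i_max])
        res["phase2_max_value"] = float(best)
        for i in range(i_max + 1, slope.size):
            if np.isfinite(slope[i]) and slope[i] < -1.0:
                res["drop_distance"] = float(mids[i])
                break
    return PhaseFeatures(**res)
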