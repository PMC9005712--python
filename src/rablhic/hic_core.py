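"""Contact-map container, I/O, matrix balancing, expected model and O/E.

The map is held as one dense genome-wide symmetric matrix with chromosome
offsets; desk-scale genomes (a few thousand bins) fit comfortably.  Balancing
uses iterative correction, which shares its fixed point (equal row sums over
good bins) with KR balancing up to a global scale.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Binning

SYMMETRY_RTOL = 1e-6


@dataclass
class BinnedContactMap:
    """Symmetric binned contact counts for a whole genome.

    ``counts[i, j]`` is the (possibly balanced or O/E) signal between global
    bins ``i`` and ``j``.  ``weights`` are per-bin balancing multipliers
    (NaN on bad bins); ``bad_bins`` marks bins excluded from analysis.
    """

    binning: Binning
    counts: np.ndarray
    weights: np.ndarray | None = None
    bad_bins: np.ndarray | None = None

    def __post_init__(self):
        n = self.binning.n_bins
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (n, n):
            raise ValueError(f"counts shape {c.shape} != ({n}, {n})")
        finite = np.isfinite(c)
        if np.any(c[finite] < 0):
            i, j = np.argwhere(finite & (c < 0))[0]
            raise ValueError(f"negative count at bin pair ({i}, {j})")
        # symmetry: tolerate tiny asymmetry, average it away; reject larger
        asym = np.abs(c - c.T)
        with np.errstate(invalid="ignore"):
            scale = np.nanmax(np.abs(c)) or 1.0
            worst = np.nanmax(asym) if asym.size else 0.0
        if worst > SYMMETRY_RTOL * scale:
            i, j = np.unravel_index(np.nanargmax(asym), asym.shape)
            raise ValueError(
                f"matrix asymmetric: |C[{i},{j}] - C[{j},{i}]| = {worst:g} "
                f"exceeds relative tolerance {SYMMETRY_RTOL:g}"
            )
        c = 0.5 * (c + c.T)
        self.counts = c
        if self.bad_bins is None:
            self.bad_bins = np.zeros(n, dtype=bool)
        else:
            self.bad_bins = np.asarray(self.bad_bins, dtype=bool).copy()
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float).copy()
            if w.shape != (n,):
                raise ValueError("weights must be one per bin")
            w[self.bad_bins] = np.nan
            if np.any(w[~self.bad_bins] <= 0):
                raise ValueError("weights on good bins must be positive")
            self.weights = w

    # -- convenience --------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.binning.n_bins

    def cis_mask(self) -> np.ndarray:
        cid = self.binning.chrom_id_of_bins()
        return cid[:, None] == cid[None, :]

    def good_mask_2d(self) -> np.ndarray:
        good = ~self.bad_bins
        return good[:, None] & good[None, :]

    def balanced(self) -> np.ndarray:
        """Weighted matrix with NaN on bad rows/columns."""
        if self.weights is None:
            raise ValueError("map is not balanced; call balance_matrix first")
        w = self.weights
        m = self.counts * w[:, None] * w[None, :]
        return m

    def cis_block(self, chrom: str) -> np.ndarray:
        s = self.binning.chrom_slice(chrom)
        return self.counts[s, s]

    def copy_with(self, **kw) -> "BinnedContactMap":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_contact_map(cmap: BinnedContactMap, path: str, format: str = "dense-text") -> None:
    if format == "dense-text":
        _save_dense_text(cmap, path)
    elif format == "npz":
        np.savez_compressed(
            path,
            counts=cmap.counts,
            bin_size=cmap.binning.bin_size,
            chrom_names=np.array(cmap.binning.chrom_names, dtype=object),
            chrom_lengths=np.array(cmap.binning.chrom_lengths),
            weights=cmap.weights if cmap.weights is not None else np.array([]),
            bad_bins=cmap.bad_bins,
        )
    else:
        raise ValueError(f"unknown contact map format: {format!r}")


def _save_dense_text(cmap: BinnedContactMap, path: str) -> None:
    b = cmap.binning
    with open(path, "w") as fh:
        fh.write(f"# bin_size={b.bin_size}\n")
        for name, length in zip(b.chrom_names, b.chrom_lengths):
            fh.write(f"# chrom={name}:{length}\n")
        for row in cmap.counts:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v: float) -> str:
    if np.isnan(v):
        return "nan"
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def load_contact_map(path: str, format: str = "dense-text", resolution: int | None = None) -> BinnedContactMap:
    """Read a contact map from a dense text or npz container.

    ``resolution``, when given, must match the container's bin size; the
    containers are single-resolution.
    """
    if format == "dense-text":
        cmap = _load_dense_text(path)
    elif format == "npz":
        with np.load(path, allow_pickle=True) as z:
            binning = Binning(tuple(z["chrom_names"]), tuple(int(x) for x in z["chrom_lengths"]), int(z["bin_size"]))
            weights = z["weights"] if z["weights"].size else None
            cmap = BinnedContactMap(binning, z["counts"], weights=weights, bad_bins=z["bad_bins"])
    else:
        raise ValueError(f"unknown contact map format: {format!r}")
    if resolution is not None and resolution != cmap.binning.bin_size:
        raise ValueError(
            f"requested resolution {resolution} not available (container bin size {cmap.binning.bin_size})"
        )
    return cmap


def _load_dense_text(path: str) -> BinnedContactMap:
    bin_size = None
    names, lengths = [], []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("bin_size="):
                    bin_size = int(body.split("=", 1)[1])
                elif body.startswith("chrom="):
                    name, length = body.split("=", 1)[1].rsplit(":", 1)
                    names.append(name)
                    lengths.append(int(length))
                continue
            rows.append([float(x) for x in line.split("\t")])
    if bin_size is None or not names:
        raise ValueError(f"{path}: missing bin_size/chrom header lines")
    binning = Binning(tuple(names), tuple(lengths), bin_size)
    counts = np.array(rows, dtype=float)
    return BinnedContactMap(binning, counts)


# ---------------------------------------------------------------------------
# Balancing (iterative correction)
# ---------------------------------------------------------------------------

def balance_matrix(
    cmap: BinnedContactMap,
    tol: float = 1e-8,
    max_iter: int = 1000,
    bad_bin_cov_frac: float = 0.02,
) -> BinnedContactMap:
    """Balance the genome-wide matrix so good-bin row sums are equal.

    Bins with zero coverage, plus bins in the lowest ``bad_bin_cov_frac``
    quantile of nonzero coverage, are masked bad.  Returns a new map with
    ``weights`` set; raises if the row-sum residual has not fallen below
    ``tol`` after ``max_iter`` sweeps.
    """
    c = cmap.counts
    n = cmap.n_bins
    coverage = np.nansum(c, axis=1)
    bad = coverage <= 0
    nz = coverage[~bad]
    if nz.size and bad_bin_cov_frac > 0:
        cut = np.quantile(nz, bad_bin_cov_frac)
        bad |= coverage < cut
    bad |= cmap.bad_bins
    good = ~bad
    if good.sum() < 2:
        raise ValueError("fewer than two good bins; cannot balance")

    sub = c[np.ix_(good, good)].copy()
    np.nan_to_num(sub, copy=False)
    b = np.ones(sub.shape[0])
    resid = np.inf
    for _ in range(max_iter):
        m = sub / b[:, None] / b[None, :]
        s = m.sum(axis=1)
        s /= s.mean()
        resid = np.abs(s - 1.0).max()
        if resid < tol:
            break
        # damp zero rows defensively (should be masked already)
        s[s == 0] = 1.0
        b *= s
    else:
        raise RuntimeError(f"balancing did not converge in {max_iter} iterations; residual {resid:g}")

    weights = np.full(n, np.nan)
    w = 1.0 / b
    # scale so the balanced total equals the raw total over good bins
    raw_total = sub.sum()
    bal_total = (sub * np.outer(w, w)).sum()
    if bal_total > 0:
        w *= np.sqrt(raw_total / bal_total)
    weights[good] = w
    return cmap.copy_with(weights=weights, bad_bins=bad)


# ---------------------------------------------------------------------------
# Expected model and O/E
# ---------------------------------------------------------------------------

@dataclass
class ExpectedProfile:
    """Distance-expected balanced contact per bin separation, plus trans mean.

    ``expected_count[d]`` is the mean balanced count at separation ``d`` bins,
    averaged over chromosomes weighted by the number of good pairs; per-
    chromosome vectors are kept in ``per_chrom``.
    """

    bin_size: int
    distances: np.ndarray          # bin separations, 0..max
    expected_count: np.ndarray     # genome-wide average
    per_chrom: dict                # chrom -> expected vector (own max distance)
    trans_expected: float


def expected_model(cmap: BinnedContactMap) -> ExpectedProfile:
    """Mean balanced count per bin separation (cis) and trans mean."""
    bal = cmap.balanced()
    good = ~cmap.bad_bins
    b = cmap.binning
    per_chrom = {}
    max_n = max(b.bins_per_chrom)
    sums = np.zeros(max_n)
    cnts = np.zeros(max_n)
    any_good_chrom = False
    for chrom in b.chrom_names:
        s = b.chrom_slice(chrom)
        g = good[s]
        if g.sum() < 1:
            import warnings

            warnings.warn(f"chromosome {chrom} has no good bins; excluded from expected model")
            continue
        any_good_chrom = True
        block = bal[s, s]
        nb = block.shape[0]
        idx = np.where(g)[0]
        vals = block[np.ix_(idx, idx)]
        d = np.abs(idx[:, None] - idx[None, :]).ravel()
        v = vals.ravel()
        fin = np.isfinite(v)
        sums_c = np.bincount(d[fin], weights=v[fin], minlength=nb)
        cnts_c = np.bincount(d[fin], minlength=nb)
        with np.errstate(invalid="ignore"):
            exp_c = np.where(cnts_c > 0, sums_c / np.maximum(cnts_c, 1), np.nan)
        sums[:nb] += sums_c
        cnts[:nb] += cnts_c
        per_chrom[chrom] = exp_c
    if not any_good_chrom:
        raise ValueError("no good bins on any chromosome")
    with np.errstate(invalid="ignore"):
        gw = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    trans = bal[~cmap.cis_mask() & cmap.good_mask_2d()]
    trans = trans[np.isfinite(trans)]
    trans_expected = float(trans.mean()) if trans.size else np.nan
    return ExpectedProfile(
        bin_size=b.bin_size,
        distances=np.arange(max_n),
        expected_count=gw,
        per_chrom=per_chrom,
        trans_expected=trans_expected,
    )


def observed_over_expected(
    cmap: BinnedContactMap,
    expected: ExpectedProfile,
    per_chrom: bool = False,
) -> BinnedContactMap:
    """Divide each balanced entry by its distance expectation (trans by the
    trans mean).  Bad bins become NaN."""
    if expected.bin_size != cmap.binning.bin_size:
        raise ValueError("expected profile computed on a different binning")
    bal = cmap.balanced()
    b = cmap.binning
    oe = np.full_like(bal, np.nan)
    for chrom in b.chrom_names:
        s = b.chrom_slice(chrom)
        nb = s.stop - s.start
        vec = expected.per_chrom.get(chrom) if per_chrom else None
        if vec is None:
            vec = expected.expected_count[:nb]
        d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
        ev = vec[d]
        block = bal[s, s]
        populated = np.isfinite(block) & (block != 0)
        if np.any(populated & (ev == 0)):
            raise ValueError(f"zero expected value at a populated distance on {chrom}")
        with np.errstate(divide="ignore", invalid="ignore"):
            oe[s, s] = block / ev
    trans_mask = ~cmap.cis_mask()
    if expected.trans_expected and np.isfinite(expected.trans_expected):
        oe[trans_mask] = bal[trans_mask] / expected.trans_expected
    oe[cmap.bad_bins, :] = np.nan
    oe[:, cmap.bad_bins] = np.nan
    out = cmap.copy_with(counts=np.nan_to_num(oe, nan=0.0))
    # keep NaN semantics: store directly, bypassing the nonneg check on NaN
    out.counts = 0.5 * (oe + oe.T)
    return out


# ---------------------------------------------------------------------------
# cis/trans summaries
# ---------------------------------------------------------------------------

def cis_trans_ratio(cmap: BinnedContactMap, use_balanced: bool = False) -> pd.DataFrame:
    """Per-chromosome and pooled (mean cis pair count) / (mean trans pair count).

    Diagonal (self) pixels are excluded from the cis mean.  A chromosome with
    zero trans contact gets ``ratio = inf`` and ``infinite = True``.
    """
    b = cmap.binning
    if len(b.chrom_names) < 2:
        raise ValueError("cis/trans ratio requires at least two chromosomes")
    m = cmap.balanced() if use_balanced else cmap.counts
    cid = b.chrom_id_of_bins()
    rows = []
    cis_sum = cis_n = trans_sum = trans_n = 0.0
    for k, chrom in enumerate(b.chrom_names):
        s = b.chrom_slice(chrom)
        block = m[s, s]
        off = ~np.eye(block.shape[0], dtype=bool)
        cvals = block[off]
        cvals = cvals[np.isfinite(cvals)]
        tblock = m[s, :][:, cid != k]
        tvals = tblock[np.isfinite(tblock)]
        cmean = cvals.mean() if cvals.size else np.nan
        tmean = tvals.mean() if tvals.size else np.nan
        inf = bool(tvals.size and tmean == 0)
        ratio = np.inf if inf else cmean / tmean
        rows.append(dict(chrom=chrom, cis_mean=cmean, trans_mean=tmean, ratio=ratio, infinite=inf))
        cis_sum += cvals.sum()
        cis_n += cvals.size
        trans_sum += tvals.sum() / 2.0  # each trans pair visited twice
        trans_n += tvals.size / 2.0
    pooled_c = cis_sum / cis_n if cis_n else np.nan
    pooled_t = trans_sum / trans_n if trans_n else np.nan
    inf = bool(trans_n and pooled_t == 0)
    rows.append(
        dict(
            chrom="genome",
            cis_mean=pooled_c,
            trans_mean=pooled_t,
            ratio=np.inf if inf else pooled_c / pooled_t,
            infinite=inf,
        )
    )
    return pd.DataFrame(rows)
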