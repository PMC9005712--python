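"""Ground-truth synthetic data: Hi-C contact maps with compartments, TADs,
Rabl geometry and loops; correlated per-bin tracks; and multi-species
rearrangement histories with known breakpoints.

The contact generator is statistical, not polymer-physical: the expectation of
every pixel is an explicit product of model terms (distance decay with two
phases x compartment plaid x TAD blocks x Rabl terms x loops), and counts are
sampled independently per pixel from a Poisson with that mean.  This is
sufficient to test each estimator's recovery against known truth.

Chromosomes are metacentric: the centromere sits mid-chromosome, so each
chromosome has two arms and the Rabl terms (inter-arm "wings" between loci
equidistant from their centromeres, and centromere/telomere cluster blocks)
appear both in cis and in trans, as they do on real Rabl-configured maps.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Binning
from .hic_core import BinnedContactMap
from .tracks import GenomicTrack


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Loop:
    """An injected focal contact between two anchors (bp midpoints)."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    fold: float = 10.0
    size_bp: int = 25_000


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    """Study conditions for the synthetic Hi-C genome.

    Defaults emulate a 50 Mb insect-like genome at 25 kb bins: power-law decay
    with exponent -0.8 steepening to -1.5 beyond 3 Mb, ~0.5 Mb compartment
    segments with A-A/B-B affinity 1.5, ~150 kb TADs enriched 3x, a Rabl
    inter-arm wing of strength 2 and centromere/telomere clusters of 3x, and
    cis contacts 5x more frequent than trans.
    """

    n_chroms: int = 4
    chrom_length: int = 12_500_000
    bin_size: int = 25_000
    # distance decay, two phases
    decay_exponent: float = -0.8
    drop_distance: int = 3_000_000
    post_drop_exponent: float = -1.5
    # compartments; the plaid is attenuated beyond mid-range distances, as on
    # Rabl-configured maps where cen/tel clustering dominates long-range
    # structure (attenuation scale None disables)
    compartment_mean_segment: int = 500_000
    compartment_affinity: float = 1.5
    compartment_attenuation_distance: int | None = 6_000_000
    # TADs
    tad_mean_length: int = 150_000
    tad_min_length: int = 30_000
    tad_enrichment: float = 3.0
    tad_mean_length_by_compartment: dict | None = None  # e.g. {"A": 1e5, "B": 5e5}
    # Rabl geometry
    rabl_strength: float = 2.0
    rabl_wing_scale: int = 250_000
    cen_tel_multiplier: float = 3.0
    cen_tel_extent: int = 1_000_000
    couple_cen_tel: bool = False  # if True, cen-tel blocks are also enriched
    # cis/trans and noise
    cis_trans_ratio: float = 5.0
    mean_scale: float = 300.0
    loops: tuple = ()

    def __post_init__(self):
        if self.decay_exponent >= 0 or self.post_drop_exponent >= 0:
            raise ValueError("decay exponents must be negative")
        for name in ("compartment_affinity", "tad_enrichment", "rabl_strength",
                     "cen_tel_multiplier", "cis_trans_ratio", "mean_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def binning(self) -> Binning:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chroms))
        return Binning(names, (self.chrom_length,) * self.n_chroms, self.bin_size)


@dataclass
class SyntheticTruth:
    """Generator ground truth for one synthetic genome."""

    config: SyntheticGenomeConfig
    labels: np.ndarray              # per-bin compartment label, "A"/"B"
    tad_id: np.ndarray              # per-bin TAD membership id
    tad_boundaries: dict            # chrom -> local bin indices of boundaries
    centromeres: dict               # chrom -> bp position
    telomeres: dict                 # chrom -> (bp, bp)
    loops: tuple = ()
    rabl_strength: float = 1.0

    @property
    def binning(self) -> Binning:
        return self.config.binning

    def labels_signed(self) -> np.ndarray:
        """+1 for A bins, -1 for B bins."""
        return np.where(self.labels == "A", 1.0, -1.0)


# ---------------------------------------------------------------------------
# Structural truth
# ---------------------------------------------------------------------------

def _sample_segments(rng, total_bins, mean_bins, min_bins=1):
    """Segment lengths (bins) covering total_bins, ~exponential."""
    out = []
    acc = 0
    while acc < total_bins:
        ln = max(min_bins, int(round(rng.exponential(mean_bins))))
        ln = min(ln, total_bins - acc)
        out.append(ln)
        acc += ln
    return out


def simulate_truth(config: SyntheticGenomeConfig, seed: int) -> SyntheticTruth:
    """Draw compartment segments, TADs and Rabl landmarks."""
    rng = np.random.default_rng(seed)
    b = config.binning
    labels = np.empty(b.n_bins, dtype=object)
    tad_id = np.zeros(b.n_bins, dtype=int)
    boundaries = {}
    centromeres = {}
    telomeres = {}
    next_tad = 0
    for chrom in b.chrom_names:
        s = b.chrom_slice(chrom)
        nb = s.stop - s.start
        # compartments: alternating segments
        lab = "A" if rng.random() < 0.5 else "B"
        pos = 0
        mean_seg = max(1, config.compartment_mean_segment // config.bin_size)
        for ln in _sample_segments(rng, nb, mean_seg):
            labels[s.start + pos : s.start + pos + ln] = lab
            lab = "B" if lab == "A" else "A"
            pos += ln
        # TADs: sequential, optionally compartment-dependent lengths
        pos = 0
        bnds = []
        while pos < nb:
            if config.tad_mean_length_by_compartment:
                mean_len = config.tad_mean_length_by_compartment[labels[s.start + pos]]
            else:
                mean_len = config.tad_mean_length
            mean_extra = max(mean_len - config.tad_min_length, config.bin_size)
            ln_bp = config.tad_min_length + rng.exponential(mean_extra)
            ln = max(1, int(round(ln_bp / config.bin_size)))
            ln = min(ln, nb - pos)
            tad_id[s.start + pos : s.start + pos + ln] = next_tad
            next_tad += 1
            pos += ln
            if pos < nb:
                bnds.append(pos)
        boundaries[chrom] = np.array(bnds, dtype=int)
        centromeres[chrom] = config.chrom_length // 2
        telomeres[chrom] = (0, config.chrom_length)
    return SyntheticTruth(
        config=config,
        labels=labels,
        tad_id=tad_id,
        tad_boundaries=boundaries,
        centromeres=centromeres,
        telomeres=telomeres,
        loops=tuple(config.loops),
        rabl_strength=config.rabl_strength,
    )


# ---------------------------------------------------------------------------
# Contact-map expectation and sampling
# ---------------------------------------------------------------------------

def decay_curve(config: SyntheticGenomeConfig, s_bins: np.ndarray) -> np.ndarray:
    """Two-phase power-law decay as a function of separation in bins.

    Continuous at the break: ``s^g1`` below ``drop_distance``,
    ``sb^(g1-g2) * s^g2`` beyond it.  Separation 0 (self) is given the
    value at separation 1.
    """
    s = np.maximum(np.asarray(s_bins, dtype=float), 1.0)
    sb = max(config.drop_distance / config.bin_size, 1.0)
    g1, g2 = config.decay_exponent, config.post_drop_exponent
    pre = s ** g1
    post = sb ** (g1 - g2) * s ** g2
    return np.where(s <= sb, pre, post)


def _cen_tel_masks(truth: SyntheticTruth):
    b = truth.binning
    cfg = truth.config
    ext = cfg.cen_tel_extent
    cen = np.zeros(b.n_bins, dtype=bool)
    tel = np.zeros(b.n_bins, dtype=bool)
    for chrom in b.chrom_names:
        s = b.chrom_slice(chrom)
        starts = np.arange(s.stop - s.start) * cfg.bin_size
        mids = starts + cfg.bin_size / 2
        c = truth.centromeres[chrom]
        cen[s] = np.abs(mids - c) <= ext
        t0, t1 = truth.telomeres[chrom]
        tel[s] = (mids - t0 <= ext) | (t1 - mids <= ext)
    return cen, tel


def _centromere_distance(truth: SyntheticTruth) -> np.ndarray:
    """Distance of each bin midpoint to its chromosome's centromere (bp)."""
    b = truth.binning
    cfg = truth.config
    out = np.empty(b.n_bins)
    for chrom in b.chrom_names:
        s = b.chrom_slice(chrom)
        mids = np.arange(s.stop - s.start) * cfg.bin_size + cfg.bin_size / 2
        out[s] = np.abs(mids - truth.centromeres[chrom])
    return out


def _arm_id(truth: SyntheticTruth) -> np.ndarray:
    """Integer arm identifier (2 per chromosome)."""
    b = truth.binning
    cfg = truth.config
    out = np.empty(b.n_bins, dtype=int)
    for k, chrom in enumerate(b.chrom_names):
        s = b.chrom_slice(chrom)
        mids = np.arange(s.stop - s.start) * cfg.bin_size + cfg.bin_size / 2
        out[s] = 2 * k + (mids > truth.centromeres[chrom]).astype(int)
    return out


def expected_matrix(config: SyntheticGenomeConfig, truth: SyntheticTruth) -> np.ndarray:
    """Noise-free expectation of every pixel: the documented product formula.

    cis (same chromosome):
        mean_scale * decay(s) * comp(i,j) * tad(i,j) * rabl(i,j) * loop(i,j)
    trans:
        trans_base    *         comp=1   *           rabl(i,j) * loop(i,j)
    where ``trans_base`` is set from the realized mean cis expectation so that
    the pooled cis/trans ratio equals ``config.cis_trans_ratio`` when the Rabl
    multipliers are 1.
    """
    b = config.binning
    n = b.n_bins
    cid = b.chrom_id_of_bins()
    same_chrom = cid[:, None] == cid[None, :]

    # distance decay on cis blocks
    m = np.zeros((n, n))
    for chrom in b.chrom_names:
        s = b.chrom_slice(chrom)
        nb = s.stop - s.start
        d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
        m[s, s] = config.mean_scale * decay_curve(config, d)

    # compartment plaid (cis only; trans compartmentalization not modeled),
    # attenuated with distance when configured
    sign = truth.labels_signed()
    like = sign[:, None] == sign[None, :]
    for chrom in b.chrom_names:
        s = b.chrom_slice(chrom)
        nb = s.stop - s.start
        d_bp = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :]) * config.bin_size
        aff = config.compartment_affinity - 1.0
        if config.compartment_attenuation_distance:
            aff = aff * np.exp(-d_bp / config.compartment_attenuation_distance)
        m[s, s] *= np.where(like[s, s], 1.0 + aff, 1.0)

    # TAD blocks
    same_tad = truth.tad_id[:, None] == truth.tad_id[None, :]
    m *= np.where(same_tad & same_chrom, config.tad_enrichment, 1.0)

    # trans baseline from realized cis mean
    off_diag_cis = same_chrom & ~np.eye(n, dtype=bool)
    mean_cis = m[off_diag_cis].mean()
    trans_base = mean_cis / config.cis_trans_ratio
    m[~same_chrom] = trans_base

    # Rabl terms: inter-arm wing + centromere/telomere clusters
    arm = _arm_id(truth)
    diff_arm = arm[:, None] != arm[None, :]
    if config.rabl_strength != 1.0:
        d_cen = _centromere_distance(truth)
        gap = np.abs(d_cen[:, None] - d_cen[None, :])
        wing = 1.0 + (config.rabl_strength - 1.0) * np.exp(-gap / config.rabl_wing_scale)
        m *= np.where(diff_arm, wing, 1.0)
    if config.cen_tel_multiplier != 1.0:
        cen, tel = _cen_tel_masks(truth)
        cen_cen = cen[:, None] & cen[None, :] & diff_arm
        tel_tel = tel[:, None] & tel[None, :] & diff_arm
        m = np.where(cen_cen | tel_tel, m * config.cen_tel_multiplier, m)
        if config.couple_cen_tel:
            cen_tel = ((cen[:, None] & tel[None, :]) | (tel[:, None] & cen[None, :])) & diff_arm
            m = np.where(cen_tel, m * config.cen_tel_multiplier, m)

    # loops
    for lp in truth.loops:
        ia = b.bin_index(lp.chrom_a, lp.pos_a)
        ib = b.bin_index(lp.chrom_b, lp.pos_b)
        half = max(0, lp.size_bp // (2 * config.bin_size))
        sl_a = slice(max(ia - half, 0), ia + half + 1)
        sl_b = slice(max(ib - half, 0), ib + half + 1)
        m[sl_a, sl_b] *= lp.fold
        m[sl_b, sl_a] *= lp.fold

    return 0.5 * (m + m.T)


def simulate_contact_map(
    config: SyntheticGenomeConfig, truth: SyntheticTruth, seed: int
) -> BinnedContactMap:
    """Sample Poisson counts around :func:`expected_matrix`, symmetrized."""
    mean = expected_matrix(config, truth)
    if np.nanmax(mean) > 1e12:
        raise ValueError("expected counts overflow the sampling scale")
    rng = np.random.default_rng(seed)
    n = mean.shape[0]
    upper = np.triu(rng.poisson(mean).astype(float))
    counts = upper + np.triu(upper, 1).T
    return BinnedContactMap(config.binning, counts)


def simulate_map(config: SyntheticGenomeConfig, seed: int):
    """Convenience: truth + sampled map from one seed."""
    truth = simulate_truth(config, seed)
    cmap = simulate_contact_map(config, truth, seed + 1)
    return cmap, truth


# ---------------------------------------------------------------------------
# Tracks correlated with compartments
# ---------------------------------------------------------------------------

DEFAULT_TRACK_EFFECTS = {"gene_density": 2.0, "expression": 3.0, "gc": 1.05}


def simulate_tracks(
    config: SyntheticGenomeConfig,
    truth: SyntheticTruth,
    seed: int,
    effects: dict | None = None,
    noise_cv: float = 0.35,
) -> dict:
    """Per-bin gene density / expression / GC tracks whose A-bin means exceed
    B-bin means by the configured ratio (``effects[name]`` = A mean / B mean;
    ratio 1 is the null).  Values are Gamma-distributed with coefficient of
    variation ``noise_cv``."""
    if effects is None:
        effects = dict(DEFAULT_TRACK_EFFECTS)
    for name, ratio in effects.items():
        if ratio <= 0:
            raise ValueError(f"effect ratio for {name} must be positive")
    rng = np.random.default_rng(seed)
    is_a = truth.labels == "A"
    shape = 1.0 / noise_cv ** 2
    out = {}
    base_means = {"gene_density": 10.0, "expression": 20.0, "gc": 40.0}
    for name, ratio in effects.items():
        base = base_means.get(name, 1.0)
        mean = np.where(is_a, base * ratio, base)
        vals = rng.gamma(shape, mean / shape)
        out[name] = GenomicTrack(truth.binning, vals, name=name)
    return out


# ---------------------------------------------------------------------------
# Rearrangement histories over a species tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RearrangementEvent:
    kind: str                 # inversion | transposition | translocation
    chrom: str
    start_idx: int            # segment-slice start (pre-event coordinates)
    end_idx: int              # slice end (exclusive)
    dest_chrom: str | None = None
    dest_idx: int | None = None


@dataclass
class RearrangementTruth:
    """Ground truth of a simulated multi-species rearrangement history."""

    tree: "dendropy.Tree"
    base_genome: dict          # chrom -> list of signed segment ids
    seg_lengths: dict          # id -> bp
    node_genomes: dict         # branch key (frozenset of leaf taxa) -> genome
    histories: dict            # branch key -> list[RearrangementEvent]
    leaf_genomes: dict         # taxon label -> genome

    def branch_key_of_node(self, node) -> frozenset:
        return frozenset(l.taxon.label for l in node.leaf_iter())


def _genome_adjacencies(genome: dict) -> set:
    """Canonical oriented adjacencies between consecutive segments."""
    adj = set()
    for segs in genome.values():
        for u, v in zip(segs, segs[1:]):
            adj.add(_canon_adj(u, v))
    return adj


def _canon_adj(u: int, v: int) -> tuple:
    return min((u, v), (-v, -u))


def _apply_event(genome: dict, ev: RearrangementEvent) -> dict:
    g = {c: list(s) for c, s in genome.items()}
    segs = g[ev.chrom]
    piece = segs[ev.start_idx : ev.end_idx]
    if ev.kind == "inversion":
        g[ev.chrom] = (
            segs[: ev.start_idx] + [-x for x in reversed(piece)] + segs[ev.end_idx :]
        )
    elif ev.kind in ("transposition", "translocation"):
        rest = segs[: ev.start_idx] + segs[ev.end_idx :]
        g[ev.chrom] = rest
        dest = g[ev.dest_chrom] if ev.dest_chrom != ev.chrom else g[ev.chrom]
        dest[ev.dest_idx : ev.dest_idx] = piece
    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")
    return g


def replay_history(base_genome: dict, events) -> dict:
    """Re-apply recorded events to the base genome (truth verification)."""
    g = {c: list(s) for c, s in base_genome.items()}
    for ev in events:
        g = _apply_event(g, ev)
    return g


def _draw_event(rng, genome: dict, event_mix: dict) -> RearrangementEvent:
    kinds = list(event_mix)
    probs = np.array([event_mix[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    for _ in range(200):
        kind = rng.choice(kinds, p=probs)
        chroms = [c for c, s in genome.items() if len(s) >= 3]
        if not chroms:
            raise ValueError("no chromosome long enough for an event")
        chrom = chroms[rng.integers(len(chroms))]
        n = len(genome[chrom])
        if kind == "inversion":
            # keep at least one segment on each side so both junctions are internal
            i = int(rng.integers(1, n - 1))
            j = int(rng.integers(i + 1, n))
            return RearrangementEvent("inversion", chrom, i, j)
        ln = int(rng.integers(1, max(2, n // 3)))
        i = int(rng.integers(1, n - ln))
        j = i + ln
        if kind == "transposition":
            rest = n - ln
            k = int(rng.integers(1, rest))
            if k == i:  # reinserting in place is a no-op
                continue
            return RearrangementEvent("transposition", chrom, i, j, dest_chrom=chrom, dest_idx=k)
        others = [c for c in genome if c != chrom and len(genome[c]) >= 1]
        if not others:
            continue
        dest = others[rng.integers(len(others))]
        k = int(rng.integers(1, max(2, len(genome[dest]))))
        return RearrangementEvent("translocation", chrom, i, j, dest_chrom=dest, dest_idx=k)
    raise RuntimeError("could not draw a valid event")


def simulate_rearrangements(
    tree,
    events_per_branch: int = 1,
    event_mix: dict | None = None,
    n_chroms: int = 3,
    segments_per_chrom: int = 40,
    mean_segment_bp: int = 500_000,
    seed: int = 0,
) -> RearrangementTruth:
    """Evolve a segmented base genome along ``tree`` (dendropy Tree).

    Each branch receives exactly ``events_per_branch`` events drawn from
    ``event_mix`` (default inversion-dominated, mirroring the rarity of
    inter-chromosomal translocations).  Genomes at every internal node are
    recorded, so every breakpoint can be attributed to its branch by replay.
    """
    if event_mix is None:
        event_mix = {"inversion": 0.8, "transposition": 0.15, "translocation": 0.05}
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves (including the outgroup)")
    if mean_segment_bp <= 0:
        raise ValueError("zero-length segments requested")
    rng = np.random.default_rng(seed)
    seg_lengths = {}
    base = {}
    sid = 1
    for c in range(n_chroms):
        segs = []
        for _ in range(segments_per_chrom):
            seg_lengths[sid] = int(max(mean_segment_bp * 0.2, rng.exponential(mean_segment_bp)))
            segs.append(sid)
            sid += 1
        base[f"chr{c + 1}"] = segs

    node_genomes = {}
    histories = {}
    leaf_genomes = {}

    def key_of(node):
        return frozenset(l.taxon.label for l in node.leaf_iter())

    root = tree.seed_node
    node_genomes[key_of(root)] = base
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_g = node_genomes[key_of(node.parent_node)]
        events = []
        g = parent_g
        for _ in range(events_per_branch):
            ev = _draw_event(rng, g, event_mix)
            g = _apply_event(g, ev)
            events.append(ev)
        k = key_of(node)
        node_genomes[k] = g
        histories[k] = events
        if node.is_leaf():
            leaf_genomes[node.taxon.label] = g
    return RearrangementTruth(
        tree=tree,
        base_genome=base,
        seg_lengths=seg_lengths,
        node_genomes=node_genomes,
        histories=histories,
        leaf_genomes=leaf_genomes,
    )


# -- alignment blocks between two leaf genomes ------------------------------

def _segment_positions(genome: dict, seg_lengths: dict) -> dict:
    """Map |segment id| -> (chrom, order index, sign, start_bp, end_bp)."""
    pos = {}
    for chrom, segs in genome.items():
        starts = np.cumsum([0] + [seg_lengths[abs(s)] for s in segs[:-1]])
        for k, (s, st) in enumerate(zip(segs, starts)):
            pos[abs(s)] = (chrom, k, 1 if s > 0 else -1, int(st), int(st + seg_lengths[abs(s)]))
    return pos


def alignment_blocks(genome_a: dict, genome_b: dict, seg_lengths: dict) -> pd.DataFrame:
    """Exact pairwise alignment blocks of the simulated homology.

    Maximal runs of segments consecutive and consistently oriented in both
    genomes become one block; columns follow the alignment-block TSV layout
    (a_chrom, a_start, a_end, b_chrom, b_start, b_end, strand).
    """
    pos_b = _segment_positions(genome_b, seg_lengths)
    rows = []
    for chrom_a, segs in genome_a.items():
        starts_a = np.cumsum([0] + [seg_lengths[abs(s)] for s in segs[:-1]])
        run = []  # list of (a_idx, sid_signed)
        def flush(run):
            if not run:
                return
            first, last = run[0], run[-1]
            a_start = int(starts_a[first[0]])
            a_end = int(starts_a[last[0]] + seg_lengths[abs(last[1])])
            b_spans = [pos_b[abs(s)][3:5] for _, s in run]
            b_chrom = pos_b[abs(run[0][1])][0]
            b_start = min(sp[0] for sp in b_spans)
            b_end = max(sp[1] for sp in b_spans)
            a_sign = 1 if run[0][1] > 0 else -1
            strand = "+" if a_sign * pos_b[abs(run[0][1])][2] > 0 else "-"
            rows.append((chrom_a, a_start, a_end, b_chrom, b_start, b_end, strand))

        prev = None
        for k, s in enumerate(segs):
            bc, bi, bs, _, _ = pos_b[abs(s)]
            sa = 1 if s > 0 else -1
            orient = sa * bs  # +1 if same strand in both genomes
            ok = False
            if prev is not None:
                pbc, pbi, porient = prev
                ok = bc == pbc and orient == porient and bi - pbi == orient
            if ok:
                run.append((k, s))
            else:
                flush(run)
                run = [(k, s)]
            prev = (bc, bi, orient)
        flush(run)
    df = pd.DataFrame(rows, columns=["a_chrom", "a_start", "a_end", "b_chrom", "b_start", "b_end", "strand"])
    return df.sort_values(["a_chrom", "a_start"]).reset_index(drop=True)


def true_ebrs(
    truth: RearrangementTruth, leaf_a: str, leaf_b: str
) -> pd.DataFrame:
    """Breakpoints between leaf_a (reference coordinates) and leaf_b, each
    attributed to the branch (leaf-set key) on which the adjacency changed."""
    genome_a = truth.leaf_genomes[leaf_a]
    genome_b = truth.leaf_genomes[leaf_b]
    adj_b = _genome_adjacencies(genome_b)
    # node path from a to b through the MRCA, as genome lookups
    taxa = {l.taxon.label: l for l in truth.tree.leaf_node_iter()}
    na, nb = taxa[leaf_a], taxa[leaf_b]
    anc_a = [na] + list(na.ancestor_iter())
    anc_b = [nb] + list(nb.ancestor_iter())
    set_a = set(id(x) for x in anc_a)
    mrca = next(x for x in anc_b if id(x) in set_a)
    path_a = []  # mrca -> ... -> a
    for x in anc_a:
        path_a.append(x)
        if x is mrca:
            break
    path_a = list(reversed(path_a))
    path_b = []
    for x in anc_b:
        path_b.append(x)
        if x is mrca:
            break
    path_b = list(reversed(path_b))

    def genome_at(node):
        return truth.node_genomes[frozenset(l.taxon.label for l in node.leaf_iter())]

    rows = []
    for chrom, segs in genome_a.items():
        starts = np.cumsum([0] + [truth.seg_lengths[abs(s)] for s in segs[:-1]])
        for k, (u, v) in enumerate(zip(segs, segs[1:])):
            a = _canon_adj(u, v)
            if a in adj_b:
                continue
            pos = int(starts[k] + truth.seg_lengths[abs(u)])
            branch = _attribute_branch(a, path_a, path_b, genome_at)
            rows.append((chrom, pos, branch))
    return pd.DataFrame(rows, columns=["chrom", "pos", "branch"])


def _attribute_branch(adj, path_a, path_b, genome_at):
    """Branch on which an adjacency (present in A, absent in B) changed."""
    present_mrca = adj in _genome_adjacencies(genome_at(path_a[0]))
    if present_mrca:
        # broken somewhere on the B side
        for node in path_b[1:]:
            if adj not in _genome_adjacencies(genome_at(node)):
                return frozenset(l.taxon.label for l in node.leaf_iter())
    else:
        # created somewhere on the A side
        for node in path_a[1:]:
            if adj in _genome_adjacencies(genome_at(node)):
                return frozenset(l.taxon.label for l in node.leaf_iter())
    return None
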