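"""Synteny-block merging, EBR calling, phylogenetic lineage classification,
ancestral chromatin states at junctions, matched randomization and the
compartment-switch test.

Alignment blocks are pairwise homologous intervals (reference species A vs
species B) with a relative orientation.  Consecutive blocks are iteratively
merged under four rules — same A orientation, same B orientation, both gaps
under ``gap_max``, gap-length difference under ``gap_diff_max`` — to a fixed
point, then length-filtered.  A breakpoint (EBR) is a reference-genome
adjacency whose B-side counterparts are not adjacent in compatible order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Binning
from .tracks import GenomicTrack, regions_to_bin_mask

BLOCK_COLUMNS = ["a_chrom", "a_start", "a_end", "b_chrom", "b_start", "b_end", "strand"]


def read_alignment_blocks(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BLOCK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[BLOCK_COLUMNS + [c for c in df.columns if c not in BLOCK_COLUMNS]]


def write_alignment_blocks(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _check_no_overlap(df: pd.DataFrame) -> None:
    for chrom, sub in df.groupby("a_chrom"):
        sub = sub.sort_values("a_start")
        prev_end, prev_idx = -1, None
        for idx, row in sub.iterrows():
            if row["a_start"] < prev_end:
                raise ValueError(
                    f"overlapping blocks on {chrom}: rows {prev_idx} and {idx}"
                )
            prev_end, prev_idx = row["a_end"], idx


def _try_merge(r1: dict, r2: dict, gap_max: int, gap_diff_max: int) -> dict | None:
    """Merge two A-consecutive blocks if the four rules hold, else None."""
    if r1["strand"] != r2["strand"]:
        return None  # rules 1/2: orientations must agree in both species
    if r1["b_chrom"] != r2["b_chrom"]:
        return None
    gap_a = r2["a_start"] - r1["a_end"]
    if gap_a < 0:
        return None
    # B-side adjacency consistent with orientation: on '+' the B images run
    # left-to-right with A; on '-' they run right-to-left
    if r1["strand"] == "+":
        gap_b = r2["b_start"] - r1["b_end"]
    else:
        gap_b = r1["b_start"] - r2["b_end"]
    if gap_b < 0:
        return None
    if gap_a >= gap_max or gap_b >= gap_max:
        return None  # rule 3
    if abs(gap_a - gap_b) >= gap_diff_max:
        return None  # rule 4
    return dict(
        a_chrom=r1["a_chrom"],
        a_start=r1["a_start"],
        a_end=r2["a_end"],
        b_chrom=r1["b_chrom"],
        b_start=min(r1["b_start"], r2["b_start"]),
        b_end=max(r1["b_end"], r2["b_end"]),
        strand=r1["strand"],
    )


def _merge_pass(df: pd.DataFrame, gap_max: int, gap_diff_max: int, min_len: int) -> pd.DataFrame:
    """One round: merge A-consecutive blocks to a fixed point, then filter."""
    out = []
    for chrom, sub in df.groupby("a_chrom", sort=False):
        rows = [dict(r) for _, r in sub.sort_values("a_start").iterrows()]
        changed = True
        while changed:
            changed = False
            merged = []
            i = 0
            while i < len(rows):
                if i + 1 < len(rows):
                    m = _try_merge(rows[i], rows[i + 1], gap_max, gap_diff_max)
                    if m is not None:
                        rows[i + 1] = m
                        changed = True
                        i += 1
                        continue
                merged.append(rows[i])
                i += 1
            rows = merged
        out.extend(rows)
    new = pd.DataFrame(out, columns=BLOCK_COLUMNS)
    new = new[new["a_end"] - new["a_start"] >= min_len]
    return new.sort_values(["a_chrom", "a_start"]).reset_index(drop=True)


def merge_synteny_blocks(
    blocks: pd.DataFrame,
    gap_max: int = 150_000,
    gap_diff_max: int = 100_000,
    min_len: int = 15_000,
) -> pd.DataFrame:
    """Iterate the four-rule merge over A-consecutive blocks to a fixed
    point, then drop blocks shorter than ``min_len`` in the reference.

    Filtering can expose a new mergeable adjacency (a short block sat
    between two compatible neighbors), so merge and filter alternate until
    jointly stable: re-running on the output changes nothing.
    """
    _check_no_overlap(blocks)
    df = _merge_pass(blocks, gap_max, gap_diff_max, min_len)
    while True:
        new = _merge_pass(df, gap_max, gap_diff_max, min_len)
        if new.equals(df):
            return new
        df = new


# ---------------------------------------------------------------------------
# EBR calling
# ---------------------------------------------------------------------------

@dataclass
class EBR:
    species_pair: tuple
    chrom: str
    start: int
    end: int
    lineage_class: str = "unassigned"
    ancestral_reference: str | None = None

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _b_adjacent(r1, r2, b_gap_max: int = 0) -> bool:
    """True if the B-side images of two A-consecutive blocks are contiguous
    (gap <= b_gap_max) in order/orientation compatible with collinearity."""
    if r1["b_chrom"] != r2["b_chrom"] or r1["strand"] != r2["strand"]:
        return False
    gap = (r2["b_start"] - r1["b_end"]) if r1["strand"] == "+" else (r1["b_start"] - r2["b_end"])
    return 0 <= gap <= b_gap_max


def call_ebrs(
    merged: pd.DataFrame,
    species_pair: tuple = ("A", "B"),
    exclusion_regions: pd.DataFrame | None = None,
    b_gap_max: int = 0,
) -> list:
    """One EBR per reference adjacency whose B neighbors are non-adjacent,
    reordered or reoriented; the EBR interval is the inter-block gap.  EBRs
    overlapping ``exclusion_regions`` (BED frame) are dropped."""
    ebrs = []
    for chrom, sub in merged.groupby("a_chrom", sort=False):
        rows = [dict(r) for _, r in sub.sort_values("a_start").iterrows()]
        for r1, r2 in zip(rows, rows[1:]):
            if _b_adjacent(r1, r2, b_gap_max):
                continue
            ebrs.append(EBR(species_pair=tuple(species_pair), chrom=chrom,
                            start=int(r1["a_end"]), end=int(r2["a_start"])))
    if exclusion_regions is not None and len(exclusion_regions):
        kept = []
        for e in ebrs:
            sub = exclusion_regions[exclusion_regions["chrom"] == e.chrom]
            hit = ((sub["start"] < max(e.end, e.start + 1)) & (sub["end"] > e.start)).any()
            if not hit:
                kept.append(e)
        ebrs = kept
    return ebrs


def ebrs_to_frame(ebrs: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(chrom=e.chrom, start=e.start, end=e.end, species=e.species_pair[1],
                 lineage_class=e.lineage_class)
            for e in ebrs
        ],
        columns=["chrom", "start", "end", "species", "lineage_class"],
    )


# ---------------------------------------------------------------------------
# Lineage classification
# ---------------------------------------------------------------------------

def species_abbrev(name: str) -> str:
    """'An. albimanus' / 'albimanus' -> 'Aalb'."""
    core = name.split(".")[-1].strip().replace("_", " ").split()[-1]
    return "A" + core[:3].lower()


def branch_classes(tree, reference: str, outgroup: str) -> dict:
    """Map each branch (frozenset of leaf labels below it) to its EBR class
    label and to the presence pattern it implies in reference-vs-X
    comparisons.

    A single event on branch ``b`` produces an EBR in the (reference, X)
    comparison iff exactly one of reference and X descends from ``b``.
    Terminal branches are labeled by species abbreviation + '*', internal
    branches by the number of ingroup descendants + 'A*'.
    """
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    others = [l for l in leaves if l != reference]
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(clade) == len(leaves):
            continue
        if len(clade) == 1:
            label = species_abbrev(next(iter(clade))) + "*"
        else:
            n_in = len([x for x in clade if x != outgroup])
            label = f"{n_in}A*"
        ref_in = reference in clade
        pattern = frozenset(x for x in others if (x in clade) != ref_in)
        out[clade] = dict(label=label, pattern=pattern)
    return out


def cluster_ebrs(ebrs_by_species: dict, match_tolerance_bp: int = 25_000) -> list:
    """Group EBRs from multiple reference-vs-X comparisons by reference
    position (single-linkage within ``match_tolerance_bp``)."""
    items = []
    for sp, ebrs in ebrs_by_species.items():
        for e in ebrs:
            items.append((e.chrom, e.midpoint, sp, e))
    items.sort(key=lambda t: (t[0], t[1]))
    clusters = []
    for chrom, pos, sp, e in items:
        if clusters and clusters[-1]["chrom"] == chrom and pos - clusters[-1]["last_pos"] <= match_tolerance_bp:
            clusters[-1]["members"].append((sp, e))
            clusters[-1]["last_pos"] = pos
        else:
            clusters.append(dict(chrom=chrom, last_pos=pos, members=[(sp, e)]))
    return clusters


def classify_ebr_lineages(
    ebrs_by_species: dict,
    tree,
    reference: str,
    outgroup: str,
    match_tolerance_bp: int = 25_000,
) -> pd.DataFrame:
    """Assign each cross-comparison EBR cluster to the tree branch whose
    presence/absence pattern it implies.

    Patterns matching no single branch but the union of two branches
    (independent events in two lineages, absent from their ancestor with
    respect to the outgroup) are labeled ``reused^``; anything else is
    ``unassigned``.  Also stamps ``lineage_class`` onto the member EBRs.
    """
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) == 0:
        raise ValueError("tree is empty")
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    for sp in list(ebrs_by_species) + [reference, outgroup]:
        if sp not in labels:
            raise ValueError(f"species {sp!r} absent from tree")
    classes = branch_classes(tree, reference, outgroup)
    # the two branches flanking the root imply identical patterns (the root
    # edge is one edge of the unrooted tree); tie-break to the smaller clade,
    # naming the event by the lineage it separates
    by_pattern = {}
    for clade, info in sorted(classes.items(), key=lambda kv: len(kv[0])):
        by_pattern.setdefault(info["pattern"], info["label"])
    clusters = cluster_ebrs(ebrs_by_species, match_tolerance_bp)
    rows = []
    clade_list = list(classes.items())
    for cl in clusters:
        present = frozenset(sp for sp, _ in cl["members"])
        label = by_pattern.get(present)
        if label is None:
            label = _reused_or_unassigned(present, clade_list, outgroup)
        for _, e in cl["members"]:
            e.lineage_class = label
        pos = int(np.mean([e.midpoint for _, e in cl["members"]]))
        rows.append(dict(chrom=cl["chrom"], pos=pos, lineage_class=label,
                         n_comparisons=len(cl["members"]),
                         species=",".join(sorted(present))))
    return pd.DataFrame(rows, columns=["chrom", "pos", "lineage_class", "n_comparisons", "species"])


def _reused_or_unassigned(present: frozenset, clade_list: list, outgroup: str) -> str:
    """Two-branch explanation: the union of two branch patterns, where
    neither branch is ancestral to the other and the outgroup-rooted
    ancestor shows no event."""
    for i in range(len(clade_list)):
        ci, info_i = clade_list[i]
        for j in range(i + 1, len(clade_list)):
            cj, info_j = clade_list[j]
            if ci <= cj or cj <= ci:
                continue  # nested: their union is a single-lineage story
            if info_i["pattern"] | info_j["pattern"] == present and info_i["pattern"] and info_j["pattern"]:
                return "reused^"
    return "unassigned"


# ---------------------------------------------------------------------------
# Ancestral states at EBR junctions and the switch test
# ---------------------------------------------------------------------------

def _tree_distance(tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return pdm.distance(ta, tb)


def _locus_in_b(row: dict, a_pos_is_end: bool) -> int:
    """Map a junction-side end of an A-block into B coordinates."""
    if (row["strand"] == "+") == a_pos_is_end:
        return int(row["b_end"])
    return int(row["b_start"])


def ancestral_state_at_ebr(
    ebr: EBR,
    event_clade: frozenset,
    tree,
    reference: str,
    cepc1_by_species: dict,
    blocks_by_species: dict,
) -> dict | None:
    """cePC1 at the four loci around an EBR junction, read in the closest
    species retaining the ancestral segment order.

    Loci 1 and 4 are the two ends newly joined by the rearrangement; 2 and 3
    are their ancestral neighbors.  The ancestral species is the reference
    itself when the causative event lies outside the reference's lineage,
    otherwise the phylogenetically closest leaf outside the event clade.
    Returns None (with no states) when no species retains ancestral order.
    """
    if event_clade is None:
        return None
    candidates = [l.taxon.label for l in tree.leaf_node_iter() if l.taxon.label not in event_clade]
    if reference not in event_clade:
        anc = reference
    else:
        candidates = [c for c in candidates if c in cepc1_by_species and c in blocks_by_species]
        if not candidates:
            return None
        anc = min(candidates, key=lambda c: _tree_distance(tree, reference, c))
    other = ebr.species_pair[1]
    if anc == reference:
        # reference holds the ancestral joint; the derived joint lives in the
        # other species — read loci 1/2 directly, map the derived neighbor
        # back through the pair's blocks for loci 3/4
        track = cepc1_by_species.get(reference)
        if track is None:
            return None
        blocks = blocks_by_species[other]
        left, right = _junction_blocks(blocks, ebr)
        if left is None:
            return None
        loci = {
            1: (ebr.chrom, int(left["a_end"]) - 1),
            2: (ebr.chrom, int(right["a_start"])),
        }
        nbr = _derived_neighbor(blocks, left)
        if nbr is None:
            return None
        loci[4] = (nbr["a_chrom"], _locus_a_side(nbr, left))
        loci[3] = (nbr["a_chrom"], _ancestral_neighbor_pos(nbr, loci[4][1]))
        read = track
    else:
        # reference is derived: map both junction flanks into the ancestral
        # species and take their ancestral neighbors there
        track = cepc1_by_species[anc]
        blocks = blocks_by_species[anc]
        left, right = _junction_blocks(blocks, ebr)
        if left is None:
            return None
        def inside_and_beyond(row, a_pos_is_end):
            edge = _locus_in_b(row, a_pos_is_end)
            if edge == int(row["b_end"]):
                return edge - 1, edge          # junction faces increasing B
            return edge, max(0, edge - 1)      # junction faces decreasing B

        l1, l2 = inside_and_beyond(left, a_pos_is_end=True)
        l4, l3 = inside_and_beyond(right, a_pos_is_end=False)
        loci = {
            1: (left["b_chrom"], l1),
            2: (left["b_chrom"], l2),
            4: (right["b_chrom"], l4),
            3: (right["b_chrom"], l3),
        }
        read = track
    states = {}
    binning = read.binning
    for k, (chrom, pos) in loci.items():
        if chrom not in binning.offsets:
            return None
        pos = int(np.clip(pos, 0, binning.chrom_lengths[binning.chrom_names.index(chrom)] - 1))
        states[k] = float(read.values[binning.bin_index(chrom, pos)])
    return dict(ancestral_species=anc, loci=loci, states=states)


def _junction_blocks(blocks: pd.DataFrame, ebr: EBR):
    sub = blocks[blocks["a_chrom"] == ebr.chrom].sort_values("a_start")
    left = sub[sub["a_end"] <= ebr.start + 1]
    right = sub[sub["a_start"] >= ebr.end - 1]
    if left.empty or right.empty:
        return None, None
    return dict(left.iloc[-1]), dict(right.iloc[0])


def _derived_neighbor(blocks: pd.DataFrame, left: dict):
    """Block adjacent (in B order) to the B image of ``left``'s junction end."""
    sub = blocks[blocks["b_chrom"] == left["b_chrom"]].sort_values("b_start").reset_index(drop=True)
    pos = sub.index[(sub["a_start"] == left["a_start"]) & (sub["a_chrom"] == left["a_chrom"])]
    if len(pos) == 0:
        return None
    i = int(pos[0])
    # junction end of `left` in B: right edge if '+', left edge if '-'
    nbr_i = i + 1 if left["strand"] == "+" else i - 1
    if not 0 <= nbr_i < len(sub):
        return None
    return dict(sub.iloc[nbr_i])


def _locus_a_side(nbr: dict, left: dict = None) -> int:
    # the end of the neighbor facing the derived junction, in A coordinates
    return int(nbr["a_start"]) if nbr["strand"] == "+" else int(nbr["a_end"]) - 1


def _ancestral_neighbor_pos(nbr: dict, locus4_pos: int) -> int:
    # locus 3 is just beyond locus 4 on its ancestral (A) side
    if locus4_pos == int(nbr["a_start"]):
        return max(0, locus4_pos - 1)
    return locus4_pos + 1


def compartment_switch_test(
    quadruples: list,
    n_perm: int = 1000,
    seed: int = 0,
    min_quadruples: int = 20,
) -> dict:
    """Probability that the two newly joined loci (1 vs 4) differ in A/B
    state, against a null of randomly re-paired synteny-block ends.

    ``quadruples`` is a list of dicts with at least states[1] and states[4]
    (signed cePC1 values; A is positive).  Two-sided p-value from ``n_perm``
    seeded re-pairings.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(quadruples) < min_quadruples:
        raise ValueError(f"need >= {min_quadruples} EBRs with ancestral states")
    a = np.array([q["states"][1] > 0 for q in quadruples])
    b = np.array([q["states"][4] > 0 for q in quadruples])
    observed = float(np.mean(a != b))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.mean(a != rng.permutation(b))
    center = null.mean()
    p = (1 + np.sum(np.abs(null - center) >= abs(observed - center))) / (n_perm + 1)
    return dict(observed=observed, null=null, null_mean=float(center), p=float(p), n=len(quadruples))


# ---------------------------------------------------------------------------
# Matched randomization and regional profiles
# ---------------------------------------------------------------------------

def matched_random_regions(
    feature_track: GenomicTrack,
    target_regions: pd.DataFrame,
    n_samples: int = 1000,
    n_bins_hist: int = 10,
    seed: int = 0,
    mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Random genomic bins whose feature-value histogram matches the target
    regions' histogram (``n_bins_hist`` equal-count bins of the target
    distribution), sampled outside ``mask``; seeded and reproducible."""
    binning = feature_track.binning
    tmask = regions_to_bin_mask(target_regions, binning)
    tvals = feature_track.values[tmask]
    tvals = tvals[np.isfinite(tvals)]
    if tvals.size == 0:
        raise ValueError("target regions carry no feature values")
    qs = np.quantile(tvals, np.linspace(0, 1, n_bins_hist + 1))
    qs[-1] = np.nextafter(qs[-1], np.inf)  # make the top edge inclusive
    # tied feature values collapse quantile edges; drop the duplicates and
    # give each surviving bin a quota proportional to its target mass
    qs = np.unique(qs)
    n_bins = qs.size - 1
    target_counts = np.histogram(tvals, bins=np.r_[qs[:-1], np.inf])[0]
    prop = target_counts / target_counts.sum()
    quota = np.floor(prop * n_samples).astype(int)
    short = n_samples - quota.sum()
    order = np.argsort(-(prop * n_samples - quota))
    quota[order[:short]] += 1
    avail = np.isfinite(feature_track.values)
    if mask is not None and len(mask):
        avail &= ~regions_to_bin_mask(mask, binning)
    rng = np.random.default_rng(seed)
    chosen = []
    fv = feature_track.values
    for k in range(n_bins):
        if quota[k] == 0:
            continue
        in_bin = avail & (fv >= qs[k]) & (fv < qs[k + 1])
        pool = np.where(in_bin)[0]
        if pool.size == 0:
            raise ValueError(
                f"no available genomic bins in target histogram bin {k} "
                f"[{qs[k]:.4g}, {qs[k + 1]:.4g})"
            )
        take = rng.choice(pool, size=quota[k], replace=pool.size < quota[k])
        chosen.append(take)
    idx = np.concatenate(chosen)
    frame = binning.to_frame().iloc[idx].copy()
    frame["feature"] = fv[idx]
    return frame.reset_index(drop=True)


def profile_at_regions(
    track: GenomicTrack,
    regions: pd.DataFrame,
    flank_bp: int = 100_000,
) -> dict:
    """Center values and the averaged +/- flank profile of a track over a
    region set."""
    if regions is None or len(regions) == 0:
        raise ValueError("empty region set")
    binning = track.binning
    f = flank_bp // binning.bin_size
    centers = []
    profiles = []
    for _, r in regions.iterrows():
        chrom = r["chrom"]
        if chrom not in binning.offsets:
            continue
        mid = (int(r["start"]) + int(r["end"])) // 2
        mid = min(mid, binning.chrom_lengths[binning.chrom_names.index(chrom)] - 1)
        i = binning.bin_index(chrom, mid)
        centers.append(track.values[i])
        s = binning.chrom_slice(chrom)
        prof = np.full(2 * f + 1, np.nan)
        lo, hi = i - f, i + f + 1
        src_lo, src_hi = max(lo, s.start), min(hi, s.stop)
        prof[src_lo - lo : src_hi - lo] = track.values[src_lo:src_hi]
        profiles.append(prof)
    centers = np.array(centers)
    profiles = np.vstack(profiles) if profiles else np.empty((0, 2 * f + 1))
    with np.errstate(invalid="ignore"):
        mean_profile = np.nanmean(profiles, axis=0) if profiles.size else np.array([])
    return dict(
        center_values=centers,
        mean_profile=mean_profile,
        offsets_bp=(np.arange(-f, f + 1) * binning.bin_size),
        n=len(centers),
    )


def ranksum_between(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p between two region-value distributions."""
    from scipy import stats

    a = values_a[np.isfinite(values_a)]
    b = values_b[np.isfinite(values_b)]
    if a.size == 0 or b.size == 0:
        return np.nan
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
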