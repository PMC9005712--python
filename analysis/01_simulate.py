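#!/usr/bin/env python
"""Generate the study's synthetic genomes and write their ground truth.

Produces the default 50 Mb / 25 kb Rabl-configured genome (wings 2x,
centromere/telomere clusters 3x, compartment affinity 1.5, ~150 kb TADs) and
its Rabl-free counterpart, plus per-bin gene density / expression / GC
tracks.  Everything downstream (02-06) regenerates what it needs from the
same seeds, so this script is a record of the conditions, not a dependency.
"""
import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from rablhic.hic_core import cis_trans_ratio, save_contact_map
from rablhic.synthetic import SyntheticGenomeConfig, simulate_contact_map, simulate_tracks, simulate_truth
from rablhic.tracks import write_bedgraph

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 1


def main():
    os.makedirs(OUT, exist_ok=True)
    for tag, cfg in {
        "rabl": SyntheticGenomeConfig(),
        "norabl": SyntheticGenomeConfig(rabl_strength=1.0, cen_tel_multiplier=1.0),
    }.items():
        truth = simulate_truth(cfg, SEED)
        cmap = simulate_contact_map(cfg, truth, SEED + 1)
        tracks = simulate_tracks(cfg, truth, SEED + 2)
        save_contact_map(cmap, f"{OUT}/map_{tag}.npz", format="npz")
        for name, tr in tracks.items():
            write_bedgraph(tr, f"{OUT}/{tag}_{name}.bedGraph")
        with open(f"{OUT}/truth_{tag}.json", "w") as fh:
            json.dump(dict(labels="".join(truth.labels),
                           tad_boundaries={c: v.tolist() for c, v in truth.tad_boundaries.items()},
                           centromeres=truth.centromeres,
                           rabl_strength=truth.rabl_strength), fh)
        pooled = cis_trans_ratio(cmap).set_index("chrom").loc["genome", "ratio"]
        print(f"{tag}: {cmap.n_bins} bins, pooled cis/trans = {pooled:.2f} "
              f"(configured {cfg.cis_trans_ratio}; Rabl terms raise trans when on)")


if __name__ == "__main__":
    main()
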