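#!/usr/bin/env python
"""Compare compartment callers on Rabl-configured vs Rabl-free maps.

Runs default PC1 and contrast-enhanced PC1 (cePC1) on the same synthetic
genomes and tabulates A/B label accuracy against truth, the correlation of
each eigenvector with truth, and cePC1's correlation with the gene density /
expression / GC tracks.  On the Rabl map the default eigenvector locks onto
centromere/telomere cluster structure and drops to near-chance accuracy,
while cePC1 stays above 0.9 — the motivating observation for contrast
enhancement.  Writes results/compartment_comparison.tsv.
"""
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from rablhic.compartments import compartment_track_correlations, compute_compartments, label_accuracy
from rablhic.hic_core import balance_matrix
from rablhic.synthetic import SyntheticGenomeConfig, simulate_contact_map, simulate_tracks, simulate_truth

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 1


def main():
    os.makedirs(OUT, exist_ok=True)
    rows = []
    for tag, cfg in {
        "rabl": SyntheticGenomeConfig(),
        "norabl": SyntheticGenomeConfig(rabl_strength=1.0, cen_tel_multiplier=1.0),
    }.items():
        truth = simulate_truth(cfg, SEED)
        bal = balance_matrix(simulate_contact_map(cfg, truth, SEED + 1), bad_bin_cov_frac=0)
        tracks = simulate_tracks(cfg, truth, SEED + 2)
        orient = tracks["gene_density"]
        for method in ("default", "cropped", "framed", "contrast_enhanced"):
            kw = {}
            if method == "cropped":
                crop = []
                for chrom in bal.binning.chrom_names:
                    c = truth.centromeres[chrom]
                    crop.append(dict(chrom=chrom, start=c - cfg.cen_tel_extent, end=c + cfg.cen_tel_extent))
                    crop.append(dict(chrom=chrom, start=0, end=cfg.cen_tel_extent))
                    crop.append(dict(chrom=chrom, start=cfg.chrom_length - cfg.cen_tel_extent,
                                     end=cfg.chrom_length))
                kw["crop_regions"] = pd.DataFrame(crop)
            res = compute_compartments(bal, method, orientation_track=orient, **kw)
            fin = np.isfinite(res.cepc1.values)
            r_truth = np.corrcoef(res.cepc1.values[fin], truth.labels_signed()[fin])[0, 1]
            rows.append(dict(map=tag, method=method,
                             accuracy=label_accuracy(res.ab_labels, truth.labels),
                             r_truth=r_truth))
            if method == "contrast_enhanced":
                corr = compartment_track_correlations(res.cepc1, tracks)
                for _, c in corr.iterrows():
                    print(f"  {tag} cePC1 vs {c['track']}: Pearson r = {c['pearson_r']:.2f}")
    df = pd.DataFrame(rows)
    df.to_csv(f"{OUT}/compartment_comparison.tsv", sep="\t", index=False, float_format="%.4f")
    print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))


if __name__ == "__main__":
    main()
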