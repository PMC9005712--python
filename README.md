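# rablhic

Hi-C analysis for genomes in a Rabl-like nuclear configuration — where
centromeres cluster at one pole of the nucleus, telomeres at the other, and
inter-arm "wings" and centromere/telomere blocks dominate the contact map.
The package implements the full analysis stack for such genomes
(insect-like, e.g. mosquito): contact-map balancing and observed/expected
normalization, A/B compartment calling by **contrast-enhanced PC1 (cePC1)**,
insulation-score TAD calling with ±1 Mb frame normalization, two-phase
contact-probability scaling *P(s)*, synteny-block merging and
evolutionary-breakpoint (EBR) lineage classification over a species tree,
feature-matched randomization controls, a compartment-switch test at
rearrangement junctions, long-range loop calling, and Rabl-configuration
quantification. Every estimator is validated on a synthetic-data generator
with known ground truth.

## Who it is for

Researchers analyzing Hi-C maps of species whose standard compartment
eigenvector fails: on Rabl-configured chromosomes the leading eigenvector of
the contact correlation matrix tracks position along the arm (the
centromere–telomere axis and heterochromatin clusters) instead of the
checkerboard compartment signal.

## The core method: contrast enhancement

For a balanced per-chromosome map `C`, compartments are called from

1. **O/E**: `Oij = Cij / E(|i − j|)`, the distance-normalized map;
2. **local smoothing** of O/E (mean over a (2w+1)² neighborhood, default
   w = 1 bin at 25 kb);
3. **Pearson correlation** `Rij = corr(Oi·, Oj·)`;
4. **block normalization** of `R` within ~1 Mb blocks — the "contrast
   enhancement" step that removes slow positional intensity gradients so the
   plaid dominates (sliding-window z-score by default; tiled min–max stretch
   to [−1, 1] available);
5. **PC1** of the enhanced matrix, sign-oriented per chromosome so that the
   gene-dense compartment (A) is positive. `cePC1 > 0 → A`, `< 0 → B`.

Baselines implemented for comparison: default PC1 (correlation matrix
eigenvector), cropping (exclude centromeric/telomeric regions before PCA),
and framing (independent PC1 in consecutive 10 Mb frames).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
genomes (50 Mb, 4 metacentric chromosomes, 25 kb bins; Rabl wing 2×,
centromere/telomere clusters 3×, compartment affinity 1.5):

```bash
python analysis/01_simulate.py
python analysis/02_compartments.py
```

`02_compartments.py` prints the method comparison (seed 1):

```
   map            method  accuracy  r_truth
  rabl           default     0.662    0.276
  rabl           cropped     0.993    0.944
  rabl            framed     0.645    0.336
  rabl contrast_enhanced     0.983    0.929
norabl           default     0.999    0.950
norabl contrast_enhanced     0.990    0.948
```

On the Rabl map the default eigenvector collapses to near-chance label
accuracy (0.66) because it locks onto the centromere/telomere cluster
structure, while cePC1 recovers the true compartments at 0.98; without Rabl
structure the two methods agree. (Cropping also works here because the
synthetic cluster extent is known exactly — on real maps it must be curated,
which is what contrast enhancement avoids.) `04_scaling.py` locates the
phase-I slope minimum at 175 kb (generator TAD length 150 kb) and the slope
drop below −1 at 2.83 Mb (generator break at 3 Mb); `05_synteny_evolution.py`
classifies breakpoint lineages on the five-taxon tree and reproduces the
gene-density confounder: breakpoint insulation (−3.26) falls inside the
envelope of gene-density-matched controls ([−3.27, −3.20]) but far outside
naive random controls ([−2.08, −1.88]).

A CLI mirrors the library for shell use:

```bash
rablhic simulate --seed 1 --out sim
rablhic balance sim.map.npz --out bal.npz
rablhic compartments bal.npz --method ce --out cepc1.bedGraph
rablhic tads bal.npz --out tads.bed
```

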