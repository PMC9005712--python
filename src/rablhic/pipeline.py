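"""End-to-end orchestration: YAML run configuration, staged execution over a
synthetic or file-based genome, output manifest with checksums, and a plain
markdown report."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time

import numpy as np
import yaml

from . import synthetic
from .compartments import compute_compartments, label_accuracy
from .hic_core import balance_matrix, cis_trans_ratio, expected_model, load_contact_map, observed_over_expected, save_contact_map
from .insulation import call_boundaries, insulation_score, normalize_insulation, tads_from_boundaries
from .loops import centromere_telomere_clustering, rabl_equidistant_enrichment
from .scaling import contact_scaling, detect_phases, scaling_slope
from .tracks import write_bedgraph

STAGES = ("simulate", "balance", "compartments", "insulation", "scaling", "rabl")


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGES))
    cfg.setdefault("outdir", "rablhic_run")
    return cfg


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute requested stages in dependency order and write a manifest.

    Identical config + seed give identical output checksums.
    """
    stages = config["stages"]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    outdir = config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = int(config["seed"])
    manifest = {"config": config, "outputs": {}, "stats": {}}

    cmap = truth = tracks = None
    if "simulate" in stages:
        sim_cfg = synthetic.SyntheticGenomeConfig(**config.get("simulate", {}))
        truth = synthetic.simulate_truth(sim_cfg, seed)
        cmap = synthetic.simulate_contact_map(sim_cfg, truth, seed + 1)
        tracks = synthetic.simulate_tracks(sim_cfg, truth, seed + 2)
        save_contact_map(cmap, f"{outdir}/map.npz", format="npz")
        manifest["outputs"]["map"] = f"{outdir}/map.npz"
        with open(f"{outdir}/truth.json", "w") as fh:
            json.dump(
                dict(
                    labels="".join(truth.labels),
                    tad_boundaries={c: v.tolist() for c, v in truth.tad_boundaries.items()},
                    centromeres=truth.centromeres,
                    rabl_strength=truth.rabl_strength,
                ),
                fh,
            )
        manifest["outputs"]["truth"] = f"{outdir}/truth.json"
        for name, tr in tracks.items():
            p = f"{outdir}/{name}.bedGraph"
            write_bedgraph(tr, p)
            manifest["outputs"][name] = p
    elif "input_map" in config:
        cmap = load_contact_map(config["input_map"], format=config.get("input_format", "npz"))
    else:
        needing = [s for s in stages if s != "simulate"]
        if needing:
            raise ValueError(f"stages {needing} need an input map: add 'simulate' or 'input_map'")

    bal = None
    if any(s in stages for s in ("balance", "compartments", "insulation", "scaling", "rabl")):
        if cmap is None:
            raise ValueError("no contact map available (missing upstream 'simulate' output)")
        bal = balance_matrix(cmap)
        manifest["stats"]["cis_trans"] = cis_trans_ratio(cmap).to_dict("records")

    if "compartments" in stages:
        orient = tracks["gene_density"] if tracks else None
        res = compute_compartments(bal, method=config.get("compartments", {}).get("method", "contrast_enhanced"),
                                   orientation_track=orient)
        p = f"{outdir}/cepc1.bedGraph"
        write_bedgraph(res.cepc1, p)
        manifest["outputs"]["cepc1"] = p
        if truth is not None:
            manifest["stats"]["cepc1_accuracy"] = label_accuracy(res.ab_labels, truth.labels)

    if "insulation" in stages:
        ins_cfg = config.get("insulation", {})
        ins = insulation_score(bal, window_bp=ins_cfg.get("window_bp", 100_000))
        ins = normalize_insulation(ins, frame_bp=ins_cfg.get("frame_bp", 1_000_000))
        bounds = call_boundaries(ins.normalized, delta_threshold=ins_cfg.get("delta", 0.05))
        tset = tads_from_boundaries(bounds, bal.binning)
        p = f"{outdir}/insulation.bedGraph"
        write_bedgraph(ins.normalized, p)
        manifest["outputs"]["insulation"] = p
        tset.tads.to_csv(f"{outdir}/tads.bed", sep="\t", index=False, header=False,
                         columns=["chrom", "start", "end"])
        manifest["outputs"]["tads"] = f"{outdir}/tads.bed"
        manifest["stats"]["n_tads"] = int(len(tset.tads))
        if truth is not None:
            rec, prec = boundary_recovery(bounds, truth)
            manifest["stats"]["boundary_recall"] = rec
            manifest["stats"]["boundary_precision"] = prec

    if "scaling" in stages:
        curve = contact_scaling(bal)
        slope = scaling_slope(curve, smooth_bins=3)
        try:
            manifest["stats"]["phases"] = dataclasses.asdict(detect_phases(curve, slope))
        except ValueError as exc:  # curve spans too few decades for phase calls
            manifest["stats"]["phases"] = {"error": str(exc)}

    if "rabl" in stages and truth is not None:
        min_len = min(cmap.binning.chrom_lengths)
        manifest["stats"]["rabl_equidistant"] = rabl_equidistant_enrichment(
            cmap, truth.centromeres,
            exclude_bp=min(1_000_000, min_len // 10),
            control_gap_min_bp=min(750_000, min_len // 8),
        )
        ctc = centromere_telomere_clustering(cmap, truth.centromeres, truth.telomeres,
                                             block_bp=truth.config.cen_tel_extent)
        manifest["stats"]["cen_tel_clustering"] = ctc.to_dict("records")

    manifest["checksums"] = {k: _checksum(p) for k, p in manifest["outputs"].items()}
    with open(f"{outdir}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)
    return manifest


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)


def boundary_recovery(boundaries, truth, tol_bins: int = 1, support=None):
    """Recall/precision of called boundaries against truth (+/- tol bins).

    ``support`` (optional boolean per global bin, e.g. finite insulation)
    restricts truth boundaries to positions the caller could observe.
    """
    b = truth.binning
    hits = 0
    n_true = 0
    called = {c: boundaries[boundaries["chrom"] == c]["bin"].to_numpy() for c in b.chrom_names}
    truth_b = {}
    for chrom, tb in truth.tad_boundaries.items():
        if support is not None:
            off = b.offsets[chrom]
            tb = np.array([t for t in tb if support[off + t] or support[off + max(t - 1, 0)]])
        truth_b[chrom] = tb
    for chrom, tb in truth_b.items():
        n_true += len(tb)
        cb = called.get(chrom, np.array([]))
        for t in tb:
            if cb.size and np.min(np.abs(cb - t)) <= tol_bins:
                hits += 1
    n_called = sum(len(v) for v in called.values())
    matched_calls = 0
    for chrom, cb in called.items():
        tb = truth_b.get(chrom, np.array([]))
        for c in cb:
            if len(tb) and np.min(np.abs(tb - c)) <= tol_bins:
                matched_calls += 1
    recall = hits / n_true if n_true else np.nan
    precision = matched_calls / n_called if n_called else np.nan
    return recall, precision


def make_report(manifest: dict) -> str:
    """Markdown summary of a completed run."""
    if "stats" not in manifest:
        raise ValueError("manifest incomplete: no stats")
    s = manifest["stats"]
    lines = ["# rablhic run report", ""]
    if "cis_trans" in s:
        pooled = [r for r in s["cis_trans"] if r["chrom"] == "genome"][0]
        lines.append(f"- pooled cis/trans ratio: {pooled['ratio']:.2f}")
    if "cepc1_accuracy" in s:
        lines.append(f"- cePC1 A/B accuracy vs truth: {s['cepc1_accuracy']:.3f}")
    if "boundary_recall" in s:
        lines.append(f"- TAD boundary recall {s['boundary_recall']:.2f} / precision {s['boundary_precision']:.2f}"
                     f" ({s.get('n_tads', '?')} TADs)")
    if "phases" in s:
        ph = s["phases"]
        def mb(x):
            return "n/a" if x is None else f"{x / 1e6:.2f} Mb"
        if "error" in ph:
            lines.append(f"- P(s) phases: not determined ({ph['error']})")
        else:
            lines.append(f"- P(s) slope minimum at {mb(ph['slope_min_distance'])}, drop at {mb(ph['drop_distance'])}")
    if "rabl_equidistant" in s:
        lines.append(f"- Rabl equidistant inter-arm enrichment: {s['rabl_equidistant']:.2f}x")
    if "cen_tel_clustering" in s:
        for r in s["cen_tel_clustering"]:
            lines.append(f"- trans {r['block']} enrichment: {r['enrichment']:.2f}x")
    if "ebr_classes" in s:
        if not s["ebr_classes"]:
            lines.append("- EBRs: no EBRs")
        else:
            lines.append("- EBR classes: " + ", ".join(f"{k}: {v}" for k, v in s["ebr_classes"].items()))
    return "\n".join(lines) + "\n"
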