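"""End-to-end orchestration: synthetic-or-real inputs through every stage.

``run_all`` executes, in order: input loading (or synthetic generation),
peak GC distributions, GC-stratified k-mer specificity, pair-correlation
profiles and homopolymer-tract panel, TSS-aligned GC/intensity profiles with
their Pearson correlation, the joint GC x distance histogram, the
CpG-normalized methylation metaprofile, and the equilibrium competition
sweep.  Every stage writes TSV into the output directory and the run ends
with a manifest (package version, seeds, parameter hash) sufficient to
reproduce every number bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .equilibrium import EquilibriumParameters, sweep_myc_total
from .genomic_io import (
    Genome,
    PeakSet,
    centered_sequence,
    gc_content,
    nearest_peak_distance,
    read_genome,
    read_peaks,
    write_bed,
    write_genome,
)
from .kmer_energy import stratified_specificity
from .repeat_correlation import mean_profile, poly_tract_panel, write_profile
from .synthetic import SyntheticSpec, generate_dataset
from .tss_profiles import (
    classify_tss,
    gc_metaprofile,
    intensity_metaprofile,
    joint_gc_distance,
    methylation_metaprofile,
    profile_pearson,
    read_methylation,
    write_methylation,
    write_profile_tsv,
)

__all__ = ["default_config", "run_all"]

log = logging.getLogger("bimodalbind")


def default_config(outdir: str = "bimodal_out", seed: int = 0) -> dict:
    """Config for a fully synthetic run."""
    return {
        "outdir": outdir,
        "seed": seed,
        "synthetic": {"seed": seed},
        "kmer": {"k_max": 8, "gc_low": 0.4, "gc_high": 0.6, "min_peaks": 200},
        "str": {"x_max": 30, "n_shuffles": 100, "exact": False},
        "tss": {"half_span": 1000, "window": 50, "bound_window": 1000},
        "methylation": {"half_span": 2000},
        "equilibrium": {"dna_tot_uM": 0.5, "n_points": 200},
    }


def _load_inputs(config: dict):
    if "synthetic" in config:
        spec_kw = dict(config["synthetic"])
        spec_kw.setdefault("seed", config.get("seed", 0))
        data = generate_dataset(SyntheticSpec(**spec_kw))
        return data["genome"], data["peaks"], data["tss"], data["methylation"]
    paths = config["paths"]
    for key in ("genome", "peaks", "tss"):
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"config path {key!r}: {paths[key]}")
    genome = read_genome(paths["genome"])
    peaks = read_peaks(paths["peaks"], tf=config.get("tf", "TF"), stage=config.get("stage", "ESC"))
    tss = read_peaks(paths["tss"], tf="TSS", stage="annotation")
    methylation = read_methylation(paths["methylation"]) if paths.get("methylation") else None
    return genome, peaks, tss, methylation


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_all(config: dict | str | Path) -> Path:
    """Run every stage; returns the report directory."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    timings: dict[str, float] = {}

    t = _stage("inputs")
    genome, peaks, tss, methylation = _load_inputs(config)
    if "synthetic" in config:
        write_genome(genome, outdir / "genome.fa")
        write_bed(peaks, outdir / "peaks.bed")
        write_bed(tss, outdir / "tss.bed")
        if methylation is not None:
            write_methylation(methylation, outdir / "methylation.tsv")
    timings["inputs"] = time.perf_counter() - t

    # --- GC distribution of peak windows -----------------------------------
    t = _stage("gc_distribution")
    gc_vals = []
    for p in peaks:
        seq = centered_sequence(p, genome)
        if seq is not None:
            g = gc_content(seq)
            if g is not None:
                gc_vals.append(g)
    gc_vals = np.array(gc_vals)
    hist, edges = np.histogram(gc_vals, bins=100, range=(0, 1))
    pd.DataFrame({"gc_bin_left": edges[:-1], "gc_bin_right": edges[1:], "count": hist}).to_csv(
        outdir / "peak_gc_distribution.tsv", sep="\t", index=False
    )
    timings["gc_distribution"] = time.perf_counter() - t

    # --- k-mer specificity --------------------------------------------------
    t = _stage("kmer_specificity")
    kcfg = config.get("kmer", {})
    summaries = stratified_specificity(
        peaks,
        genome,
        gc_low=kcfg.get("gc_low", 0.4),
        gc_high=kcfg.get("gc_high", 0.6),
        min_peaks=kcfg.get("min_peaks", 1000),
        k_range=tuple(range(1, kcfg.get("k_max", 8) + 1)),
        seed=seed,
    )
    rows = []
    for s in summaries:
        for k, auc in sorted(s.auc_by_k.items()):
            rows.append(
                {
                    "tf": s.tf_name,
                    "stage": s.stage,
                    "stratum": s.stratum,
                    "k": k,
                    "auc": auc,
                    "delta_auc": s.delta_auc,
                    "n_peaks": s.n_peaks,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "kmer_specificity.tsv", sep="\t", index=False)
    timings["kmer_specificity"] = time.perf_counter() - t

    # --- pair correlations --------------------------------------------------
    t = _stage("str_correlations")
    scfg = config.get("str", {})
    gc_low = kcfg.get("gc_low", 0.4)
    gc_high = kcfg.get("gc_high", 0.6)
    strata_seqs = {"low-GC": [], "high-GC": []}
    for p in peaks:
        seq = centered_sequence(p, genome)
        if seq is None:
            continue
        g = gc_content(seq)
        if g is None:
            continue
        if g < gc_low:
            strata_seqs["low-GC"].append(seq)
        elif g > gc_high:
            strata_seqs["high-GC"].append(seq)
    for stratum, seqs in strata_seqs.items():
        if len(seqs) < 10:
            continue
        for alpha in ("A", "C"):
            prof = mean_profile(
                seqs,
                alpha,
                alpha,
                x_max=scfg.get("x_max", 30),
                n_shuffles=scfg.get("n_shuffles", 100),
                seed=seed,
                exact=scfg.get("exact", False),
            )
            write_profile(prof, outdir / f"eta_{alpha}{alpha}_{stratum}.tsv")
    panel = poly_tract_panel(
        peaks, genome, tss, n_shuffles=scfg.get("n_shuffles", 100),
        seed=seed, exact=scfg.get("exact", False),
    )
    panel.to_csv(outdir / "poly_tract_panel.tsv", sep="\t", index=False)
    timings["str_correlations"] = time.perf_counter() - t

    # --- TSS profiles -------------------------------------------------------
    t = _stage("tss_profiles")
    tcfg = config.get("tss", {})
    half_span = tcfg.get("half_span", 1000)
    window = tcfg.get("window", 50)
    bound, unbound = classify_tss(tss, peaks, window=tcfg.get("bound_window", 1000))
    pearson_row = {}
    if len(bound) >= 10:
        gc_prof = gc_metaprofile(bound, genome, half_span=half_span, window=window, seed=seed)
        write_profile_tsv(gc_prof, outdir / "tss_gc_bound.tsv")
        int_prof = intensity_metaprofile(bound, peaks, half_span=half_span, seed=seed)
        write_profile_tsv(int_prof, outdir / "tss_intensity_bound.tsv")
        r, pval = profile_pearson(gc_prof, int_prof)
        pearson_row = {"R_gc_intensity": r, "p_value": pval, "n_bound_tss": len(bound)}
        pd.DataFrame([pearson_row]).to_csv(outdir / "tss_gc_intensity_pearson.tsv", sep="\t", index=False)
    if len(unbound) >= 10:
        write_profile_tsv(
            gc_metaprofile(unbound, genome, half_span=half_span, window=window, seed=seed),
            outdir / "tss_gc_unbound.tsv",
        )
    dists = nearest_peak_distance(peaks, tss)
    gcs = []
    for p in peaks:
        seq = centered_sequence(p, genome)
        gcs.append(gc_content(seq) if seq is not None else None)
    hist2d = joint_gc_distance(gcs, dists)
    np.savetxt(outdir / "joint_gc_distance.tsv", hist2d.counts, delimiter="\t", fmt="%d")
    timings["tss_profiles"] = time.perf_counter() - t

    # --- methylation --------------------------------------------------------
    if methylation is not None:
        t = _stage("methylation")
        mprof = methylation_metaprofile(
            peaks, methylation, half_span=config.get("methylation", {}).get("half_span", 2000)
        )
        write_profile_tsv(mprof, outdir / "methylation_metaprofile.tsv")
        timings["methylation"] = time.perf_counter() - t

    # --- equilibrium --------------------------------------------------------
    t = _stage("equilibrium")
    ecfg = config.get("equilibrium", {})
    dna_tot = ecfg.get("dna_tot_uM", 0.5) * 1e-6
    for label, tetramer in (("tetramer_on", True), ("tetramer_off", False)):
        params = EquilibriumParameters(
            DNAH_tot=dna_tot, DNAL_tot=dna_tot, tetramer_enabled=tetramer
        )
        sweep = sweep_myc_total(params, n_points=ecfg.get("n_points", 200))
        sweep.to_frame().to_csv(outdir / f"equilibrium_sweep_{label}.tsv", sep="\t", index=False)
    timings["equilibrium"] = time.perf_counter() - t

    # --- manifest -----------------------------------------------------------
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": cfg_hash,
        "config": config,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "n_peaks": len(peaks),
        "n_tss": len(tss),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
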