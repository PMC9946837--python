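"""Stage wiring: end-to-end pipelines over synthetic or supplied inputs.

Each pipeline is a deterministic function of (config, seed): it simulates
(or loads) its inputs, runs the analysis stages in order, persists every
intermediate table when an output directory is given, and emits a run
manifest (config hash, seeds, per-stage record counts, version) so that a
rerun with the same config reproduces the same outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amplicon import (consensus_composition, filter_amplicons,
                       group_umi_families, write_consensus_tsv,
                       write_reads_tsv)
from .dsb import (dedup_cut_sites, element_counts, genomewide_breaks,
                  quartile_stratify, write_cut_sites_tsv)
from .intervals import write_bed
from .mutation import (class_frequencies, normalize_to_young, profile_table,
                       rout_outliers)
from .norm import (batch_adjust, classify_inducible, filter_low_counts,
                   normalize_counts, size_factors)
from .resampling import assign_infection, observed_difference, resample_null
from .simulate import (SimulationConfig, simulate_cut_sites,
                       simulate_expression, simulate_mutation_cohort,
                       simulate_signal_tracks, simulate_elements)

__all__ = [
    "config_from_yaml",
    "run_manifest",
    "run_mutation_pipeline",
    "run_dsb_pipeline",
    "run_resampling_pipeline",
]


def config_from_yaml(path) -> SimulationConfig:
    """Build a simulation config from a YAML mapping of dataclass fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _merge_dataclass(SimulationConfig(), raw)


def _merge_dataclass(obj, overrides: dict):
    for key, value in overrides.items():
        if not hasattr(obj, key):
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _merge_dataclass(current, value)
        else:
            setattr(obj, key, value)
    return obj


def run_manifest(cfg: SimulationConfig, seed: int, counts: dict[str, int]) -> dict:
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": seed, "record_counts": counts, "version": __version__}


def _write(out_dir, name, df: pd.DataFrame) -> None:
    if out_dir is not None:
        df.to_csv(Path(out_dir) / name, sep="\t", index=False)


def run_mutation_pipeline(cfg: SimulationConfig, seed: int,
                          out_dir=None, rout_q: float = 0.001,
                          min_depth: int = 10,
                          min_mean_depth: float = 100.0) -> dict:
    """Amplicon mutation pipeline: simulate cohort -> UMI families ->
    consensus-10 tables -> amplicon depth filter -> frequencies ->
    young-median normalization -> robust outlier masks."""
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    panel, reads_by_animal, sheet, truth = simulate_mutation_cohort(cfg, seed)
    profiles = []
    n_reads = n_families = 0
    for animal, reads in reads_by_animal.items():
        n_reads += len(reads)
        families, qc = group_umi_families(reads)
        n_families += len(families)
        by_amp: dict[str, list] = {}
        for f in families:
            by_amp.setdefault(f.amplicon_id, []).append(f)
        tables = [consensus_composition(
            fams, min_depth=min_depth, reference=panel[aid].reference,
            primer_len=panel[aid].primer_len)
            for aid, fams in by_amp.items()]
        kept = set(filter_amplicons(tables, min_mean_depth=min_mean_depth))
        profiles.extend(class_frequencies(t, sample_id=animal)
                        for t in tables if t.amplicon_id in kept)
        if out_dir is not None and animal == next(iter(reads_by_animal)):
            write_consensus_tsv(tables, Path(out_dir) / f"consensus_{animal}.tsv")
    prof = profile_table(profiles)
    age = dict(zip(sheet["animal_id"], sheet["age_group"]))
    freq = prof.rename(columns={"amplicon_id": "site_id",
                                "sample_id": "animal_id"})
    freq["age_group"] = freq["animal_id"].map(age)
    rates = normalize_to_young(freq[["site_id", "animal_id", "age_group",
                                     "f_total"]])
    masks = []
    for site, g in rates.dropna(subset=["value"]).groupby("site_id"):
        if len(g) >= 3:
            flag = rout_outliers(g["value"].to_numpy(), q=rout_q)
            masks.append(pd.DataFrame({"site_id": site,
                                       "animal_id": g["animal_id"],
                                       "outlier": flag}))
    outliers = (pd.concat(masks, ignore_index=True) if masks
                else pd.DataFrame(columns=["site_id", "animal_id", "outlier"]))
    _write(out_dir, "profiles.tsv", prof)
    _write(out_dir, "normalized_rates.tsv", rates)
    _write(out_dir, "outliers.tsv", outliers)
    manifest = run_manifest(cfg, seed, {
        "reads": n_reads, "families": n_families, "profiles": len(prof),
        "normalized_rates": len(rates)})
    if out_dir is not None:
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"panel": panel, "profiles": prof, "normalized_rates": rates,
            "outliers": outliers, "truth": truth, "sheet": sheet,
            "manifest": manifest}


def run_dsb_pipeline(cfg: SimulationConfig, seed: int, out_dir=None,
                     fold_threshold: float = 2.0, alpha: float = 0.05) -> dict:
    """Cut-site pipeline: simulate landscape + tracks + records -> dedup ->
    element counts -> low-count filter -> size factors -> batch-adjusted
    log-normalized counts -> inducible calls (2 h vs 0 h) -> binding
    quartiles -> genome-wide unique-break totals."""
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    elements = simulate_elements(cfg, seed)
    num_track, den_track, peaks, replicate_sets, btruth = \
        simulate_signal_tracks(cfg, seed + 1, elements=elements)
    records, sheet, truth, elements = simulate_cut_sites(
        cfg, seed + 2, elements=elements, binding_truth=btruth)
    raw_by_sample = {s: g.drop(columns="sample_id")
                     for s, g in records.groupby("sample_id")}
    sets = [dedup_cut_sites(raw_by_sample[s], s) for s in sheet["sample_id"]]
    counts = element_counts(sets, elements)
    mask = filter_low_counts(counts, mode="any_nonzero")
    counts = counts.loc[mask]
    s = size_factors(counts)
    normalized = normalize_counts(counts, s)
    logn = np.log2(normalized + 1)
    adjusted = batch_adjust(logn, sheet["batch"], sheet["condition"])
    cond = dict(zip(sheet["sample_id"], sheet["condition"]))
    pre = [x for x in counts.columns if cond[x] == "0h"]
    post = [x for x in counts.columns if cond[x] == "2h"]
    norm_adj = 2.0 ** adjusted - 1  # back to normalized scale, batch-free
    calls = classify_inducible(norm_adj.clip(lower=0), pre, post,
                               fold_threshold=fold_threshold, alpha=alpha)
    quartiles = quartile_stratify(elements, num_track, den_track, peaks)
    totals = genomewide_breaks(
        sets, seed + 3,
        records_per_sample=[raw_by_sample[s_.sample_id] for s_ in sets])
    calls_df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
    quart_df = pd.DataFrame([dataclasses.asdict(q) for q in quartiles])
    if out_dir is not None:
        write_bed([e.interval for e in elements], Path(out_dir) / "landscape.bed",
                  names=[e.element_id for e in elements])
        counts.reset_index().to_csv(Path(out_dir) / "counts.tsv", sep="\t",
                                    index=False)
        _write(out_dir, "sample_sheet.tsv", sheet)
        _write(out_dir, "inducible_calls.tsv", calls_df)
        _write(out_dir, "quartiles.tsv", quart_df)
        totals.rename_axis("sample_id").reset_index().to_csv(
            Path(out_dir) / "genomewide_breaks.tsv", sep="\t", index=False)
    manifest = run_manifest(cfg, seed, {
        "records": len(records), "samples": len(sets),
        "elements": len(elements), "elements_kept": int(mask.sum())})
    if out_dir is not None:
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"elements": elements, "counts": counts, "size_factors": s,
            "normalized": normalized, "adjusted_log2": adjusted,
            "inducible_calls": calls_df, "quartiles": quart_df,
            "genomewide_totals": totals, "truth": truth,
            "binding_truth": btruth, "sheet": sheet,
            "replicate_peak_sets": replicate_sets, "manifest": manifest}


def run_resampling_pipeline(cfg: SimulationConfig, seed: int,
                            n_iter: int = 10_000, out_dir=None) -> dict:
    """Expression pipeline: simulate matrix -> infection assignment ->
    observed target difference -> resampling null and empirical p."""
    expr, meta, truth = simulate_expression(cfg, seed)
    infection = assign_infection(meta[["mCherry", "GFP"]])
    ct = cfg.expression.cell_type
    observed = observed_difference(expr, infection, meta["cell_type"],
                                   truth["targets"], ct)
    null = resample_null(expr, infection, meta["cell_type"], ct,
                         n_targets=len(truth["targets"]), observed=observed,
                         n_iter=n_iter, seed=seed + 1)
    result = pd.DataFrame([{"cell_type": ct, "observed": observed,
                            "p_value": null.p_value, "n_iter": n_iter,
                            "seed": seed}])
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        result.to_csv(Path(out_dir) / "resampling.tsv", sep="\t", index=False)
    return {"expr": expr, "meta": meta, "infection": infection,
            "observed": observed, "null": null, "result": result,
            "truth": truth}
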