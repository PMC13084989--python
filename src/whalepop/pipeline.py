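"""Config-driven orchestration of the full analysis pipeline.

Stage order: simulate (or load VCF) -> filter -> kinship exclusion -> LD
prune -> {diversity, ROH + F_ROH + ages, PCA / F_ST} and
{polarize -> SFS -> stairway}, {IBD -> recent Ne}.  Every stage writes TSV
tables into the output directory, and a manifest records the seed and a
stable hash of all parameters so a run can be reproduced exactly.  The
global seed fans out to per-stage seeds by stable hashing of stage names.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import filtering, ibd, relatedness, roh, sfs, structure, vcfio
from .simulate import DemographicModel, SimulationConfig, simulate_dataset

__all__ = ["load_config", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _log(msg: str, fh=None):
    print(f"[whalepop] {msg}", file=sys.stderr)
    if fh:
        fh.write(msg + "\n")


def _model_from_config(sim: dict) -> DemographicModel:
    pops = tuple(tuple((float(t), float(n)) for t, n in pop)
                 for pop in sim.get("populations", [[[0, 5000]]]))
    return DemographicModel(
        populations=pops,
        split_time_generations=float(sim.get("split_time_generations", 0)),
        migration_rate=float(sim.get("migration_rate", 0)),
        mutation_rate=float(sim.get("mutation_rate", 0.9664e-8)),
        recombination_rate_cM_per_Mb=float(
            sim.get("recombination_rate_cM_per_Mb", 1.0)),
        generation_time_years=float(sim.get("generation_time_years", 32)),
    )


def run_pipeline(config: dict, outdir: str) -> dict:
    """Execute the enabled stages; returns a dict of result tables/paths."""
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 1))
    results: dict = {}
    log_fh = open(os.path.join(outdir, "pipeline.log"), "w")

    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": config,
    }

    current_stage = "setup"
    try:
        # ------------------------------------------------------ simulate
        current_stage = "simulate"
        sim = config.get("simulate")
        if sim is not None:
            model = _model_from_config(sim)
            sc = SimulationConfig(
                n_diploids=tuple(sim.get("n_diploids", [9])),
                n_chromosomes=int(sim.get("n_chromosomes", 1)),
                chromosome_length_bp=int(sim.get("chromosome_length_bp",
                                                 10_000_000)),
                n_independent_loci=int(sim.get("n_independent_loci", 1000)),
                locus_length_bp=int(sim.get("locus_length_bp", 10_000)),
                seed=stage_seed(seed, "simulate"),
                include_outgroup=bool(sim.get("include_outgroup", False)),
                outgroup_divergence_generations=float(
                    sim.get("outgroup_divergence_generations", 0)),
                mode=sim.get("mode", "independent"),
            )
            dataset = simulate_dataset(model, sc)
            vcf_path = os.path.join(outdir, "simulated.vcf")
            vcfio.write_vcf(dataset, vcf_path)
            _log(f"simulate: {dataset.n_sites} sites, "
                 f"{dataset.n_samples} samples", log_fh)
        else:
            model = None
            dataset = vcfio.read_vcf(config["input"]["vcf"])
            _log(f"load: {dataset.n_sites} sites from "
                 f"{config['input']['vcf']}", log_fh)
        results["dataset"] = dataset

        # -------------------------------------------------------- filter
        current_stage = "filter"
        fcfg_raw = config.get("filter", {})
        if fcfg_raw.get("enabled", True):
            fcfg = filtering.FilterConfig(
                min_genotype_dp=fcfg_raw.get("min_genotype_dp", 10),
                min_gq=fcfg_raw.get("min_gq", 30),
                max_missing_fraction=fcfg_raw.get("max_missing_fraction",
                                                  0.25),
                min_mq=fcfg_raw.get("min_mq", 30),
                max_depth_multiplier=fcfg_raw.get("max_depth_multiplier",
                                                  2.0),
                min_scaffold_length_bp=fcfg_raw.get("min_scaffold_length_bp",
                                                    0),
                repeat_mask=fcfg_raw.get("repeat_mask"),
                sex_scaffolds=tuple(fcfg_raw.get("sex_scaffolds", ())),
            )
            dataset, report = filtering.apply_filters(dataset, fcfg)
            report.to_frame().to_csv(os.path.join(outdir, "filter_report.tsv"),
                                     sep="\t", index=False)
            vcfio.write_vcf(dataset, os.path.join(outdir, "filtered.vcf"))
            results["filter_report"] = report
            _log(f"filter: {report.site_counts()}", log_fh)

        # ------------------------------------------------------- kinship
        current_stage = "kinship"
        g = dataset.genotypes()
        non_outgroup = [i for i, p in enumerate(dataset.sample_population)
                        if p != "outgroup"]
        outgroup_idx = [i for i in range(dataset.n_samples)
                        if i not in non_outgroup]
        ktab = relatedness.kinship_table(
            g[:, non_outgroup],
            [dataset.sample_ids[i] for i in non_outgroup])
        ktab.to_csv(os.path.join(outdir, "kinship.tsv"), sep="\t",
                    index=False)
        retained, removed = relatedness.exclude_relatives(ktab)
        results["kinship"] = ktab
        results["removed_relatives"] = removed
        keep_idx = [i for i in non_outgroup
                    if dataset.sample_ids[i] in set(retained)] + outgroup_idx
        dataset = dataset.subset_samples(keep_idx)
        _log(f"kinship: removed {removed or 'none'}", log_fh)

        # ------------------------------------------- per-population views
        ingroup = [i for i, p in enumerate(dataset.sample_population)
                   if p != "outgroup"]
        ds_in = dataset.subset_samples(ingroup)
        pop_names = sorted({p for p in ds_in.sample_population})
        pop_sets = {p: [i for i, q in enumerate(ds_in.sample_population)
                        if q == p] for p in pop_names}

        # ----------------------------------------------------- diversity
        current_stage = "diversity"
        dcfg = config.get("diversity", {})
        div_rows = {}
        for pop in pop_names:
            ds_pop = ds_in.subset_samples(pop_sets[pop])
            windows = div.window_stats(
                ds_pop, window_size=int(dcfg.get("window_size", 10_000)))
            div.windows_frame(windows).to_csv(
                os.path.join(outdir, f"diversity_windows.{pop}.tsv"),
                sep="\t", index=False)
            gw = div.genome_wide_means(windows)
            gw["tajimas_d"] = div.tajimas_d(ds_pop)
            div_rows[pop] = gw
            _log(f"diversity[{pop}]: pi={gw['pi']:.3g} "
                 f"theta={gw['theta_w']:.3g} D={gw['tajimas_d']:.3g}",
                 log_fh)
        results["diversity"] = div_rows
        pd.DataFrame([{"population": p, **v} for p, v in div_rows.items()]
                     ).to_csv(os.path.join(outdir, "diversity_summary.tsv"),
                              sep="\t", index=False)

        # ----------------------------------------------------------- roh
        current_stage = "roh"
        rcfg = config.get("roh", {})
        method = rcfg.get("method", "hmm")
        segs = roh.detect_roh_dataset(ds_in, method=method)
        seg_df = roh.segments_frame(segs)
        rate = (model.recombination_rate_cM_per_Mb if model else
                float(rcfg.get("recombination_rate_cM_per_Mb", 1.0)))
        gtime = (model.generation_time_years if model else
                 float(rcfg.get("generation_time_years", 32.0)))
        if len(seg_df):
            ages = [roh.roh_age(l, rate, gtime) for l in seg_df["length_bp"]]
            seg_df["age_generations"] = [a[0] for a in ages]
            seg_df["age_years"] = [a[1] for a in ages]
        seg_df.to_csv(os.path.join(outdir, "roh_segments.tsv"), sep="\t",
                      index=False)
        autosomal = int(ds_in.scaffold_lengths.sum())
        fr = roh.froh(segs, autosomal) if segs else []
        fr_rows = [{"sample": f.sample, **f.per_class,
                    "total_froh": f.total_froh} for f in fr]
        pd.DataFrame(fr_rows).to_csv(os.path.join(outdir, "froh.tsv"),
                                     sep="\t", index=False)
        results["roh_segments"] = seg_df
        results["froh"] = fr
        _log(f"roh[{method}]: {len(seg_df)} segments", log_fh)

        # --------------------------------------------- structure (PCA/FST)
        current_stage = "structure"
        pops = [ds_in.sample_population[i] for i in range(ds_in.n_samples)]
        if len(set(pops)) == 2:
            est, _ = structure.weighted_fst(ds_in.genotypes(), pops)
            results["fst"] = est
            pd.DataFrame([{"weighted_fst": est}]).to_csv(
                os.path.join(outdir, "fst.tsv"), sep="\t", index=False)
            _log(f"fst: {est:.4f}", log_fh)
        try:
            coords, frac = structure.pca(ds_in.genotypes())
            pca_df = pd.DataFrame(coords[:, :4],
                                  columns=[f"PC{i + 1}" for i in range(
                                      min(4, coords.shape[1]))])
            pca_df.insert(0, "sample", ds_in.sample_ids)
            pca_df.to_csv(os.path.join(outdir, "pca.tsv"), sep="\t",
                          index=False)
            results["pca"] = (coords, frac)
        except ValueError:
            _log("pca: skipped (no polymorphic site)", log_fh)

        # ------------------------------------------------- sfs / stairway
        current_stage = "sfs"
        scfg = config.get("stairway", {})
        if scfg.get("enabled", True) and "outgroup" in dataset.sample_population:
            og = dataset.sample_population.index("outgroup")
            anc, kept, reasons = sfs.polarize(dataset, og)
            results["sfs"] = {}
            results["stairway"] = {}
            for pop in pop_names:
                excl = tuple(i for i, p in enumerate(dataset.sample_population)
                             if p != pop)
                spectrum = sfs.build_sfs(dataset, anc, exclude_samples=excl)
                np.savetxt(os.path.join(outdir, f"sfs.{pop}.txt"),
                           spectrum.counts[None, :], fmt="%d")
                with open(os.path.join(outdir, f"sfs.{pop}.json"), "w") as fh:
                    json.dump({"n_haplotypes": spectrum.n_haplotypes,
                               "dropped": reasons}, fh, indent=1)
                results["sfs"][pop] = spectrum
                if spectrum.n_segregating == 0:
                    continue
                st_cfg = sfs.StairwayConfig(
                    mu=(model.mutation_rate if model else 0.9664e-8),
                    L_total=float(scfg.get(
                        "L_total", int(dataset.scaffold_lengths.sum()))),
                    generation_time_years=(model.generation_time_years
                                           if model else 32.0),
                    n_boot=int(scfg.get("n_boot", 0)),
                    max_steps=int(scfg.get("max_steps", 3)),
                    n_restarts=int(scfg.get("n_restarts", 2)),
                    seed=stage_seed(seed, f"stairway:{pop}"),
                )
                traj = sfs.fit_stairway(spectrum, st_cfg)
                traj.to_frame().to_csv(
                    os.path.join(outdir, f"stairway_ne.{pop}.tsv"),
                    sep="\t", index=False)
                results["stairway"][pop] = traj
                _log(f"stairway[{pop}]: epochs at "
                     f"{traj.breakpoints.tolist()}", log_fh)

        # --------------------------------------------------- ibd / ibdne
        current_stage = "ibd"
        icfg = config.get("ibdne", {})
        if icfg.get("enabled", True) and dataset.phased:
            results["ibd_segments"] = {}
            results["ibdne"] = {}
            for pop in pop_names:
                ds_pop = ds_in.subset_samples(pop_sets[pop])
                segs = ibd.detect_ibd(
                    ds_pop, min_cM=float(icfg.get("min_cM", 2.0)),
                    rate_cM_per_Mb=rate,
                    max_mismatches_per_cM=float(
                        icfg.get("max_mismatches_per_cM", 1.0)))
                ibd.segments_frame(segs).to_csv(
                    os.path.join(outdir, f"ibd_segments.{pop}.tsv"),
                    sep="\t", index=False)
                n_hap = 2 * ds_pop.n_samples
                n_pairs = n_hap * (n_hap - 1) // 2 - ds_pop.n_samples
                gm = ds_pop.genetic_length_cM(rate) / 100.0
                spec = ibd.ibd_spectrum(segs, n_pairs, gm)
                results["ibd_segments"][pop] = segs
                if spec.counts.sum() == 0:
                    _log(f"ibdne[{pop}]: no segments >= threshold", log_fh)
                    continue
                ne_cfg = ibd.RecentNeConfig(
                    n_boot=int(icfg.get("n_boot", 0)),
                    knots=tuple(icfg.get("knots", ())),
                    seed=stage_seed(seed, f"ibdne:{pop}"))
                rtraj = ibd.fit_recent_ne(spec, ne_cfg)
                rtraj.to_frame().to_csv(
                    os.path.join(outdir, f"ibdne.{pop}.tsv"),
                    sep="\t", index=False)
                results["ibdne"][pop] = rtraj
                _log(f"ibdne[{pop}]: {len(segs)} segments, "
                     f"lambda={rtraj.smoothing_lambda}", log_fh)

    except Exception as exc:
        _log(f"FAILED at stage {current_stage}: {exc}", log_fh)
        log_fh.close()
        raise RuntimeError(f"pipeline failed at stage '{current_stage}': "
                           f"{exc}") from exc

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log_fh.close()
    return results
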