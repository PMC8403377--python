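"""End-to-end experiment: simulate, sequence, impute both ways, score, report.

The experiment mirrors a two-cohort design: a small deep-sequenced
evaluation cohort drives the coverage and genotype-concordance panels across
a grid of downsampled depths, and a case/control cohort drives the PRS,
AUC and cross-platform agreement analyses. Three genotyping routes are
compared throughout: low-pass sequencing imputed from genotype likelihoods
(GL mode), low-pass sequencing imputed from fixed calls (hard-call mode),
and a simulated genotyping array imputed from its typed subset.

One global seed fans out to per-stage seeds through a SeedSequence-derived
table, so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as cc
from . import coverage as cov
from . import evaluation as ev
from . import impute as imp
from . import prs as prs_mod
from . import reads as rd
from . import simulate as sim

__all__ = ["ExperimentConfig", "ExperimentBundle", "run_experiment", "stage_seeds"]

logger = logging.getLogger(__name__)

_STAGES = (
    "panel", "panel_subsample", "eval_cohort", "pool_cohort", "weights", "phenotypes",
    "reads_eval", "array_eval", "reads_prs", "array_prs", "auc_boot",
    "downsample_eval", "downsample_prs",
)


def stage_seeds(seed: int) -> dict:
    """Named per-stage integer seeds derived from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}


@dataclass
class ExperimentConfig:
    """Study conditions for the full synthetic experiment (defaults are the
    conditions every report in this package refers to)."""

    seed: int = 0
    # panel / region
    population_haplotypes: int = 300
    n_panel_haplotypes: int = 150
    n_sites: int = 300
    region_length: int = 1_000_000
    maf_min: float = 0.0
    # cohorts
    n_eval_individuals: int = 50
    n_cases: int = 87
    n_controls: int = 101
    pool_size: int = 15_000
    prevalence: float = 0.01
    cohort_switch_rate: float = 1e-6
    cohort_mutation_rate: float = 5e-4
    # genetic architecture
    h2: float = 0.2
    n_causal: int = 15
    weight_noise_sd: float = 0.05
    eff_sample_size: float = 30_000.0
    # sequencing
    source_depth: float = 30.0
    depth_grid: tuple = (0.5, 1.0, 2.0, 5.0)
    error_rate: float = 0.001
    overdispersion: float = 0.0
    # array route
    array_fraction: float = 0.16
    array_error: float = 0.001
    # imputation
    hmm_switch_rate: float = 1e-6
    hmm_miscopy: float | None = None
    hmm_call_error: float = 0.01
    min_call_depth: int = 1
    info_threshold: float = 0.3
    # metrics
    af_bin_edges: tuple = (0.005, 0.05)
    af_source: str = "population"  # 'population', 'panel' or 'cohort'
    window_size: int = 10_000
    # numerics
    hmm_dtype: str = "float32"  # imputation arithmetic for production arms
    # PRS
    p_thresholds: tuple = prs_mod.DEFAULT_P_THRESHOLDS
    ld_r2: float = 0.5
    sig_threshold: float = 5e-8

    def hmm_params(self) -> imp.HmmParams:
        return imp.HmmParams(
            switch_rate=self.hmm_switch_rate,
            miscopy=self.hmm_miscopy,
            call_error=self.hmm_call_error,
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        for k in ("depth_grid", "af_bin_edges", "p_thresholds"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExperimentBundle:
    """All tables produced by one experiment run."""

    coverage: pd.DataFrame
    concordance: pd.DataFrame
    af_bins: pd.DataFrame
    fraction_more_accurate: pd.DataFrame
    prs: pd.DataFrame
    pt_tables: dict
    score_correlations: pd.DataFrame
    scores: pd.DataFrame
    manifest: dict

    def write(self, outdir: str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "coverage.tsv": self.coverage,
            "concordance.tsv": self.concordance,
            "af_bins.tsv": self.af_bins,
            "fraction_more_accurate.tsv": self.fraction_more_accurate,
            "prs.tsv": self.prs,
            "score_correlations.tsv": self.score_correlations,
            "scores.tsv": self.scores,
        }
        manifest = dict(self.manifest)
        manifest["outputs"] = sorted(tables)
        for name, df in tables.items():
            df.to_csv(out / name, sep="\t", index=False, float_format="%.6g")
        for arm, df in self.pt_tables.items():
            fname = f"pt_{arm}.tsv"
            df.to_csv(out / fname, sep="\t", index=False, float_format="%.6g")
            manifest["outputs"].append(fname)
        manifest["outputs"] = sorted(manifest["outputs"])
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _impute_arm(mode, evidence, panel, params, dtype):
    if mode == "gl":
        return imp.impute_gl(evidence, panel, params, dtype=dtype)
    return imp.impute_hardcall(evidence, panel, params, dtype=dtype)


def _arm_metrics(truth, dosages, keep, afs, bins):
    cols = np.flatnonzero(keep)
    rep = cc.concordance_report(
        truth[:, cols],
        dosages.dosage[:, cols],
        dosages.best_guess[:, cols],
        afs[cols],
        bins,
    )
    return rep, cols


def run_experiment(config: ExperimentConfig, outdir: str | None = None) -> ExperimentBundle:
    """Run the full grid and return (optionally also write) the report bundle."""
    t0 = time.time()
    seeds = stage_seeds(config.seed)
    params = config.hmm_params()
    bins = cc.AfBins(edges=tuple(config.af_bin_edges))

    def _stage(name):
        logger.info("stage %-18s t=%.1fs", name, time.time() - t0)

    dtype = np.dtype(config.hmm_dtype).type

    _stage("simulate panel")
    # the population pool targets are drawn from; the reference panel the HMM
    # copies from is a finite subsample of it, so rare population alleles are
    # often absent from the panel — the dominant cause of rare-variant
    # imputation failure
    population = sim.simulate_panel(
        config.population_haplotypes,
        config.n_sites,
        config.region_length,
        config.maf_min,
        seed=seeds["panel"],
    )
    panel = sim.subsample_panel(
        population, config.n_panel_haplotypes, seed=seeds["panel_subsample"]
    )
    if config.af_source == "population":
        afs = population.population_af
    elif config.af_source == "panel":
        afs = panel.allele_frequencies
    else:
        afs = None  # fall back to each cohort's empirical AF

    # ---- evaluation cohort: coverage + concordance across the depth grid
    _stage("eval cohort")
    eval_geno = sim.simulate_cohort(
        population,
        config.n_eval_individuals,
        config.cohort_switch_rate,
        config.cohort_mutation_rate,
        seed=seeds["eval_cohort"],
    )
    eval_afs = afs if afs is not None else eval_geno.allele_frequencies
    source_reads = rd.simulate_reads(
        eval_geno,
        config.source_depth,
        config.error_rate,
        config.overdispersion,
        seed=seeds["reads_eval"],
    )

    coverage_rows, conc_rows, bin_rows, fma_rows = [], [], [], []
    per_snp_by_arm: dict[str, np.ndarray] = {}

    _stage("array arm (eval)")
    eval_array = rd.simulate_array(
        eval_geno,
        config.array_fraction,
        config.array_error,
        seed=seeds["array_eval"],
        afs=eval_afs,
    )
    arr_dos = imp.impute_hardcall(eval_array, panel, params, dtype=dtype)
    arr_keep = imp.filter_by_info(arr_dos, config.info_threshold)
    rep, cols = _arm_metrics(eval_geno.genotypes, arr_dos, arr_keep, eval_afs, bins)
    conc_rows.append(("array", np.nan, rep.r2_overall, rep.ndr, rep.fpr, rep.fnr, cols.size))
    # AF-stratified accuracy uses all imputed dosages: filtering first would
    # keep only well-imputed rare survivors and mask the rare-bin behavior
    for row in cc.aggregate_r2_by_bin(
        eval_geno.genotypes, arr_dos.dosage, eval_afs, bins
    ).itertuples(index=False):
        bin_rows.append(("array", np.nan) + tuple(row))
    per_snp_by_arm["array"] = cc.per_snp_r2(eval_geno.genotypes, arr_dos.dosage)

    for d_i, depth in enumerate(config.depth_grid):
        _stage(f"depth {depth}x (eval)")
        reads_d = rd.downsample_reads(source_reads, depth, seed=seeds["downsample_eval"] + d_i)
        prof = [
            cov.coverage_profile(panel.positions, reads_d.depth[n], config.window_size)
            for n in range(config.n_eval_individuals)
        ]
        coverage_rows.append(
            (depth,
             float(np.mean([p.covered_fraction for p in prof])),
             float(np.mean([p.gini for p in prof])))
        )
        gl = rd.compute_gl(reads_d)
        calls = rd.hard_call(gl, config.min_call_depth)
        for mode, evidence in (("gl", gl), ("hardcall", calls)):
            dos = _impute_arm(mode, evidence, panel, params, dtype)
            keep = imp.filter_by_info(dos, config.info_threshold)
            rep, cols = _arm_metrics(eval_geno.genotypes, dos, keep, eval_afs, bins)
            conc_rows.append((mode, depth, rep.r2_overall, rep.ndr, rep.fpr, rep.fnr, cols.size))
            for row in cc.aggregate_r2_by_bin(
                eval_geno.genotypes, dos.dosage, eval_afs, bins
            ).itertuples(index=False):
                bin_rows.append((mode, depth) + tuple(row))
            per_snp_by_arm[f"{mode}_{depth:g}x"] = cc.per_snp_r2(
                eval_geno.genotypes, dos.dosage
            )

        # LPS (GL mode) vs array, per AF bin, on overlapping imputed SNPs
        a = per_snp_by_arm[f"gl_{depth:g}x"]
        b = per_snp_by_arm["array"]
        which = bins.assign(eval_afs)
        for b_i, label in enumerate(bins.labels):
            sel = which == b_i
            frac = cc.fraction_more_accurate(a[sel], b[sel])
            fma_rows.append((depth, label, frac))

    # ---- case/control cohort: PRS, AUC, cross-platform agreement
    _stage("pool cohort")
    pool = sim.simulate_cohort(
        population,
        config.pool_size,
        config.cohort_switch_rate,
        config.cohort_mutation_rate,
        seed=seeds["pool_cohort"],
    )
    weights = sim.assign_effects(
        population.population_af,
        config.n_causal,
        config.h2,
        config.weight_noise_sd,
        seed=seeds["weights"],
        site_ids=panel.site_ids,
        eff_sample_size=config.eff_sample_size,
    )
    phen = sim.simulate_phenotypes(
        pool, weights, config.prevalence, config.n_cases, config.n_controls,
        seed=seeds["phenotypes"],
    )
    cohort = pool.subset(phen.selected)
    labels = phen.selected_labels
    prs_afs = afs if afs is not None else cohort.allele_frequencies

    sig = [
        s for s, p in zip(weights.site_id, weights.p_value) if p < config.sig_threshold
    ]
    sig_clumped = (
        prs_mod.ld_clump(cohort.genotypes, panel.site_ids, weights, config.ld_r2)
        if sig
        else []
    )
    sig_set = [s for s in sig_clumped if s in set(sig)]

    cohort_reads = rd.simulate_reads(
        cohort, config.source_depth, config.error_rate, config.overdispersion,
        seed=seeds["reads_prs"],
    )
    dosage_by_arm: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "truth": (cohort.genotypes.astype(float), np.arange(panel.n_sites))
    }
    for d_i, depth in enumerate(config.depth_grid):
        _stage(f"depth {depth}x (prs)")
        reads_d = rd.downsample_reads(cohort_reads, depth, seed=seeds["downsample_prs"] + d_i)
        dos = imp.impute_gl(rd.compute_gl(reads_d), panel, params, dtype=dtype)
        keep = imp.filter_by_info(dos, config.info_threshold)
        dosage_by_arm[f"gl_{depth:g}x"] = (dos.dosage, np.flatnonzero(keep))
    _stage("array arm (prs)")
    prs_array = rd.simulate_array(
        cohort, config.array_fraction, config.array_error,
        seed=seeds["array_prs"], afs=prs_afs,
    )
    arr_dos2 = imp.impute_hardcall(prs_array, panel, params, dtype=dtype)
    keep2 = imp.filter_by_info(arr_dos2, config.info_threshold)
    dosage_by_arm["array"] = (arr_dos2.dosage, np.flatnonzero(keep2))

    prs_rows, pt_tables = [], {}
    scores_by_arm: dict[str, np.ndarray] = {}
    for arm, (mat, keep_cols) in dosage_by_arm.items():
        ids = panel.site_ids[keep_cols]
        sub = mat[:, keep_cols]
        best, table = prs_mod.p_plus_t(
            sub, ids, weights, labels,
            thresholds=config.p_thresholds, r2_threshold=config.ld_r2,
            ld_reference=cohort.genotypes[:, keep_cols],
        )
        pt_tables[arm] = table
        models = []
        if best is not None:
            models.append((best.model, best))
        arm_sig = [s for s in sig_set if s in set(ids)]
        if arm_sig:
            unadj = prs_mod.normalize_scores(
                prs_mod.compute_prs(sub, ids, weights, arm_sig, model="unadjusted")
            )
            models.append(("unadjusted", unadj))
            scores_by_arm[arm] = unadj.scores
        for model, res in models:
            a = ev.auc(res.scores, labels, seed=seeds["auc_boot"])
            gs = ev.group_summary(res.scores, labels)
            prs_rows.append(
                (arm, model, len(res.snps_used), a.auc, a.ci_low, a.ci_high,
                 gs.case_mean, gs.control_mean)
            )

    corr_rows = []
    arms = sorted(scores_by_arm)
    for i, a_name in enumerate(arms):
        for b_name in arms[i + 1:]:
            r, r2 = ev.score_correlation(scores_by_arm[a_name], scores_by_arm[b_name])
            corr_rows.append((a_name, b_name, r, r2))

    scores_df = pd.DataFrame({"individual": phen.selected, "label": labels})
    for arm, s in scores_by_arm.items():
        scores_df[f"score_{arm}"] = s

    bundle = ExperimentBundle(
        coverage=pd.DataFrame(coverage_rows, columns=["depth", "covered_fraction", "gini"]),
        concordance=pd.DataFrame(
            conc_rows, columns=["mode", "depth", "r2", "ndr", "fpr", "fnr", "n_sites"]
        ),
        af_bins=pd.DataFrame(
            bin_rows,
            columns=["mode", "depth", "bin", "n_snps", "pooled_r2", "mean_snp_r2", "sd_snp_r2"],
        ),
        fraction_more_accurate=pd.DataFrame(
            fma_rows, columns=["depth", "bin", "fraction_lps_better"]
        ),
        prs=pd.DataFrame(
            prs_rows,
            columns=["arm", "model", "n_snps", "auc", "ci_low", "ci_high",
                     "case_mean", "control_mean"],
        ),
        pt_tables=pt_tables,
        score_correlations=pd.DataFrame(corr_rows, columns=["arm_a", "arm_b", "r", "r2"]),
        scores=scores_df,
        manifest={
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "stage_seeds": seeds,
            "n_sites": int(panel.n_sites),
            "n_panel_haplotypes": int(panel.n_haplotypes),
        },
    )
    _stage("done")
    if outdir is not None:
        bundle.write(outdir)
    return bundle
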