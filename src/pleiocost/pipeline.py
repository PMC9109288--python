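"""End-to-end workflow: simulate an admixture E&R experiment to sync files,
and analyze sync files into selection, cost-of-pleiotropy and divergence
results.

The analyze step always goes through the sync text format, so the synthetic
path exercises exactly the interfaces a real PoPoolation2 dataset would use.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import divergence, polarity, selstats, sync_io
from .sim import (BASES, Design, ExperimentDataset, PoolSeqConfig, SimConfig,
                  run_experiment)

log = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    min_count: int = 5            # summed-count polymorphism threshold
    max_freq: float = 0.9         # strict upper bound on q110 when conditioning
    boundary_eps: Optional[float] = None  # default 1 / (2 * coverage)
    n_bins: int = 5
    n_boot: int = 1000
    n_perm: int = 1000
    n_components: int = 2
    mask_bed: Optional[str] = None
    mask_flank: int = 5
    seed: int = 0


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    poolseq: PoolSeqConfig = field(default_factory=PoolSeqConfig)
    design: Design = field(default_factory=Design)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design_raw = dict(raw.get("design", {}))
        if "shared_history" in design_raw:
            design_raw["shared_history"] = {
                tuple(k.split(",")): int(v) for k, v in design_raw["shared_history"].items()
            }
        if "pairs" in design_raw:
            design_raw["pairs"] = tuple(tuple(p) for p in design_raw["pairs"])
        if "parental_ids" in design_raw:
            design_raw["parental_ids"] = tuple(design_raw["parental_ids"])
        return cls(
            sim=SimConfig(**raw.get("simulate", {})),
            poolseq=PoolSeqConfig(**raw.get("poolseq", {})),
            design=Design(**design_raw),
            analysis=AnalysisParams(**raw.get("analysis", {})),
            seed=int(raw.get("seed", 0)),
        )

    def config_hash(self) -> str:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj
        payload = json.dumps(
            {"sim": _clean(asdict(self.sim)), "poolseq": _clean(asdict(self.poolseq)),
             "design": _clean(asdict(self.design)), "seed": self.seed},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# simulate: dataset -> sync files on disk
# ---------------------------------------------------------------------------

def _counts_to_sync_records(dataset: ExperimentDataset, column_sources) -> list:
    """Assemble SyncRecord rows from (counts, depth) sample columns.

    column_sources is an ordered list of (label, {gen: (counts, depth)} key,
    gen) resolved to per-locus counts; beneficial-allele reads go to the
    beneficial base, the remainder to the reference base.
    """
    loci = dataset.loci
    n_loci = len(loci)
    base_idx = {b: i for i, b in enumerate(BASES)}
    ref_idx = loci["ref"].map(base_idx).to_numpy()
    alt_idx = loci["beneficial_base"].map(base_idx).to_numpy()
    per_sample = []
    for counts, depth in column_sources:
        sample = np.zeros((n_loci, 6), dtype=np.int64)
        sample[np.arange(n_loci), alt_idx] = counts
        sample[np.arange(n_loci), ref_idx] += depth - counts
        per_sample.append(sample)
    stacked = np.stack(per_sample, axis=1)      # loci x samples x 6
    records = []
    for i in range(n_loci):
        records.append(sync_io.SyncRecord(
            chrom=loci["chrom"].iloc[i],
            pos=int(loci["pos"].iloc[i]),
            ref=loci["ref"].iloc[i],
            samples=stacked[i],
        ))
    return records


def write_dataset(dataset: ExperimentDataset, outdir, config: PipelineConfig, force: bool = False) -> dict:
    """Write parental and per-pair mixed sync files, the truth table and a
    manifest; rerunning with the same config and seed is byte-identical."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{outdir} already holds a dataset (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    design = dataset.design

    parental_labels, parental_cols = [], []
    for rep in design.parental_ids:
        for gen in sorted(dataset.parental_counts[rep]):
            parental_labels.append(f"{rep}:{gen}")
            parental_cols.append(dataset.parental_counts[rep][gen])
    sync_io.write_sync(_counts_to_sync_records(dataset, parental_cols),
                       outdir / "parental.sync")

    mixed_files = {}
    mixed_labels = {}
    for imm, rec in design.pairs:
        label = design.pair_label(imm, rec)
        cols, labels = [], []
        for mrep in range(design.n_mix_replicates):
            for gen in sorted(design.mixed_timepoints):
                labels.append(f"{label}:{mrep}:F{gen}")
                cols.append(dataset.mixed_counts[label][mrep][gen])
        fname = f"mixed_{imm}_{rec}.sync"
        sync_io.write_sync(_counts_to_sync_records(dataset, cols), outdir / fname)
        mixed_files[label] = fname
        mixed_labels[label] = labels

    dataset.loci.reset_index().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "seed": dataset.seed,
        "config_hash": config.config_hash(),
        "mix_proportion": dataset.config.mix_proportion,
        "adapt_generations": dataset.config.adapt_generations,
        "coverage": dataset.poolseq.coverage,
        "parental_file": "parental.sync",
        "parental_samples": parental_labels,
        "mixed_files": mixed_files,
        "mixed_samples": mixed_labels,
        "parental_ids": list(design.parental_ids),
        "pairs": [list(p) for p in design.pairs],
        "n_mix_replicates": design.n_mix_replicates,
        "mixed_timepoints": list(design.mixed_timepoints),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def simulate(config: PipelineConfig, outdir, force: bool = False) -> ExperimentDataset:
    """Run the forward simulation and write the full synthetic dataset."""
    dataset = run_experiment(config.sim, config.poolseq, config.design, config.seed)
    write_dataset(dataset, outdir, config, force=force)
    return dataset


# ---------------------------------------------------------------------------
# analyze: sync files -> results bundle
# ---------------------------------------------------------------------------

def _allele_freq(base_freq: np.ndarray, base_allele: pd.Series, wanted: pd.Series) -> np.ndarray:
    """Frequency of `wanted` allele given the tracked allele's frequency."""
    same = (wanted.values == base_allele.values)
    return np.where(same, base_freq, 1.0 - base_freq)


class AnalysisResult(dict):
    """Plain dict of result tables/values; attribute access for convenience."""

    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError as exc:
            raise AttributeError(name) from exc


def analyze(rundir, params: Optional[AnalysisParams] = None, outdir=None) -> AnalysisResult:
    """Full inference chain on a simulated (or externally supplied) run
    directory holding a manifest plus sync files.

    Stages: read sync -> optional interval masking -> biallelic SNP calling
    (summed min count) -> per-parent polarization and conditioning ->
    per-pair origin classes, frequency changes, selection coefficients,
    cost of pleiotropy -> parental F_ST and PCA.
    """
    rundir = Path(rundir)
    params = params or AnalysisParams()
    with open(rundir / "manifest.json") as fh:
        manifest = json.load(fh)
    coverage = manifest.get("coverage", 50)
    eps = params.boundary_eps if params.boundary_eps is not None else 1.0 / (2 * coverage)

    # --- load and merge all sync files on shared positions
    parental_records = sync_io.read_sync(rundir / manifest["parental_file"])
    labels = list(manifest["parental_samples"])
    merged = parental_records
    key = [(r.chrom, r.pos) for r in parental_records]
    for pair_label, fname in manifest["mixed_files"].items():
        recs = sync_io.read_sync(rundir / fname)
        if [(r.chrom, r.pos) for r in recs] != key:
            raise ValueError(f"{fname}: positions do not match parental sync")
        merged = [
            sync_io.SyncRecord(a.chrom, a.pos, a.ref, np.vstack([a.samples, b.samples]))
            for a, b in zip(merged, recs)
        ]
        labels += list(manifest["mixed_samples"][pair_label])
    col = {lab: i for i, lab in enumerate(labels)}
    n_read = len(merged)

    # --- filtering
    if params.mask_bed:
        masks = sync_io.MaskSet.from_bed(params.mask_bed)
        merged = sync_io.apply_masks(merged, masks, flank=params.mask_flank)
    n_masked = len(merged)
    called, allele_pairs = sync_io.call_snps(merged, min_count=params.min_count)
    n_called = len(called)
    if n_called == 0:
        raise ValueError("no biallelic SNPs survive filtering")
    sites = sync_io.records_frame(called, allele_pairs)
    # frequencies of the minor allele; any other allele's frequency derives
    # from it because sites are biallelic
    minor_pairs = [(minor, major) for major, minor in allele_pairs]
    freqs, depths = sync_io.frequencies(called, [p[0] for p in minor_pairs])

    # --- per-parent polarization + conditioning
    t_adapt = manifest["adapt_generations"]
    polarized, conditioned, cond_counts = {}, {}, {}
    for rep in manifest["parental_ids"]:
        f0 = freqs[:, col[f"{rep}:0"]]
        f110 = freqs[:, col[f"{rep}:{t_adapt}"]]
        pol = polarity.polarize_to_rising(f0, f110, minor_pairs,
                                          sites["chrom"], sites["pos"], rep)
        pol["snp_idx"] = np.flatnonzero(~(np.isnan(f0) | np.isnan(f110)))
        polarized[rep] = pol
        conditioned[rep], cond_counts[rep] = polarity.condition_snps(pol, params.max_freq)

    # --- parental divergence and PCA at admixture time
    rep_cols_110 = [col[f"{rep}:{t_adapt}"] for rep in manifest["parental_ids"]]
    fst_110 = divergence.fst_matrix(freqs[:, rep_cols_110], manifest["parental_ids"])
    parental_cols = [col[lab] for lab in manifest["parental_samples"]]
    pca_parental = divergence.pca_frequencies(
        freqs[:, parental_cols], manifest["parental_samples"], params.n_components)

    # --- per-pair analyses
    windows = sorted(manifest["mixed_timepoints"])
    pair_results = {}
    estimate_tables = []
    for imm, rec in [tuple(p) for p in manifest["pairs"]]:
        label = f"{imm}->{rec}"
        classes = polarity.assign_origin(conditioned[imm], conditioned[rec])
        classes = classes.merge(sites.reset_index(names="snp_idx"), on=["chrom", "pos"])
        # the tracked allele per class: immigrant polarization where defined,
        # else the recipient's
        benef = classes["beneficial_allele_immigrant"].fillna(
            classes["beneficial_allele_recipient"])
        idx = classes["snp_idx"].to_numpy()
        minor_allele = sites["minor"].iloc[idx].reset_index(drop=True)

        per_rep = []
        for mrep in range(manifest["n_mix_replicates"]):
            fcols = {tp: col[f"{label}:{mrep}:F{tp}"] for tp in windows}
            fr = {tp: _allele_freq(freqs[idx, fcols[tp]], minor_allele, benef)
                  for tp in windows}
            table = selstats.estimate_table(
                classes.assign(pos=classes["pos"]),
                fr[windows[0]], fr[windows[1]], windows[1] - windows[0],
                f"F{windows[0]}->F{windows[1]}", eps)
            table.insert(0, "pair", label)
            table.insert(1, "mix_replicate", mrep)
            late = selstats.estimate_table(
                classes.assign(pos=classes["pos"]),
                fr[windows[1]], fr[windows[2]], windows[2] - windows[1],
                f"F{windows[1]}->F{windows[2]}", eps)
            late.insert(0, "pair", label)
            late.insert(1, "mix_replicate", mrep)
            estimate_tables += [table, late]
            per_rep.append({"freqs": fr, "table": table, "late": late})

        def _pooled(cls_name, tp_from, tp_to):
            starts = np.concatenate([r["freqs"][tp_from][classes["origin_class"] == cls_name]
                                     for r in per_rep])
            ends = np.concatenate([r["freqs"][tp_to][classes["origin_class"] == cls_name]
                                   for r in per_rep])
            return starts, ends

        afc = {}
        for cls_name in (polarity.ORIGIN_IMMIGRANT, polarity.ORIGIN_RECIPIENT):
            if (classes["origin_class"] == cls_name).any():
                s0, s1 = _pooled(cls_name, windows[0], windows[1])
                afc[cls_name] = selstats.mean_afc(s0, s1, params.n_boot, params.seed)
                s1b, s2 = _pooled(cls_name, windows[1], windows[2])
                afc[cls_name + ":late"] = selstats.mean_afc(s1b, s2, params.n_boot, params.seed)

        # frequency dependence over the immigrant parent's full beneficial set
        imm_mask = classes["beneficial_allele_immigrant"].notna().to_numpy()
        starts = np.concatenate([r["freqs"][windows[0]][imm_mask] for r in per_rep])
        ends = np.concatenate([r["freqs"][windows[1]][imm_mask] for r in per_rep])
        bins = selstats.bin_by_start_frequency(starts, ends - starts, params.n_bins,
                                               params.n_perm, params.seed)

        pooled_tables = pd.concat([r["table"] for r in per_rep], ignore_index=True)
        costs = {}
        for focal in (selstats.IMMIGRANT, selstats.RECIPIENT):
            cls_name = f"{focal}-beneficial"
            if (pooled_tables["origin_class"] == cls_name).any():
                costs[focal] = selstats.cost_of_pleiotropy(
                    pooled_tables, focal, params.n_boot, params.seed)

        # realized parental s over adaptation: for each focal class, the same
        # alleles' selection coefficient in their own parental population
        realized = {}
        for focal, parent, cls_name in ((selstats.IMMIGRANT, imm, polarity.ORIGIN_IMMIGRANT),
                                        (selstats.RECIPIENT, rec, polarity.ORIGIN_RECIPIENT)):
            excl = classes["origin_class"] == cls_name
            sel_idx = classes.loc[excl, "snp_idx"].to_numpy()
            if not len(sel_idx):
                realized[focal] = {"mean": np.nan, "n": 0}
                continue
            benef_excl = benef[excl].reset_index(drop=True)
            minor_excl = sites["minor"].iloc[sel_idx].reset_index(drop=True)
            q0 = _allele_freq(freqs[sel_idx, col[f"{parent}:0"]], minor_excl, benef_excl)
            q110 = _allele_freq(freqs[sel_idx, col[f"{parent}:{t_adapt}"]], minor_excl, benef_excl)
            realized[focal] = {
                "mean": float(np.mean(selstats.estimate_s(q0, q110, t_adapt, eps))),
                "n": int(len(sel_idx)),
            }

        # negative control: the immigrant-beneficial alleles in the unmixed
        # immigrant parent over the matching late window (110 -> 130)
        imm_excl = classes["origin_class"] == polarity.ORIGIN_IMMIGRANT
        ctrl_idx = classes.loc[imm_excl, "snp_idx"].to_numpy()
        control = None
        if len(ctrl_idx):
            benef_ctrl = benef[imm_excl].reset_index(drop=True)
            minor_ctrl = sites["minor"].iloc[ctrl_idx].reset_index(drop=True)
            gens = sorted(int(lab.split(":")[1]) for lab in manifest["parental_samples"]
                          if lab.startswith(f"{imm}:"))
            c110 = _allele_freq(freqs[ctrl_idx, col[f"{imm}:{t_adapt}"]], minor_ctrl, benef_ctrl)
            c130 = _allele_freq(freqs[ctrl_idx, col[f"{imm}:{gens[-1]}"]], minor_ctrl, benef_ctrl)
            control = selstats.control_afc(c110, c130, params.n_boot, params.seed)

        # PCA of this pair: founders at their sampled generations + mixtures
        pca_labels = [f"{r}:{g}" for r in (imm, rec)
                      for g in sorted(int(lab.split(":")[1]) for lab in manifest["parental_samples"]
                                      if lab.startswith(f"{r}:")) if g > 0]
        pca_labels += manifest["mixed_samples"][label]
        pca_pair = divergence.pca_frequencies(
            freqs[:, [col[lab] for lab in pca_labels]], pca_labels, params.n_components)
        imm_rows = [lab for lab in pca_labels if lab.startswith(f"{imm}:")]
        anchor = pca_pair.coordinates.loc[imm_rows].to_numpy().mean(axis=0)
        dists = {}
        for tp in windows:
            pts = pca_pair.coordinates.loc[
                [f"{label}:{mrep}:F{tp}" for mrep in range(manifest["n_mix_replicates"])]]
            dists[f"F{tp}"] = float(np.linalg.norm(pts.to_numpy() - anchor, axis=1).mean())

        pair_results[label] = {
            "immigrant": imm, "recipient": rec,
            "classes": classes, "afc": afc, "bins": bins, "costs": costs,
            "realized": realized, "control": control,
            "pca": pca_pair, "pca_dist_to_immigrant": dists,
            "fst_110": float(fst_110.loc[imm, rec]),
            "n_class": classes["origin_class"].value_counts().to_dict(),
        }

    estimates = pd.concat(estimate_tables, ignore_index=True) if estimate_tables else pd.DataFrame()
    result = AnalysisResult(
        filter_counts={"read": n_read, "after_mask": n_masked, "called": n_called,
                       "conditioned": {r: c for r, c in cond_counts.items()}},
        sites=sites, freqs=freqs, depths=depths, columns=col,
        polarized=polarized, conditioned=conditioned,
        fst_110=fst_110, pca_parental=pca_parental,
        pairs=pair_results, estimates=estimates,
        params=params, manifest=manifest,
    )
    if outdir is not None:
        _write_results(result, outdir)
    return result


def _write_results(result: AnalysisResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(result["estimates"]):
        result["estimates"].drop(columns=["snp_idx"], errors="ignore").to_csv(
            outdir / "selection_estimates.tsv", sep="\t", index=False)
    result["fst_110"].to_csv(outdir / "fst_parental_110.tsv", sep="\t")
    result["pca_parental"].coordinates.to_csv(outdir / "pca_parental.tsv", sep="\t")
    cost_rows, summary = [], {}
    for label, pr in result["pairs"].items():
        pr["bins"].to_frame().to_csv(outdir / f"bins_{label.replace('->', '_')}.tsv",
                                     sep="\t", index=False)
        for focal, cost in pr["costs"].items():
            cost_rows.append({"pair": label, "focal_origin": focal, **cost,
                              "realized_s": pr["realized"][focal]["mean"]})
        summary[label] = {
            "fst_110": pr["fst_110"],
            "afc": {k: v for k, v in pr["afc"].items()},
            "correlation": pr["bins"].correlation,
            "correlation_p": pr["bins"].p_value,
            "pca_dist_to_immigrant": pr["pca_dist_to_immigrant"],
            "n_class": pr["n_class"],
            "control": pr["control"],
        }
    if cost_rows:
        pd.DataFrame(cost_rows).to_csv(outdir / "cost_table.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump({"filter_counts": result["filter_counts"], "pairs": summary},
                  fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# replica: scaled-down end-to-end reproduction of the study's result surface
# ---------------------------------------------------------------------------

def replica_config(seed: int = 0, cost: float = 0.05, cost_dominance: float = 0.0,
                   diverged_only: bool = False) -> PipelineConfig:
    """Desk-scale study conditions: N = 300, L = 60 redundant loci starting at
    frequency 0.05, optimum shift 8 under omega = 7, per-locus cost c with
    dominance h_c, 15:85 mixtures in triplicate, Pool-Seq at ~40x."""
    sim = SimConfig(census_size=300, n_loci=60, cost_per_locus=cost,
                    cost_dominance=cost_dominance, seed=seed)
    psc = PoolSeqConfig(coverage=40, coverage_model="poisson")
    if diverged_only:
        design = Design(parental_ids=("R1", "R2"), shared_history={},
                        pairs=(("R1", "R2"), ("R2", "R1")))
    else:
        design = Design()
    analysis = AnalysisParams(seed=seed)
    return PipelineConfig(sim=sim, poolseq=psc, design=design, analysis=analysis, seed=seed)


def diverged_pairs(config: PipelineConfig) -> list[str]:
    """Pair labels whose members do not share early history."""
    shared = {frozenset(g) for g in config.design.shared_history}
    return [config.design.pair_label(i, r) for i, r in config.design.pairs
            if frozenset((i, r)) not in shared]


def similar_pairs(config: PipelineConfig) -> list[str]:
    shared = {frozenset(g) for g in config.design.shared_history}
    return [config.design.pair_label(i, r) for i, r in config.design.pairs
            if frozenset((i, r)) in shared]


def pooled_class_afc(result: AnalysisResult, pair_labels, origin_class: str,
                     window=("F1", "F20"), n_boot: int = 1000, seed: int = 0) -> dict:
    """Mean AFC of one origin class pooled over pairs and mix replicates."""
    tp_from = int(window[0].lstrip("F"))
    tp_to = int(window[1].lstrip("F"))
    starts, ends = [], []
    for label in pair_labels:
        pr = result["pairs"][label]
        classes = pr["classes"]
        mask = (classes["origin_class"] == origin_class).to_numpy()
        idx = classes.loc[mask, "snp_idx"].to_numpy()
        benef = classes["beneficial_allele_immigrant"].fillna(
            classes["beneficial_allele_recipient"])[mask].reset_index(drop=True)
        minor = result["sites"]["minor"].iloc[idx].reset_index(drop=True)
        for mrep in range(result["manifest"]["n_mix_replicates"]):
            c_from = result["columns"][f"{label}:{mrep}:F{tp_from}"]
            c_to = result["columns"][f"{label}:{mrep}:F{tp_to}"]
            starts.append(_allele_freq(result["freqs"][idx, c_from], minor, benef))
            ends.append(_allele_freq(result["freqs"][idx, c_to], minor, benef))
    return selstats.mean_afc(np.concatenate(starts), np.concatenate(ends), n_boot, seed)


def pooled_frequency_dependence(result: AnalysisResult, pair_labels,
                                n_bins: int = 5, n_perm: int = 1000, seed: int = 0):
    """Fig-4A-style analysis pooled over pairs: start frequency vs change of
    all immigrant-parent beneficial alleles."""
    starts, changes = [], []
    for label in pair_labels:
        pr = result["pairs"][label]
        classes = pr["classes"]
        mask = classes["beneficial_allele_immigrant"].notna().to_numpy()
        idx = classes.loc[mask, "snp_idx"].to_numpy()
        benef = classes.loc[mask, "beneficial_allele_immigrant"].reset_index(drop=True)
        minor = result["sites"]["minor"].iloc[idx].reset_index(drop=True)
        for mrep in range(result["manifest"]["n_mix_replicates"]):
            f1 = _allele_freq(result["freqs"][idx, result["columns"][f"{label}:{mrep}:F1"]],
                              minor, benef)
            f20 = _allele_freq(result["freqs"][idx, result["columns"][f"{label}:{mrep}:F20"]],
                               minor, benef)
            starts.append(f1)
            changes.append(f20 - f1)
    return selstats.bin_by_start_frequency(np.concatenate(starts), np.concatenate(changes),
                                           n_bins, n_perm, seed)


def replica(seed: int = 0, outdir=None, cost: float = 0.05, cost_dominance: float = 0.0,
            diverged_only: bool = False) -> dict:
    """Run the scaled-down end-to-end replica and evaluate the four headline
    checks: immigrant-vs-recipient asymmetry, negative frequency dependence,
    cost below realized advantage, and PCA movement toward the immigrant
    founder.  Each check reports pass / fail / inconclusive with its numbers.
    """
    import tempfile

    config = replica_config(seed, cost, cost_dominance, diverged_only)
    with tempfile.TemporaryDirectory() as tmp:
        rundir = Path(outdir) / "run" if outdir else Path(tmp) / "run"
        dataset = simulate(config, rundir, force=True)
        result = analyze(rundir, config.analysis,
                         outdir=(Path(outdir) / "results" if outdir else None))
    div = diverged_pairs(config)
    sim_pairs = similar_pairs(config)
    boot_seed = config.analysis.seed

    imm = pooled_class_afc(result, div, polarity.ORIGIN_IMMIGRANT, seed=boot_seed)
    rec = pooled_class_afc(result, div, polarity.ORIGIN_RECIPIENT, seed=boot_seed)
    asym = imm["mean"] - rec["mean"]
    # the two classes are disjoint SNP sets, so the bootstrap SEs combine
    se_diff = np.hypot(imm["ci_high"] - imm["ci_low"], rec["ci_high"] - rec["ci_low"]) / 3.92
    check_asym = {
        "immigrant_afc": imm, "recipient_afc": rec, "asymmetry": asym,
        "asymmetry_se": float(se_diff),
        "passed": bool(imm["mean"] > 0 and asym > 1.96 * se_diff),
    }

    bins = pooled_frequency_dependence(result, div, config.analysis.n_bins,
                                       config.analysis.n_perm, boot_seed)
    check_freq = {
        "correlation": bins.correlation, "p_value": bins.p_value, "n": bins.n,
        "passed": bool(np.isfinite(bins.correlation) and bins.correlation < 0
                       and bins.p_value < 0.05),
    }

    costs, realized = [], []
    for label in div:
        pr = result["pairs"][label]
        if selstats.RECIPIENT in pr["costs"]:
            costs.append(pr["costs"][selstats.RECIPIENT]["cost"])
            realized.append(pr["realized"][selstats.RECIPIENT]["mean"])
    mean_cost = float(np.mean(costs)) if costs else np.nan
    mean_realized = float(np.mean(realized)) if realized else np.nan
    ratio = mean_cost / mean_realized if realized and mean_realized else np.nan
    check_cost = {
        "cost": mean_cost, "realized_s": mean_realized, "ratio": ratio,
        "passed": bool(np.isfinite(ratio) and mean_cost > 0 and ratio < 1),
    }

    move = [{"pair": label, **result["pairs"][label]["pca_dist_to_immigrant"]}
            for label in div]
    d1 = float(np.mean([m["F1"] for m in move]))
    d20 = float(np.mean([m["F20"] for m in move]))
    d29 = float(np.mean([m["F29"] for m in move]))
    check_pca = {"distances": move, "mean_F1": d1, "mean_F20": d20, "mean_F29": d29,
                 "passed": bool(move and d20 < d1 and d29 < d1)}

    report = {
        "seed": seed, "cost": cost, "cost_dominance": cost_dominance,
        "config_hash": config.config_hash(),
        "checks": {
            "masking_asymmetry": check_asym,
            "frequency_dependence": check_freq,
            "cost_below_realized": check_cost,
            "pca_movement": check_pca,
        },
        "fst": {label: result["pairs"][label]["fst_110"]
                for label in list(result["pairs"])},
        "diverged_pairs": div, "similar_pairs": sim_pairs,
        "filter_counts": result["filter_counts"],
    }
    if outdir is not None:
        with open(Path(outdir) / "replica_report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    report["_result"] = result
    return report
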