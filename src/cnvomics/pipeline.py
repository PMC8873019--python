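"""End-to-end orchestration of the multi-omic dosage pipeline.

Stages run in a fixed order — synthetic data, CNV QC, expression QC and
covariates, RNA differential expression, protein differential expression,
co-expression networks with genotype association and cross-omics
preservation, enrichment, integration — and communicate only through
declared files in the run directory, so stages can be toggled without
shifting each other's random streams (each stage derives its own seed
from the master seed and its name).  A manifest records file hashes and
row counts; identical configuration reproduces identical hashes.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate, cnv, qc, de, protein, network, enrich, phenotype
from .io import (write_matrix, read_matrix, write_table, read_table,
                 write_yaml, sha256_file, write_manifest)

log = logging.getLogger("cnvomics")

STAGES = ("synth", "cnv", "qc", "de", "dep", "net", "enrich", "integrate")


@dataclass
class RunConfig:
    """Everything a run needs; serialized next to its outputs."""

    outdir: str = "run"
    seed: int = 0
    # synthetic scale
    n_genes: int = 2000
    n_locus: int = 29
    n_modules: int = 5
    module_size: int = 100
    n_proteins: int = 300
    # analysis choices
    timepoint: str = "org1M"
    tpm_min: float = 0.5
    expressed_frac: float = 0.8
    outlier_z_cut: float = -2.0
    max_clone_frac: float = 0.5
    fdr: float = 0.10
    burden_z_max: float = 1.5
    n_perm: int = 1000
    n_boot: int = 2000
    network_power: int = 6
    min_module_size: int = 30
    preservation_perm: int = 50
    stages: tuple[str, ...] = STAGES
    truth: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .io import read_yaml
        d = read_yaml(path) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the requested stages; returns the manifest."""
    rundir = Path(config.outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    write_yaml(config.to_dict(), rundir / "config.yaml")
    stages = tuple(stages or config.stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    manifest: dict = {"stages": {}, "seed": config.seed}
    for stage in STAGES:
        if stage not in stages:
            continue
        fn = _STAGE_FN[stage]
        t0 = time.time()
        try:
            outputs = fn(config, rundir)
        except Exception as exc:  # noqa: BLE001 - structured stage error
            raise StageError(stage, exc) from exc
        entry = {}
        for path in outputs:
            df_rows = _count_rows(path)
            entry[Path(path).name] = {"sha256": sha256_file(path),
                                      "rows": df_rows}
        manifest["stages"][stage] = entry
        log.info("stage %s: %d outputs in %.1fs", stage, len(outputs),
                 time.time() - t0)
    write_manifest(rundir, manifest)
    return manifest


def _count_rows(path) -> int:
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)


# ---------------------------------------------------------------------------
# stages

def _truth(config: RunConfig) -> simulate.SimTruth:
    t = simulate.SimTruth(**config.truth) if config.truth else simulate.SimTruth()
    t.seed = config.stage_seed("synth")
    return t


def _stage_synth(config: RunConfig, rundir: Path) -> list[Path]:
    seed = config.stage_seed("synth")
    design = simulate.generate_design()
    ann = simulate.generate_annotations(config.n_genes, config.n_locus,
                                        config.n_modules, seed=seed,
                                        module_size=config.module_size)
    truth = _truth(config)
    counts, tpm = simulate.simulate_rnaseq(design, ann, truth)
    pmap = simulate.generate_protein_map(ann, n_proteins=config.n_proteins,
                                         seed=seed)
    peptides = simulate.simulate_proteomics(design, ann, pmap, truth,
                                            timepoint=config.timepoint)
    ref = simulate.simulate_celltype_reference(("Neuron", "IP", "RG"), ann,
                                               seed=seed)
    calls, markers = simulate.simulate_cnv_calls(seed=seed)
    diam = simulate.simulate_organoid_diameters(seed=seed)
    ct = simulate.simulate_ct_values(log2_fc={"TARGET1": {"DEL": -1.0}},
                                     seed=seed)
    # lightweight stand-in sequencing QC metrics driven by library size
    rng = np.random.default_rng(seed + 7)
    lib = counts.sum(axis=0)
    metrics = pd.DataFrame(
        {f"metric{i+1}": np.log10(lib) * rng.normal(1, 0.2)
         + rng.normal(0, 0.1, len(lib)) for i in range(8)},
        index=lib.index)
    out = [
        write_table(design, rundir / "design.csv"),
        write_table(ann, rundir / "annotations.tsv"),
        write_matrix(counts, rundir / "counts.tsv"),
        write_matrix(tpm, rundir / "tpm.tsv"),
        write_table(pmap, rundir / "protein_map.csv"),
        write_table(peptides, rundir / "peptides.csv"),
        write_matrix(ref, rundir / "celltype_reference.tsv"),
        write_table(calls, rundir / "cnv_calls.csv"),
        write_table(diam, rundir / "diameters.csv"),
        write_table(ct, rundir / "ct_values.csv"),
        write_matrix(metrics, rundir / "qc_metrics.tsv", index_label="sample_id"),
    ]
    markers_df = pd.concat([pd.DataFrame({"chrom": c, "pos": p})
                            for c, p in markers.items()], ignore_index=True)
    out.append(write_table(markers_df, rundir / "marker_map.tsv"))
    return out


def _stage_cnv(config: RunConfig, rundir: Path) -> list[Path]:
    calls = read_table(rundir / "cnv_calls.csv")
    markers_df = read_table(rundir / "marker_map.tsv")
    markers = {c: np.sort(g["pos"].to_numpy())
               for c, g in markers_df.groupby("chrom")}
    stitched = cnv.stitch_cnvs(calls, markers)
    filtered = cnv.filter_cnvs(stitched)
    locus = cnv.Interval("chr16", 29_500_000, 30_100_000)
    fibro = filtered[filtered["sample_id"] == "fibroblast"]
    clones = {s: g for s, g in filtered.groupby("sample_id")
              if s != "fibroblast"}
    report, retained = cnv.clone_burden_selection(fibro, clones, locus,
                                                  z_max=config.burden_z_max)
    report["retained"] = report["subject_id"].isin(retained)
    report["focal_confirmed"] = [
        cnv.confirm_focal_cnv(clones[s], locus, "DEL") if s in clones
        else cnv.confirm_focal_cnv(fibro, locus, "DEL")
        for s in report["subject_id"]]
    return [write_table(filtered, rundir / "cnv_filtered.tsv"),
            write_table(report, rundir / "cnv_burden.tsv")]


def _load_timepoint(config: RunConfig, rundir: Path):
    design = read_table(rundir / "design.csv")
    counts = read_matrix(rundir / "counts.tsv")
    tpm = read_matrix(rundir / "tpm.tsv")
    rna = design[(design["assay"] == "rna")
                 & (design["timepoint"] == config.timepoint)]
    cols = [c for c in counts.columns if c in set(rna["sample_id"])]
    return design, rna, counts[cols], tpm[cols]


def _stage_qc(config: RunConfig, rundir: Path) -> list[Path]:
    design, rna, counts, tpm = _load_timepoint(config, rundir)
    expressed = qc.filter_expressed_genes(tpm, rna, tpm_min=config.tpm_min,
                                          frac=config.expressed_frac)
    log_expr = np.log2(tpm.loc[expressed] + 1)
    outliers = qc.detect_outlier_samples(log_expr, z_cut=config.outlier_z_cut)
    keep_samples = outliers.loc[~outliers["flagged"], "sample_id"]
    log_expr = log_expr[keep_samples]
    rna_kept = rna[rna["sample_id"].isin(keep_samples)]
    kept_genes = qc.clone_variance_filter(log_expr, rna_kept,
                                          max_clone_frac=config.max_clone_frac)

    metrics = read_matrix(rundir / "qc_metrics.tsv").loc[keep_samples]
    seq_pcs = qc.compute_seq_pcs(metrics)
    geno = pd.get_dummies(rna_kept.set_index("sample_id")["genotype"])\
        .loc[keep_samples].to_numpy(float)
    svs = qc.estimate_surrogate_variables(log_expr.loc[kept_genes], geno,
                                          seed=config.stage_seed("qc"))
    candidates = seq_pcs.scores.join(svs)
    centered = log_expr.loc[kept_genes]
    centered = (centered.T - centered.mean(axis=1)).T
    sel = qc.select_covariates(centered, candidates)
    cov = candidates[sel.selected] if sel.selected else candidates.iloc[:, :0]
    return [
        write_table(pd.DataFrame({"gene_id": kept_genes}),
                    rundir / "genes_retained.tsv"),
        write_table(outliers, rundir / "outlier_report.tsv"),
        write_matrix(cov, rundir / "covariates.tsv", index_label="sample_id"),
    ]


def _stage_de(config: RunConfig, rundir: Path) -> list[Path]:
    design, rna, counts, _ = _load_timepoint(config, rundir)
    genes = read_table(rundir / "genes_retained.tsv")["gene_id"]
    outliers = read_table(rundir / "outlier_report.tsv")
    keep = outliers.loc[~outliers["flagged"], "sample_id"]
    cov = read_matrix(rundir / "covariates.tsv")
    counts = counts.loc[genes, [c for c in counts.columns if c in set(keep)]]
    rna = rna[rna["sample_id"].isin(counts.columns)]
    cov = cov.loc[counts.columns] if cov.shape[1] else None
    model = de.ModeratedDE(counts, rna, covariates=cov, fdr=config.fdr)
    res = model.fit()
    ann = read_table(rundir / "annotations.tsv")
    locus = set(ann.loc[ann["is_locus"], "gene_id"])
    out = []
    for name, table in res.tables.items():
        table = table.copy()
        table["is_locus"] = table["gene_id"].isin(locus)
        out.append(write_table(table, rundir / f"de_{name}.tsv"))
    (rundir / "de_summary.txt").write_text(res.summary() + "\n")
    out.append(rundir / "de_summary.txt")
    return out


def _stage_dep(config: RunConfig, rundir: Path) -> list[Path]:
    design = read_table(rundir / "design.csv")
    peptides = read_table(rundir / "peptides.csv")
    merged = protein.normalize_tmt_runs(peptides)
    collapsed = protein.collapse_subject_measurements(merged, design)
    res = protein.ProteinMixedDE(collapsed, fdr=config.fdr).fit()
    out = []
    for name, table in res.tables.items():
        out.append(write_table(table, rundir / f"dep_{name}.tsv"))
    pm = protein.protein_matrix_from_peptides(merged)
    out.append(write_matrix(pm, rundir / "protein_matrix.tsv",
                            index_label="protein_id"))
    (rundir / "dep_summary.txt").write_text(res.summary() + "\n")
    out.append(rundir / "dep_summary.txt")
    return out


def _stage_net(config: RunConfig, rundir: Path) -> list[Path]:
    design, rna, counts, tpm = _load_timepoint(config, rundir)
    genes = read_table(rundir / "genes_retained.tsv")["gene_id"]
    outliers = read_table(rundir / "outlier_report.tsv")
    keep = outliers.loc[~outliers["flagged"], "sample_id"]
    cov = read_matrix(rundir / "covariates.tsv")
    expr = np.log2(tpm.loc[genes, [c for c in tpm.columns if c in set(keep)]] + 1)
    if cov.shape[1]:
        expr = network.regress_covariates(expr, cov.loc[expr.columns])
    params = network.NetworkParams(power=config.network_power,
                                   min_module_size=config.min_module_size)
    res = network.CoexpressionNetwork(expr, params).fit()
    rna_kept = rna[rna["sample_id"].isin(expr.columns)]
    assoc = network.eigengene_genotype_association(res.eigengenes, rna_kept,
                                                   fdr=config.fdr)
    out = [
        write_table(pd.DataFrame({"gene_id": res.labels.index,
                                  "module": res.labels.to_numpy()}),
                    rundir / "modules.tsv"),
        write_matrix(res.eigengenes, rundir / "eigengenes.tsv",
                     index_label="sample_id"),
        write_matrix(res.kme, rundir / "kme.tsv"),
        write_table(assoc, rundir / "module_genotype.tsv"),
    ]
    pm_path = rundir / "protein_matrix.tsv"
    if pm_path.exists():
        pm = read_matrix(pm_path)
        pm.index = [p.removeprefix("P_") for p in pm.index]
        pres = network.module_preservation(
            expr, res.labels, pm, power=config.network_power,
            n_perm=config.preservation_perm, seed=config.stage_seed("net"))
        out.append(write_table(pres, rundir / "preservation.tsv"))
    (rundir / "net_summary.txt").write_text(res.summary() + "\n")
    out.append(rundir / "net_summary.txt")
    return out


def _stage_enrich(config: RunConfig, rundir: Path) -> list[Path]:
    ann = read_table(rundir / "annotations.tsv").fillna({"true_module": "",
                                                         "true_celltype": ""})
    de_table = read_table(rundir / "de_DEL_vs_CTRL.tsv")
    genes_retained = set(read_table(rundir / "genes_retained.tsv")["gene_id"])
    universe = ann[ann["gene_id"].isin(genes_retained)]
    locus = ann.loc[ann["is_locus"], "gene_id"].tolist()
    target = de_table.loc[(de_table["q"] < config.fdr)
                          & ~de_table["is_locus"], "gene_id"].tolist()
    out = []
    if len(target) >= 5 and len(universe) >= 2 * len(target):
        ens = enrich.build_matched_nulls(target, universe,
                                         n_lists=config.n_perm,
                                         seed=config.stage_seed("enrich"))
        gene_sets = {f"module_{m}": ann.loc[ann["true_module"] == m,
                                            "gene_id"].tolist()
                     for m in sorted(set(ann["true_module"]) - {""})}
        res = enrich.permutation_enrichment(target, gene_sets, ens,
                                            exclude=locus)
        out.append(write_table(res, rundir / "enrichment_sets.tsv"))
    ref = read_matrix(rundir / "celltype_reference.tsv")
    spec_m = enrich.celltype_specificity(ref)
    modules = read_table(rundir / "modules.tsv")
    tables = []
    for m in sorted(set(modules["module"]) - {network.GREY}):
        mod_genes = modules.loc[modules["module"] == m, "gene_id"].tolist()
        t = enrich.celltype_enrichment_table(mod_genes, spec_m,
                                             n_boot=config.n_boot,
                                             seed=config.stage_seed("enrich"))
        t.insert(0, "module", m)
        tables.append(t)
    if tables:
        out.append(write_table(pd.concat(tables, ignore_index=True),
                               rundir / "enrichment_celltypes.tsv"))
    return out


def _stage_integrate(config: RunConfig, rundir: Path) -> list[Path]:
    ann = read_table(rundir / "annotations.tsv")
    rna = read_table(rundir / "de_DEL_vs_CTRL.tsv")
    out = []
    dep_path = rundir / "dep_DEL_vs_CTRL.tsv"
    if dep_path.exists():
        prot = read_table(dep_path)
        pairs = phenotype.pair_omics(rna, prot, ann)
        rows = []
        for subset in ("all", "de_union", "exclude_locus"):
            try:
                r, p, n = phenotype.correlate_rna_protein(pairs, subset,
                                                          fdr=config.fdr)
                rows.append({"subset": subset, "pearson_r": r, "p": p, "n": n})
            except ValueError:
                continue
        out.append(write_table(pd.DataFrame(rows),
                               rundir / "rna_protein_correlation.tsv"))
    diam = read_table(rundir / "diameters.csv")
    out.append(write_table(phenotype.classify_organoid_sizes(diam),
                           rundir / "size_bins.tsv"))
    ct = read_table(rundir / "ct_values.csv")
    out.append(write_table(phenotype.delta_delta_ct(ct, "TARGET1",
                                                    housekeeping_genes=("HPRT1", "ACTB")),
                           rundir / "ddct.tsv"))
    return out


_STAGE_FN = {
    "synth": _stage_synth, "cnv": _stage_cnv, "qc": _stage_qc,
    "de": _stage_de, "dep": _stage_dep, "net": _stage_net,
    "enrich": _stage_enrich, "integrate": _stage_integrate,
}
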