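"""Synthetic multi-omic data with known ground truth.

Emulates a reciprocal-CNV organoid study design: three genotypes
(CTRL / DEL / DUP), three individuals per genotype, two iPSC clones per
individual, two replicates per clone, three timepoints (iPSC, 1-month and
3-month organoids).  RNA-seq counts are negative-binomial with a cis dosage
effect on a small "locus" gene set (0.5x / 1.5x of the diploid mean) and
trans effects organised in planted co-expression modules; TMT proteomics is
simulated at peptide level with peptide random intercepts, run offsets and
pooled reference channels.

Every generator is deterministic given its seed, so downstream statistics
can be tested against the planted truth without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

GENOTYPES = ("CTRL", "DEL", "DUP")
TIMEPOINTS = ("iPSC", "org1M", "org3M")

#: copy number per genotype at the focal locus (diploid = 2)
COPY_NUMBER = {"CTRL": 2, "DEL": 1, "DUP": 3}


@dataclass
class DesignConfig:
    """Factorial layout of the study: genotype x individual x clone x
    replicate x timepoint for RNA; proteomics skips the iPSC stage."""

    n_individuals: int = 3
    n_clones: int = 2
    n_replicates: int = 2
    timepoints: tuple[str, ...] = TIMEPOINTS
    protein_timepoints: tuple[str, ...] = ("org1M", "org3M")

    def validate(self) -> None:
        if min(self.n_individuals, self.n_clones, self.n_replicates) < 1:
            raise ValueError("design counts must all be >= 1")
        if not self.timepoints:
            raise ValueError("at least one timepoint required")
        if "iPSC" in self.protein_timepoints:
            raise ValueError("proteomics is not assayed at the iPSC stage")


@dataclass
class SimTruth:
    """Ground-truth parameters shared by the RNA and protein simulators.

    ``cis_fc_del`` / ``cis_fc_dup`` are copy-ratio fold changes applied to
    locus genes (defaults 0.5 and 1.5 = one and three copies of a diploid
    locus).  ``trans_effects`` maps a planted module label to per-genotype
    log2 shifts of its latent eigengene.  ``icc_individual`` and
    ``clone_var_frac`` are the fractions of biological log-expression
    variance attributable to individual and clone-within-individual;
    ``residual_sd`` is the residual biological log2 SD.
    """

    cis_fc_del: float = 0.5
    cis_fc_dup: float = 1.5
    trans_effects: dict = field(default_factory=lambda: {
        "M1": {"DEL": -0.5, "DUP": 0.5},
        "M2": {"DEL": 0.4, "DUP": -0.4},
    })
    icc_individual: float = 0.2
    clone_var_frac: float = 0.1
    nb_dispersion: float = 0.1
    peptide_sd: float = 0.5
    residual_sd: float = 0.3
    ref_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.cis_fc_del <= 0 or self.cis_fc_dup <= 0:
            raise ValueError("cis fold changes must be positive")
        for name in ("icc_individual", "clone_var_frac"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.icc_individual + self.clone_var_frac >= 1:
            raise ValueError("variance fractions must sum to < 1")
        if self.nb_dispersion < 0 or self.peptide_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance parameters must be >= 0")

    def component_sds(self) -> tuple[float, float, float]:
        """(individual, clone, residual) log2 SDs implied by the fractions."""
        resid_frac = 1.0 - self.icc_individual - self.clone_var_frac
        total_var = self.residual_sd ** 2 / resid_frac
        return (
            math.sqrt(self.icc_individual * total_var),
            math.sqrt(self.clone_var_frac * total_var),
            self.residual_sd,
        )

    def cis_fold(self, genotype: str) -> float:
        if genotype == "DEL":
            return self.cis_fc_del
        if genotype == "DUP":
            return self.cis_fc_dup
        return 1.0

    def to_dict(self) -> dict:
        return asdict(self)


def generate_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """Full factorial sample sheet for both assays.

    Returns a tidy frame with one row per (sample, assay); RNA rows cover
    all timepoints, protein rows only the organoid stages.
    """
    config = config or DesignConfig()
    config.validate()
    rows = []
    for assay, tps in (("rna", config.timepoints),
                       ("protein", config.protein_timepoints)):
        for g in GENOTYPES:
            for i in range(1, config.n_individuals + 1):
                ind = f"{g}_{i}"
                for c in range(1, config.n_clones + 1):
                    clone = f"{ind}_c{c}"
                    for r in range(1, config.n_replicates + 1):
                        for tp in tps:
                            rows.append({
                                "sample_id": f"{clone}_r{r}_{tp}_{assay}",
                                "genotype": g,
                                "individual": ind,
                                "clone": clone,
                                "replicate": r,
                                "timepoint": tp,
                                "assay": assay,
                            })
    design = pd.DataFrame(rows)
    if design["sample_id"].duplicated().any():
        raise AssertionError("sample ids must be unique")
    return design


def generate_annotations(n_genes: int = 2000, n_locus: int = 29,
                         n_modules: int = 5, seed: int = 0,
                         module_size: int = 100,
                         cell_types: tuple[str, ...] = ("Neuron", "IP", "RG"),
                         n_markers_per_type: int = 50) -> pd.DataFrame:
    """Gene annotation table: lengths (log-normal), GC (beta), a locus flag
    for the first ``n_locus`` genes, and disjoint blocks of planted module
    and cell-type-marker labels."""
    if n_locus > n_genes:
        raise ValueError("n_locus cannot exceed n_genes")
    if n_modules * module_size > n_genes - n_locus:
        raise ValueError("planted modules do not fit in the gene universe")
    rng = np.random.default_rng(seed)
    length = np.maximum(200, np.round(rng.lognormal(np.log(2500), 0.8, n_genes))).astype(int)
    gc = np.clip(rng.beta(12, 14, n_genes), 1e-6, 1 - 1e-6)
    gene_id = np.array([f"G{i:05d}" for i in range(n_genes)])
    is_locus = np.zeros(n_genes, bool)
    is_locus[:n_locus] = True

    true_module = np.full(n_genes, "", dtype=object)
    pos = n_locus
    for m in range(1, n_modules + 1):
        true_module[pos:pos + module_size] = f"M{m}"
        pos += module_size
    true_celltype = np.full(n_genes, "", dtype=object)
    for ct in cell_types:
        if pos + n_markers_per_type > n_genes:
            raise ValueError("cell-type marker blocks do not fit")
        true_celltype[pos:pos + n_markers_per_type] = ct
        pos += n_markers_per_type

    return pd.DataFrame({
        "gene_id": gene_id, "length_bp": length, "gc_fraction": gc,
        "is_locus": is_locus, "true_module": true_module,
        "true_celltype": true_celltype,
    })


def _genotype_log2_effects(annotations: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    """Per-gene expected log2 shift for each genotype (cis + trans)."""
    eff = pd.DataFrame(0.0, index=annotations["gene_id"], columns=list(GENOTYPES))
    locus = annotations["is_locus"].to_numpy()
    eff.loc[locus, "DEL"] += math.log2(truth.cis_fc_del)
    eff.loc[locus, "DUP"] += math.log2(truth.cis_fc_dup)
    for module, shifts in truth.trans_effects.items():
        members = (annotations["true_module"] == module).to_numpy()
        for g, delta in shifts.items():
            eff.loc[members, g] += float(delta)
    return eff


def simulate_rnaseq(design: pd.DataFrame, annotations: pd.DataFrame,
                    truth: SimTruth | None = None,
                    mean_log2_baseline: float = 8.0,
                    baseline_sd: float = 1.5,
                    module_factor_sd: float = 1.0,
                    library_size_sd: float = 0.1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts and TPM for the RNA rows of ``design``.

    The log2 mean of gene g in sample s is
    ``baseline_g + cis_g(genotype) + module-shift + w_g * factor_{m,s}
    + individual + clone + residual``, where ``factor_{m,s}`` is a latent
    per-sample module activity driving within-module correlation.  Counts
    are gamma-Poisson draws with dispersion ``truth.nb_dispersion``;
    TPM = 1e6 * (count/length) / sum(count/length) per sample.
    """
    truth = truth or SimTruth()
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    rna = design[design["assay"] == "rna"].reset_index(drop=True)
    if rna.empty:
        raise ValueError("design contains no RNA samples")
    genes = annotations["gene_id"].to_numpy()
    G, S = len(genes), len(rna)

    baseline = rng.normal(mean_log2_baseline, baseline_sd, G)
    eff = _genotype_log2_effects(annotations, truth)
    sd_ind, sd_clone, sd_res = truth.component_sds()

    individuals = rna["individual"].unique()
    clones = rna["clone"].unique()
    b_ind = {i: rng.normal(0, sd_ind, G) for i in individuals}
    b_clone = {c: rng.normal(0, sd_clone, G) for c in clones}

    # latent module activities: per-sample factor shared by module members
    modules = [m for m in annotations["true_module"].unique() if m]
    loadings = rng.uniform(0.5, 1.0, G)
    factor = {m: rng.normal(0, module_factor_sd, S) for m in modules}
    module_of = annotations["true_module"].to_numpy()

    lib = rng.normal(0, library_size_sd, S)
    log2mu = np.empty((G, S))
    geno = rna["genotype"].to_numpy()
    for s in range(S):
        col = (baseline + eff[geno[s]].to_numpy()
               + b_ind[rna.at[s, "individual"]] + b_clone[rna.at[s, "clone"]]
               + rng.normal(0, sd_res, G) + lib[s])
        for m in modules:
            mask = module_of == m
            col[mask] += loadings[mask] * factor[m][s]
        log2mu[:, s] = col

    mu = np.exp2(log2mu)
    phi = truth.nb_dispersion
    if phi < 1e-8:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts = rng.poisson(lam)
    counts = pd.DataFrame(counts, index=genes, columns=rna["sample_id"])

    rate = counts.to_numpy() / annotations["length_bp"].to_numpy()[:, None]
    tpm = pd.DataFrame(1e6 * rate / rate.sum(axis=0, keepdims=True),
                       index=genes, columns=rna["sample_id"])
    return counts, tpm


def generate_protein_map(annotations: pd.DataFrame, n_proteins: int = 800,
                         min_peptides: int = 2, max_peptides: int = 8,
                         seed: int = 0) -> pd.DataFrame:
    """Peptide -> protein map; protein ``P_<gene>`` inherits that gene's
    genotype effects, so RNA/protein fold changes are comparable."""
    if n_proteins > len(annotations):
        raise ValueError("more proteins requested than genes available")
    rng = np.random.default_rng(seed)
    # evenly spaced through the universe: covers locus, modules and noise
    idx = np.linspace(0, len(annotations) - 1, n_proteins).astype(int)
    genes = annotations["gene_id"].to_numpy()[idx]
    rows = []
    for g in genes:
        for p in range(rng.integers(min_peptides, max_peptides + 1)):
            rows.append({"peptide_id": f"pep_{g}_{p}", "protein_id": f"P_{g}",
                         "gene_id": g})
    return pd.DataFrame(rows)


def simulate_proteomics(design: pd.DataFrame, annotations: pd.DataFrame,
                        protein_map: pd.DataFrame, truth: SimTruth | None = None,
                        n_runs: int | None = None,
                        samples_per_run: int = 8,
                        run_offset_sd: float = 0.5,
                        baseline_sd: float = 1.0,
                        timepoint: str | None = "org1M") -> pd.DataFrame:
    """Long-format TMT peptide table across multiplexed runs.

    log2 intensity = protein baseline + genotype effect + individual effect
    + peptide random intercept (SD ``truth.peptide_sd``) + run offset +
    residual (SD ``truth.residual_sd``).  Each run carries two pooled
    reference channels (131N / 131C) holding the grand-mean signal plus the
    run offset, which is what multi-run normalization divides out.
    """
    truth = truth or SimTruth()
    truth.validate()
    if protein_map.empty:
        raise ValueError("protein map is empty: no peptides to simulate")
    if protein_map.groupby("protein_id")["peptide_id"].count().min() < 1:
        raise ValueError("every protein needs at least one peptide")
    rng = np.random.default_rng(truth.seed + 1)
    prot = design[design["assay"] == "protein"]
    if timepoint is not None:
        prot = prot[prot["timepoint"] == timepoint]
    prot = prot.reset_index(drop=True)
    if prot.empty:
        raise ValueError("design contains no protein samples")

    n_samples = len(prot)
    if n_runs is None:
        n_runs = math.ceil(n_samples / samples_per_run)
    if n_samples > n_runs * samples_per_run:
        raise ValueError("too few runs for the number of samples")

    gene_of = protein_map.set_index("peptide_id")["gene_id"]
    prot_of = protein_map.set_index("peptide_id")["protein_id"]
    peptides = protein_map["peptide_id"].to_numpy()
    eff = _genotype_log2_effects(annotations, truth)

    prot_ids = protein_map["protein_id"].unique()
    base_prot = dict(zip(prot_ids, rng.normal(12.0, baseline_sd, len(prot_ids))))
    pep_int = dict(zip(peptides, rng.normal(0, truth.peptide_sd, len(peptides))))
    sd_ind, _, _ = truth.component_sds()
    b_ind = {i: rng.normal(0, sd_ind) for i in prot["individual"].unique()}
    run_offsets = rng.normal(0, run_offset_sd, n_runs)

    gene_idx = eff.index.get_indexer(gene_of.loc[peptides])
    base = np.array([base_prot[prot_of[p]] for p in peptides])
    pint = np.array([pep_int[p] for p in peptides])

    rows = []
    # round-robin assignment keeps genotypes balanced across runs
    run_of_sample = [s % n_runs for s in range(n_samples)]
    # pooled mean of expected sample signals (baseline + mean genotype effect)
    pooled = base + np.mean(
        [eff[prot.at[s, "genotype"]].to_numpy()[gene_idx] for s in range(n_samples)],
        axis=0)

    for s in range(n_samples):
        run = run_of_sample[s]
        g = prot.at[s, "genotype"]
        log2 = (base + eff[g].to_numpy()[gene_idx] + pint
                + b_ind[prot.at[s, "individual"]] + run_offsets[run]
                + rng.normal(0, truth.residual_sd, len(peptides)))
        rows.append(pd.DataFrame({
            "run_id": f"run{run + 1}", "channel": f"ch{s // n_runs + 1}",
            "sample_id": prot.at[s, "sample_id"], "peptide_id": peptides,
            "protein_id": prot_of.loc[peptides].to_numpy(),
            "intensity": np.exp2(log2),
        }))
    for run in range(n_runs):
        for ch in ("131N", "131C"):
            log2 = pooled + run_offsets[run]
            if truth.ref_noise_sd > 0:
                log2 = log2 + rng.normal(0, truth.ref_noise_sd, len(peptides))
            rows.append(pd.DataFrame({
                "run_id": f"run{run + 1}", "channel": ch, "sample_id": "REF",
                "peptide_id": peptides,
                "protein_id": prot_of.loc[peptides].to_numpy(),
                "intensity": np.exp2(log2),
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_celltype_reference(cell_types: list[str] | tuple[str, ...],
                                annotations: pd.DataFrame, seed: int = 0,
                                marker_amplitude: float = 5.0,
                                baseline: float = 1.0,
                                noise_sd: float = 0.1) -> pd.DataFrame:
    """Mean-expression matrix (genes x cell types) in which planted marker
    genes are elevated by ``marker_amplitude`` in their own type."""
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    G = len(annotations)
    expr = np.maximum(
        0.0, baseline + rng.normal(0, noise_sd, (G, len(cell_types))))
    ct_of = annotations["true_celltype"].to_numpy()
    for j, ct in enumerate(cell_types):
        expr[ct_of == ct, j] += marker_amplitude
    return pd.DataFrame(expr, index=annotations["gene_id"], columns=list(cell_types))


def simulate_cnv_calls(n_clones: int = 4, seed: int = 0,
                       focal_locus: tuple[str, int, int] = ("chr16", 29_500_000, 30_100_000),
                       focal_type: str = "DEL",
                       n_background: int = 3,
                       outlier_clone: bool = True) -> tuple[pd.DataFrame, dict]:
    """PennCNV-style call sets for a fibroblast line plus iPSC clones,
    with the focal-locus call present in every sample and random background
    calls elsewhere; one clone optionally carries an excess burden.

    Returns (calls frame, marker map dict chrom -> sorted positions).
    """
    rng = np.random.default_rng(seed)
    chrom, fstart, fend = focal_locus
    samples = ["fibroblast"] + [f"clone{i+1}" for i in range(n_clones)]
    rows = []
    for si, s in enumerate(samples):
        rows.append({"chrom": chrom, "start": fstart, "end": fend,
                     "cn_type": focal_type, "n_markers": 120,
                     "confidence": 200.0, "sample_id": s})
        n_bg = n_background + (3 if (outlier_clone and si == n_clones) else 0)
        for _ in range(n_bg):
            c = f"chr{rng.integers(1, 12)}"
            start = int(rng.integers(1_000_000, 80_000_000))
            size = int(rng.integers(120_000, 400_000))
            rows.append({"chrom": c, "start": start, "end": start + size,
                         "cn_type": rng.choice(["DEL", "DUP"]),
                         "n_markers": int(rng.integers(10, 40)),
                         "confidence": float(rng.uniform(25, 100)),
                         "sample_id": s})
    calls = pd.DataFrame(rows)
    markers: dict[str, np.ndarray] = {}
    for c in calls["chrom"].unique():
        markers[c] = np.unique(rng.integers(1, 100_000_000, 5000))
    return calls, markers


def simulate_organoid_diameters(n_batches: int = 3, n_per_batch: int = 60,
                                mean_um: float = 1500.0, sd_um: float = 200.0,
                                seed: int = 0) -> pd.DataFrame:
    """Normally distributed organoid diameters per batch (micrometres)."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(1, n_batches + 1):
        d = rng.normal(mean_um, sd_um, n_per_batch)
        rows.append(pd.DataFrame({
            "batch": f"batch{b}",
            "organoid_id": [f"batch{b}_org{i+1}" for i in range(n_per_batch)],
            "diameter_um": d,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_ct_values(target_genes: list[str] | None = None,
                       housekeeping: tuple[str, ...] = ("HPRT1", "ACTB"),
                       groups: tuple[str, ...] = GENOTYPES,
                       n_per_group: int = 3,
                       log2_fc: dict | None = None,
                       noise_sd: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """qPCR Ct table with planted log2 fold changes relative to the first
    group (one PCR cycle = one log2 unit, lower Ct = more transcript)."""
    rng = np.random.default_rng(seed)
    target_genes = target_genes or ["TARGET1"]
    log2_fc = log2_fc or {}
    rows = []
    for grp in groups:
        for i in range(n_per_group):
            sample = f"{grp}_{i+1}"
            for hk in housekeeping:
                rows.append({"sample": sample, "gene": hk, "group": grp,
                             "ct": 20.0 + rng.normal(0, noise_sd)})
            for t in target_genes:
                shift = -float(log2_fc.get(t, {}).get(grp, 0.0))
                rows.append({"sample": sample, "gene": t, "group": grp,
                             "ct": 25.0 + shift + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)
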