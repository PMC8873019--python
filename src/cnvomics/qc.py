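"""Expression-level quality control and covariate discovery.

Covers the pre-modelling stages of a nested bulk RNA-seq (or proteomics)
design: expressed-gene filtering per genotype group, sample-network
connectivity outliers, removal of genes dominated by clone-to-clone
variability, principal components of sequencing QC metrics, surrogate
variables for hidden confounders, and a spline-based forward selection of
which candidate covariates the differential-expression model should carry.

The surrogate-variable and covariate-selection steps are deliberately
reduced re-implementations: residual PCA with permutation parallel
analysis in place of full iteratively-reweighted SVA, and a greedy
hinge-basis forward pass with a GCV stop in place of full multivariate
adaptive regression splines.  Both keep the decisions those methods make
(how many hidden factors, which covariates) without their machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# expressed-gene filter

def filter_expressed_genes(tpm: pd.DataFrame, design: pd.DataFrame,
                           tpm_min: float = 0.5, frac: float = 0.8,
                           require_all_genotypes: bool = False) -> list[str]:
    """Genes with TPM strictly above ``tpm_min`` in at least ``frac`` of the
    samples of a genotype group.

    By default passing in any one genotype suffices (preserves
    genotype-specific expression); ``require_all_genotypes=True`` demands
    the criterion in every group.
    """
    groups = design.groupby("genotype")["sample_id"].agg(set)
    if groups.empty:
        raise ValueError("design defines no genotype groups")
    passing = []
    for g, idx in groups.items():
        cols = [c for c in tpm.columns if c in idx]
        if not cols:
            raise ValueError(f"genotype group {g!r} has no samples in the matrix")
        sub = tpm[cols]
        n_needed = frac * len(cols)
        passing.append((sub > tpm_min).sum(axis=1) >= n_needed)
    mask = pd.concat(passing, axis=1)
    keep = mask.all(axis=1) if require_all_genotypes else mask.any(axis=1)
    return tpm.index[keep].tolist()


# ---------------------------------------------------------------------------
# sample-network connectivity outliers

def detect_outlier_samples(log_expr: pd.DataFrame, z_cut: float = -2.0,
                           cor_type: str = "pearson") -> pd.DataFrame:
    """Flag samples whose network connectivity is abnormally low.

    Connectivity k_i is the sum of inter-sample correlations of sample i;
    samples with standardized z(k) strictly below ``z_cut`` are flagged.
    A zero-variance sample has undefined correlations and is auto-flagged.
    Single pass (no re-standardization after removal).
    """
    if log_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for network connectivity")
    X = log_expr.to_numpy(float)
    sds = X.std(axis=0)
    degenerate = sds == 0
    if degenerate.any():
        warnings.warn("zero-variance sample(s) auto-flagged as outliers")
    if cor_type == "bicor":
        from .network import bicor_matrix
        C = bicor_matrix(log_expr).to_numpy()
    elif cor_type == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X, rowvar=False)
    else:
        raise ValueError(f"unknown cor_type {cor_type!r}")
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 0.0)
    k = C.sum(axis=1)
    z = (k - k.mean()) / k.std(ddof=0) if k.std(ddof=0) > 0 else np.zeros_like(k)
    flagged = (z < z_cut) | degenerate
    return pd.DataFrame({"sample_id": log_expr.columns, "connectivity": k,
                         "z_k": z, "flagged": flagged})


# ---------------------------------------------------------------------------
# clone-variance gene filter

def clone_variance_components(log_expr: pd.DataFrame,
                              design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene nested variance decomposition: individual, clone within
    individual, residual (method-of-moments nested ANOVA, vectorized over
    genes; negative moment estimates are clipped to zero).

    Clones without replication, and individuals left with fewer than two
    replicated clones (e.g. after outlier-sample removal), cannot inform
    the decomposition and are dropped with a warning; an entirely
    unreplicated design is an error.
    """
    design = design.set_index("sample_id").loc[log_expr.columns]
    usable_clones = design.groupby("clone").size()
    usable_clones = set(usable_clones.index[usable_clones >= 2])
    sub = design[design["clone"].isin(usable_clones)]
    clones_per_ind = sub.groupby("individual")["clone"].nunique()
    usable_inds = set(clones_per_ind.index[clones_per_ind >= 2])
    sub = sub[sub["individual"].isin(usable_inds)]
    if sub.empty or sub["individual"].nunique() < 2:
        raise ValueError(
            "design has no replicated clones nested in >= 2 individuals")
    if len(sub) < len(design):
        warnings.warn(f"dropping {len(design) - len(sub)} samples from "
                      "unreplicated clones/individuals in the variance "
                      "decomposition")
        log_expr = log_expr[sub.index]
        design = sub
    clones = design["clone"]
    individuals = design["individual"]
    n_clone_levels = clones.nunique()
    n_ind = individuals.nunique()

    Y = log_expr.to_numpy(float)  # G x S
    S = Y.shape[1]
    clone_mean = pd.DataFrame(Y.T, index=log_expr.columns).groupby(clones).transform("mean").T.to_numpy()
    ind_mean = pd.DataFrame(Y.T, index=log_expr.columns).groupby(individuals).transform("mean").T.to_numpy()
    grand = Y.mean(axis=1, keepdims=True)

    ss_within = ((Y - clone_mean) ** 2).sum(axis=1)
    ss_clone = ((clone_mean - ind_mean) ** 2).sum(axis=1)
    ss_ind = ((ind_mean - grand) ** 2).sum(axis=1)

    df_within = S - n_clone_levels
    df_clone = n_clone_levels - n_ind
    df_ind = n_ind - 1
    ms_within = ss_within / df_within
    ms_clone = ss_clone / df_clone
    ms_ind = ss_ind / df_ind

    # balanced-design expected mean squares coefficients
    n_rep = S / n_clone_levels
    n_per_ind = S / n_ind
    var_e = ms_within
    var_c = np.maximum(0.0, (ms_clone - ms_within) / n_rep)
    var_i = np.maximum(0.0, (ms_ind - ms_clone) / n_per_ind)
    total = var_e + var_c + var_i
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, var_c / total, 0.0)
    return pd.DataFrame({"var_individual": var_i, "var_clone": var_c,
                         "var_residual": var_e, "clone_frac": frac},
                        index=log_expr.index)


def clone_variance_filter(log_expr: pd.DataFrame, design: pd.DataFrame,
                          max_clone_frac: float = 0.5) -> list[str]:
    """Drop genes whose clone-within-individual variance fraction exceeds
    ``max_clone_frac`` (technical clone-to-clone instability); a constant
    gene has fraction 0 and is retained."""
    comp = clone_variance_components(log_expr, design)
    return log_expr.index[comp["clone_frac"] <= max_clone_frac].tolist()


# ---------------------------------------------------------------------------
# QC-metric principal components

@dataclass
class SeqPcs:
    scores: pd.DataFrame            # samples x PCs
    loadings: pd.DataFrame          # metrics x PCs
    explained_variance_ratio: np.ndarray


def compute_seq_pcs(qc_metrics: pd.DataFrame, n_pcs: int | None = None,
                    min_variance_explained: float = 0.6) -> SeqPcs:
    """Principal components of standardized sequencing-QC metrics
    (samples x metrics).  When ``n_pcs`` is None, the smallest number of
    components explaining at least ``min_variance_explained`` of the total
    variance is returned.  Constant metrics are dropped."""
    if qc_metrics.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    X = qc_metrics.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    evr = s ** 2 / (s ** 2).sum()
    if n_pcs is None:
        n_pcs = int(np.searchsorted(np.cumsum(evr), min_variance_explained) + 1)
    n_pcs = min(n_pcs, len(s))
    cols = [f"seqPC{i+1}" for i in range(n_pcs)]
    scores = pd.DataFrame(U[:, :n_pcs] * s[:n_pcs], index=qc_metrics.index,
                          columns=cols)
    loadings = pd.DataFrame(Vt[:n_pcs].T, index=qc_metrics.columns[keep],
                            columns=cols)
    return SeqPcs(scores, loadings, evr[:n_pcs])


# ---------------------------------------------------------------------------
# surrogate variables

def estimate_surrogate_variables(log_expr: pd.DataFrame,
                                 protected_design: pd.DataFrame | np.ndarray,
                                 n_permutations: int = 20,
                                 quantile: float = 0.95,
                                 max_sv: int | None = None,
                                 seed: int = 0) -> pd.DataFrame:
    """Hidden-confounder axes from residual principal components.

    Expression is residualized on the protected design (the biological
    variables whose signal must survive, e.g. genotype); surrogate
    variables are the leading principal components of the residual matrix
    whose variance exceeds the ``quantile`` of a permutation null
    (each gene's residuals permuted independently, ``n_permutations``
    rounds) — a parallel-analysis cut on the residual spectrum.
    """
    X = np.asarray(protected_design, float)
    if X.ndim == 1:
        X = X[:, None]
    X = np.column_stack([np.ones(X.shape[0]), X])
    Y = log_expr.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    var_obs = s ** 2 / (s ** 2).sum()  # variance proportions

    rng = np.random.default_rng(seed)
    null_top = np.empty((n_permutations, len(s)))
    for b in range(n_permutations):
        Rp = rng.permuted(R, axis=0)  # break sample structure per gene
        beta_p, *_ = np.linalg.lstsq(X, Rp, rcond=None)
        sp = np.linalg.svd(Rp - X @ beta_p, compute_uv=False)
        null_top[b] = sp ** 2 / (sp ** 2).sum()
    thresh = np.quantile(null_top, quantile, axis=0)
    n_sv = 0
    for i in range(len(s)):
        if var_obs[i] > thresh[i]:
            n_sv += 1
        else:
            break
    if max_sv is not None:
        n_sv = min(n_sv, max_sv)
    cols = [f"SV{i+1}" for i in range(n_sv)]
    return pd.DataFrame(U[:, :n_sv], index=log_expr.columns, columns=cols)


# ---------------------------------------------------------------------------
# covariate selection (reduced MARS)

@dataclass
class CovariateSelection:
    selected: list[str]
    basis_terms: list[tuple[str, str]] = field(default_factory=list)
    gcv_path: list[float] = field(default_factory=list)


def _hinge_bases(x: np.ndarray, name: str) -> list[tuple[str, str, np.ndarray]]:
    """Linear term plus hinge pairs at the quartile knots of x."""
    bases = [(name, "linear", x)]
    for q in (0.25, 0.5, 0.75):
        knot = np.quantile(x, q)
        left = np.maximum(knot - x, 0.0)
        right = np.maximum(x - knot, 0.0)
        if left.std() > 0:
            bases.append((name, f"hinge({knot:.4g}-x)", left))
        if right.std() > 0:
            bases.append((name, f"hinge(x-{knot:.4g})", right))
    return bases


def select_covariates(normalized_expr: pd.DataFrame,
                      candidates: pd.DataFrame,
                      penalty: float = 3.0,
                      max_terms: int | None = None) -> CovariateSelection:
    """Greedy hinge-spline forward selection of model covariates.

    For every candidate covariate, the basis pool holds its linear term
    and hinge pairs at quartile knots.  Starting from an intercept-only
    model, the basis most reducing summed residual sum-of-squares across
    all genes is added while generalized cross-validation
    ``GCV = RSS / (n (1 - C/n)^2)`` with effective parameters
    ``C = M + penalty (M - 1)`` keeps improving.  A covariate is selected
    if any of its bases survives.
    """
    if candidates.shape[1] == 0:
        return CovariateSelection(selected=[])
    Y = normalized_expr.to_numpy(float).T  # samples x genes
    Y = Y - Y.mean(axis=0)
    n = Y.shape[0]
    pool = []
    for name in candidates.columns:
        x = candidates[name].to_numpy(float)
        if x.std() == 0:
            continue
        pool.extend(_hinge_bases(x, name))

    Q = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis of the model space
    rss = float((Y ** 2).sum())
    m_terms = 1
    gcv = rss / (n * (1 - _mars_cost(m_terms, penalty) / n) ** 2)
    chosen: list[tuple[str, str]] = []
    path = [gcv]
    used = np.zeros(len(pool), bool)
    if max_terms is None:
        max_terms = min(n - 2, 2 * candidates.shape[1] + 5)

    while m_terms - 1 < max_terms:
        best = None
        for j, (name, label, x) in enumerate(pool):
            if used[j]:
                continue
            u = x - Q @ (Q.T @ x)
            norm = np.linalg.norm(u)
            if norm < 1e-10:
                continue
            u = u / norm
            gain = float(((u @ Y) ** 2).sum())
            if best is None or gain > best[1]:
                best = (j, gain, u)
        if best is None:
            break
        j, gain, u = best
        new_cost = _mars_cost(m_terms + 1, penalty)
        if new_cost >= n:
            break
        new_gcv = (rss - gain) / (n * (1 - new_cost / n) ** 2)
        if new_gcv >= gcv:
            break
        used[j] = True
        Q = np.column_stack([Q, u])
        rss -= gain
        m_terms += 1
        gcv = new_gcv
        path.append(gcv)
        chosen.append((pool[j][0], pool[j][1]))

    selected = sorted({name for name, _ in chosen},
                      key=list(candidates.columns).index)
    return CovariateSelection(selected=selected, basis_terms=chosen,
                              gcv_path=path)


def _mars_cost(m_terms: int, penalty: float) -> float:
    return m_terms + penalty * (m_terms - 1)
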