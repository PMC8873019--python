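"""Signed weighted co-expression networks, modules and preservation.

The pipeline is the weighted co-expression strategy: robust biweight
midcorrelation between genes, a signed adjacency a_ij = ((1+cor)/2)^beta
with beta chosen by the scale-free topology fit index (signed R^2 of the
log-log connectivity distribution, threshold 0.8), topological-overlap
dissimilarity clustered by average linkage, a static tree cut with a
minimum module size, iterative merging of modules with correlated
eigengenes, module eigengenes (first principal component) with kME
(gene-eigengene correlation), mixed-model eigengene-genotype association
(random intercept per individual), and a permutation Z-summary that asks
whether a module's density and connectivity pattern recur in a second
dataset (Z > 2 evidence of preservation, Z > 10 strong).

Module detection here uses a static cut plus size enforcement and
eigengene merging rather than the dynamic hybrid tree cut; the deep-split
parameter of the original heuristic is recorded in `NetworkParams` but
inert.  Planted-structure recovery, not label-for-label parity with any
particular cut heuristic, is the fidelity criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import statsmodels.api as sm

from .de import bh_fdr

GREY = "grey"


@dataclass
class NetworkParams:
    """Network construction parameters.  ``deep_split`` is recorded for
    provenance but has no effect on the static-cut module detection."""

    power: int | None = 6
    network_type: str = "signed"
    cor_type: str = "bicor"
    min_module_size: int = 30
    merge_cut_height: float = 0.1
    deep_split: int = 2
    min_kme_to_stay: float = 0.3

    def __post_init__(self):
        if self.power is not None and self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if self.network_type != "signed":
            raise ValueError("only signed networks are supported")


#: per-dataset presets (RNA: iPSC / 1-month / 3-month organoids; protein
#: layers for the organoid stages)
PRESETS: dict[str, NetworkParams] = {
    "iPSC": NetworkParams(power=14, deep_split=0, min_module_size=100),
    "org1M": NetworkParams(power=16, deep_split=2, min_module_size=50),
    "org3M": NetworkParams(power=19, deep_split=2, min_module_size=70),
    "protein_org1M": NetworkParams(power=13, deep_split=3, min_module_size=40),
    "protein_org3M": NetworkParams(power=17, deep_split=2, min_module_size=10),
}


# ---------------------------------------------------------------------------
# correlation and adjacency

def bicor_matrix(expr: pd.DataFrame, max_p_outlier: float = 1.0) -> pd.DataFrame:
    """Biweight midcorrelation between the rows of ``expr``.

    Each vector is median-centred and weighted by (1-u^2)^2 for
    u = (x - med)/(9 mad), truncated at |u| >= 1; rows with zero MAD fall
    back to Pearson weighting (mean-centred, unit weights) with a warning.
    """
    X = expr.to_numpy(float)
    if X.shape[1] < 4:
        raise ValueError("need >= 4 samples for a stable correlation")
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    degenerate = (mad[:, 0] == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (X - med) / (9 * mad)
    w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
    Xw = (X - med) * w
    if degenerate.any():
        warnings.warn(f"{degenerate.sum()} constant-MAD rows: Pearson fallback")
        Xw[degenerate] = X[degenerate] - X[degenerate].mean(axis=1, keepdims=True)
    norms = np.sqrt((Xw ** 2).sum(axis=1, keepdims=True))
    norms[norms == 0] = 1.0
    Z = Xw / norms
    C = np.clip(Z @ Z.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=expr.index, columns=expr.index)


def correlation_matrix(expr: pd.DataFrame, cor_type: str = "bicor") -> pd.DataFrame:
    if cor_type == "bicor":
        return bicor_matrix(expr)
    if cor_type == "pearson":
        C = np.corrcoef(expr.to_numpy(float))
        return pd.DataFrame(C, index=expr.index, columns=expr.index)
    raise ValueError(f"unknown cor_type {cor_type!r}")


def signed_adjacency(cor: pd.DataFrame | np.ndarray, power: int) -> np.ndarray:
    C = cor.to_numpy() if isinstance(cor, pd.DataFrame) else np.asarray(cor)
    return ((1.0 + C) / 2.0) ** power


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) ~ log10(mean k) over equal-width bins of
    the connectivity distribution (empty bins dropped); the sign is
    negative for an increasing relationship — scale-free topology means
    frequency falls with connectivity."""
    k = np.asarray(k, float)
    k = k[k > 0]
    if len(k) == 0 or np.ptp(k) == 0:
        raise ValueError("degenerate connectivity distribution")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    logs_k, logs_f = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        logs_k.append(np.log10(k[sel].mean()))
        logs_f.append(np.log10(sel.mean()))
    if len(logs_k) < 2:
        raise ValueError("fewer than 2 occupied connectivity bins")
    slope, _, r, _, _ = stats.linregress(logs_k, logs_f)
    return float(-np.sign(slope) * r ** 2)


def pick_soft_threshold(expr: pd.DataFrame,
                        candidate_powers: tuple[int, ...] = tuple(range(1, 21)),
                        r2_min: float = 0.8,
                        cor_type: str = "bicor") -> tuple[int, pd.DataFrame]:
    """Smallest soft-threshold power whose scale-free fit index reaches
    ``r2_min``; if none does, the best-fitting power is returned with a
    warning."""
    if not candidate_powers:
        raise ValueError("no candidate powers")
    C = correlation_matrix(expr, cor_type).to_numpy()
    rows = []
    for beta in candidate_powers:
        A = signed_adjacency(C, beta)
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        rows.append({"power": beta, "fit_index": scale_free_fit(k),
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    ok = table[table["fit_index"] >= r2_min]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        beta = int(table.loc[table["fit_index"].idxmax(), "power"])
        warnings.warn(f"no power reached fit {r2_min}; using best power {beta}")
    return beta, table


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap of a (signed) adjacency; TOM_ii = 1."""
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(T, 1.0)
    return np.clip(T, 0.0, 1.0)


# ---------------------------------------------------------------------------
# eigengenes and kME

def module_eigengene_kme(expr: pd.DataFrame, labels: pd.Series
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module eigengenes (unit-norm first PC of the standardized member
    expression, sign-oriented to positive mean member kME) and the full
    gene x module kME matrix."""
    labels = labels.reindex(expr.index)
    modules = sorted(m for m in labels.unique() if m != GREY)
    X = expr.to_numpy(float)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    mes = {}
    for m in modules:
        members = (labels == m).to_numpy()
        _, _, Vt = np.linalg.svd(Z[members], full_matrices=False)
        me = Vt[0]
        member_cor = _safe_corr(Z[members], me)
        if member_cor.mean() < 0:
            me = -me
        mes[m] = me
    me_df = pd.DataFrame(mes, index=expr.columns)
    kme = pd.DataFrame(
        {m: _safe_corr(Z, me_df[m].to_numpy()) for m in modules},
        index=expr.index)
    return me_df, kme


def _safe_corr(Z_rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Correlation of each (already centred) row with vector v."""
    vc = v - v.mean()
    num = Z_rows @ vc
    den = np.sqrt((Z_rows ** 2).sum(axis=1) * (vc ** 2).sum())
    den[den == 0] = 1.0
    return np.clip(num / den, -1.0, 1.0)


# ---------------------------------------------------------------------------
# module detection

@dataclass
class CoexpressionResults:
    """Module labels, eigengenes, kME and fit diagnostics."""

    labels: pd.Series                 # gene -> module ("grey" = unassigned)
    eigengenes: pd.DataFrame          # samples x modules
    kme: pd.DataFrame                 # genes x modules
    params: NetworkParams
    fit_table: pd.DataFrame | None = None
    merge_log: list = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    def module_genes(self, module: str, sort_by_kme: bool = True) -> list[str]:
        genes = self.labels.index[self.labels == module]
        if sort_by_kme and module in self.kme.columns:
            genes = self.kme.loc[genes, module].sort_values(ascending=False).index
        return list(genes)

    def summary(self) -> str:
        counts = self.labels.value_counts()
        lines = ["Signed co-expression network",
                 "=" * 48,
                 f"power: {self.params.power}  correlation: {self.params.cor_type}"
                 f"  min module size: {self.params.min_module_size}",
                 f"genes: {len(self.labels)}   modules: {len(self.modules)}"
                 f"   unassigned (grey): {int(counts.get(GREY, 0))}",
                 "-" * 48]
        for m in self.modules:
            lines.append(f"{m:<12}{int(counts.get(m, 0)):>6} genes")
        return "\n".join(lines)


class CoexpressionNetwork:
    """Signed weighted co-expression network model for one expression
    layer (genes x samples, covariates already regressed out).

    ``power=None`` triggers scale-free soft-threshold selection at fit
    time.  `fit()` returns `CoexpressionResults`; genotype association
    and cross-layer preservation are computed from those results via
    :func:`eigengene_genotype_association` and :func:`module_preservation`.
    """

    def __init__(self, expr: pd.DataFrame, params: NetworkParams | None = None,
                 preset: str | None = None):
        if preset is not None:
            if params is not None:
                raise ValueError("give either params or preset, not both")
            params = PRESETS[preset]
        self.expr = expr
        self.params = params or NetworkParams()
        if len(expr) < 2 * self.params.min_module_size:
            raise ValueError("too few genes for the minimum module size")

    def fit(self, power: int | None = None) -> CoexpressionResults:
        params = self.params
        cor = correlation_matrix(self.expr, params.cor_type)
        fit_table = None
        beta = power if power is not None else params.power
        if beta is None:
            beta, fit_table = pick_soft_threshold(self.expr,
                                                  cor_type=params.cor_type)
        A = signed_adjacency(cor, beta)
        T = tom_matrix(A)
        dist = 1.0 - T
        np.fill_diagonal(dist, 0.0)
        link = hierarchy.linkage(squareform(dist, checks=False),
                                 method="average")
        raw = _static_cut(link, params.min_module_size)

        labels = pd.Series(index=self.expr.index, dtype=object)
        sizes = pd.Series(raw).value_counts()
        next_id = 1
        for cl in sizes.index:
            sel = raw == cl
            if sizes[cl] >= max(2, params.min_module_size):
                labels.iloc[np.where(sel)[0]] = f"M{next_id}"
                next_id += 1
            else:
                labels.iloc[np.where(sel)[0]] = GREY
        labels = labels.fillna(GREY)

        labels = _prune_by_kme(self.expr, labels, params.min_kme_to_stay,
                               params.min_module_size)
        labels, merge_log = _merge_close_modules(self.expr, labels,
                                                 params.merge_cut_height)
        labels = _relabel_by_size(labels)
        if (labels == GREY).all():
            warnings.warn("no module passed the size threshold; all genes grey")
            me = pd.DataFrame(index=self.expr.columns)
            kme = pd.DataFrame(index=self.expr.index)
        else:
            me, kme = module_eigengene_kme(self.expr, labels)
        used = NetworkParams(**{**params.__dict__, "power": beta})
        return CoexpressionResults(labels=labels, eigengenes=me, kme=kme,
                                   params=used, fit_table=fit_table,
                                   merge_log=merge_log)


def _static_cut(link: np.ndarray, min_module_size: int,
                quantile_grid: np.ndarray | None = None) -> np.ndarray:
    """Static tree cut: scan candidate heights (quantiles of the merge
    heights) and keep the one producing the most clusters of at least
    the minimum module size; ties break toward the lower height (tighter
    clusters).  Deterministic for a given tree."""
    heights = link[:, 2]
    if quantile_grid is None:
        quantile_grid = np.linspace(0.05, 0.99, 48)
    best = None
    for q in quantile_grid:
        cut = float(np.quantile(heights, q))
        raw = hierarchy.fcluster(link, t=cut, criterion="distance")
        sizes = np.bincount(raw)
        n_big = int((sizes >= min_module_size).sum())
        n_assigned = int(sizes[sizes >= min_module_size].sum())
        key = (n_big, n_assigned)
        if best is None or key > best[0]:
            best = (key, raw)
    return best[1]


def _prune_by_kme(expr, labels, min_kme, min_module_size):
    """Remove weakly connected members (kME below the stay threshold) from
    each module; modules falling under the size floor dissolve to grey."""
    modules = [m for m in labels.unique() if m != GREY]
    if not modules:
        return labels
    _, kme = module_eigengene_kme(expr, labels)
    labels = labels.copy()
    for m in modules:
        members = labels.index[labels == m]
        weak = members[kme.loc[members, m] < min_kme]
        labels.loc[weak] = GREY
        if (labels == m).sum() < min_module_size:
            labels.loc[labels == m] = GREY
    return labels


def _merge_close_modules(expr, labels, cut_height):
    """Iteratively merge the closest pair of modules whose eigengene
    dissimilarity (1 - cor) is below the merge cut."""
    merge_log = []
    while True:
        modules = sorted(m for m in labels.unique() if m != GREY)
        if len(modules) < 2:
            break
        me, _ = module_eigengene_kme(expr, labels)
        C = np.corrcoef(me.to_numpy().T)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        diss = 1.0 - C[i, j]
        if diss >= cut_height:
            break
        a, b = me.columns[i], me.columns[j]
        labels = labels.replace(b, a)
        merge_log.append((b, a, float(diss)))
    return labels, merge_log


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    mapping = {old: f"M{i+1}" for i, old in enumerate(sizes.index)}
    mapping[GREY] = GREY
    return labels.map(mapping)


# ---------------------------------------------------------------------------
# genotype association

def eigengene_genotype_association(eigengenes: pd.DataFrame,
                                   design: pd.DataFrame,
                                   contrasts: tuple[str, ...] = (
                                       "DEL_vs_CTRL", "DUP_vs_CTRL",
                                       "DUP_vs_DEL"),
                                   fdr: float = 0.10) -> pd.DataFrame:
    """Mixed-model association of module eigengenes with genotype.

    Per module: ME ~ genotype (fixed) + (1 | individual), REML estimates;
    contrast p from a Wald t-statistic on between-individual degrees of
    freedom (n_individuals - n_genotypes), the exact reference for this
    balanced nested design where genotype is constant within individual
    (a chi-square likelihood-ratio reference is anticonservative with a
    handful of individuals); BH q across modules within a contrast.  If
    every individual contributes one sample the model reduces to OLS
    (flagged).
    """
    from .protein import _fixed_design, _contrast_estimate, _ols_contrast_p

    design = design.set_index("sample_id").loc[eigengenes.index]
    geno = design["genotype"].to_numpy()
    groups = design["individual"].to_numpy()
    n_ind = pd.Series(groups).nunique()
    if n_ind < 2:
        raise ValueError("need >= 2 individuals")
    singleton = pd.Series(groups).value_counts().max() == 1
    if singleton:
        warnings.warn("all individuals are singletons; using OLS")
    df_between = max(n_ind - 3, 1)

    _CVEC = {"DEL_vs_CTRL": np.array([0.0, 1.0, 0.0]),
             "DUP_vs_CTRL": np.array([0.0, 0.0, 1.0]),
             "DUP_vs_DEL": np.array([0.0, -1.0, 1.0])}
    X_full = _fixed_design(geno, "full")
    rows = []
    for m in eigengenes.columns:
        y = eigengenes[m].to_numpy(float)
        if np.std(y) == 0:
            for c in contrasts:
                rows.append({"module": m, "contrast": c, "effect": 0.0,
                             "p": 1.0, "mixed": False})
            continue
        use_ols = singleton
        beta = cov_fe = None
        if not use_ols:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    r = sm.MixedLM(y, X_full, groups=groups).fit(reml=True)
                    beta = np.asarray(r.fe_params)
                    cov_fe = np.asarray(r.cov_params())[:3, :3]
                except Exception:
                    use_ols = True
        if use_ols:
            beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        for c in contrasts:
            est = _contrast_estimate(beta, c)
            if use_ols:
                p = _ols_contrast_p(y, geno, c)
            else:
                cv = _CVEC[c]
                se = float(np.sqrt(cv @ cov_fe @ cv))
                tstat = est / se if se > 0 else 0.0
                p = float(2 * stats.t.sf(abs(tstat), df_between))
            rows.append({"module": m, "contrast": c, "effect": est, "p": p,
                         "mixed": not use_ols})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for c in contrasts:
        sel = out["contrast"] == c
        out.loc[sel, "q"] = bh_fdr(out.loc[sel, "p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


# ---------------------------------------------------------------------------
# module preservation

def module_preservation(ref_expr: pd.DataFrame, ref_labels: pd.Series,
                        test_expr: pd.DataFrame, power: int = 6,
                        n_perm: int = 100, seed: int = 0,
                        cor_type: str = "bicor",
                        min_shared: int = 3) -> pd.DataFrame:
    """Permutation Z-summary of module preservation in a second dataset.

    For each reference module restricted to the genes shared by both
    layers, the observed statistics in the test data are (1) density, the
    mean off-diagonal signed adjacency among members, and (2)
    connectivity preservation, the correlation between intramodular
    connectivities in reference and test.  The null re-draws same-size
    gene sets from the shared universe; Z-summary is the median of the
    two Z statistics.  Modules with fewer than ``min_shared`` shared
    genes are skipped.
    """
    shared = ref_expr.index.intersection(test_expr.index)
    if len(shared) < 10:
        raise ValueError("too few shared genes between layers")
    A_ref = signed_adjacency(
        correlation_matrix(ref_expr.loc[shared], cor_type), power)
    A_test = signed_adjacency(
        correlation_matrix(test_expr.loc[shared], cor_type), power)
    np.fill_diagonal(A_ref, 0.0)
    np.fill_diagonal(A_test, 0.0)
    pos = {g: i for i, g in enumerate(shared)}
    rng = np.random.default_rng(seed)

    rows = []
    for m in sorted(x for x in ref_labels.unique() if x != GREY):
        genes = [g for g in ref_labels.index[ref_labels == m] if g in pos]
        if len(genes) < min_shared:
            warnings.warn(f"module {m}: <{min_shared} shared genes, skipped")
            continue
        idx = np.array([pos[g] for g in genes])
        obs_d, obs_c = _preservation_stats(A_ref, A_test, idx)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for b in range(n_perm):
            ridx = rng.choice(len(shared), size=len(idx), replace=False)
            null_d[b], null_c[b] = _preservation_stats(A_ref, A_test, ridx)
        z_d = _z(obs_d, null_d)
        z_c = _z(obs_c, null_c)
        rows.append({"module": m, "n_shared": len(idx),
                     "density": obs_d, "connectivity_cor": obs_c,
                     "z_density": z_d, "z_connectivity": z_c,
                     "z_summary": float(np.median([z_d, z_c]))})
    return pd.DataFrame(rows)


def _preservation_stats(A_ref, A_test, idx) -> tuple[float, float]:
    sub_t = A_test[np.ix_(idx, idx)]
    m = len(idx)
    density = float(sub_t.sum() / (m * (m - 1)))
    k_ref = A_ref[np.ix_(idx, idx)].sum(axis=1)
    k_test = sub_t.sum(axis=1)
    if np.std(k_ref) == 0 or np.std(k_test) == 0:
        conn = 0.0
    else:
        conn = float(np.corrcoef(k_ref, k_test)[0, 1])
    return density, conn


def _z(obs: float, null: np.ndarray) -> float:
    sd = null.std(ddof=1)
    return float((obs - null.mean()) / sd) if sd > 0 else 0.0


def regress_covariates(expr: pd.DataFrame,
                       covariates: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Residualize expression on covariates (everything except genotype is
    removed before network construction), keeping gene means."""
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(C.shape[0]), C])
    Y = expr.to_numpy(float).T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    resid += Y.mean(axis=0, keepdims=True)
    return pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)
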