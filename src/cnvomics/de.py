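"""Precision-weighted moderated differential expression for nested designs.

The model is the limma-voom strategy: counts are converted to log2-CPM
with per-observation precision weights from a fitted mean-variance trend;
repeated samples from the same individual (clones, replicates) are handled
by a consensus intra-block correlation shared across genes
(the duplicate-correlation device), giving a block-exchangeable GLS fit
per gene; residual variances are shrunk toward a common prior by empirical
Bayes, yielding moderated t-statistics on augmented degrees of freedom;
discoveries are controlled by Benjamini-Hochberg FDR (default 10%).

`ModeratedDE` is the model object; `ModeratedDE(...).fit()` returns a
`ModeratedDEResults` carrying per-contrast tables, the consensus
correlation and the moderation hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

DEFAULT_CONTRASTS = ("DEL_vs_CTRL", "DUP_vs_CTRL", "DUP_vs_DEL")


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate as NaN
    and are excluded from the ranking."""
    p = np.asarray(p, float)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# voom precision weights

@dataclass
class PrecisionWeights:
    weights: pd.DataFrame            # genes x samples
    log2_cpm: pd.DataFrame
    trend_x: np.ndarray              # mean log2-count grid of the lowess fit
    trend_y: np.ndarray              # sqrt residual SD on that grid


def voom_weights(counts: pd.DataFrame,
                 design_matrix: np.ndarray,
                 span: float = 0.5) -> PrecisionWeights:
    """Mean-variance precision weights for count data.

    log2-CPM uses a 0.5-count offset; per-gene OLS residual SDs are
    lowess-smoothed (quarter-root variance scale) against mean log2-count,
    and each observation's weight is the trend evaluated at its fitted
    log2-count, raised to the power -4.
    """
    lib = counts.sum(axis=0).to_numpy(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    X = np.asarray(design_matrix, float)
    n, p = X.shape
    if n - p < 2:
        raise ValueError("fewer than 2 residual degrees of freedom")
    Y = np.log2((counts.to_numpy(float) + 0.5) / (lib + 1.0) * 1e6)
    log2_cpm = pd.DataFrame(Y, index=counts.index, columns=counts.columns)

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    resid_sd = np.sqrt(((Y - fitted) ** 2).sum(axis=1) / (n - p))

    # mean log2-count per gene (undo the CPM scaling at the average library)
    sx = Y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(resid_sd)

    if len(counts) < 10 or np.ptp(sx) == 0:
        # too few genes for a trend: flat unit weights
        W = np.ones_like(Y)
        return PrecisionWeights(
            pd.DataFrame(W, index=counts.index, columns=counts.columns),
            log2_cpm, np.array([sx.mean()]), np.array([1.0]))

    fit = lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = fit[:, 0], np.maximum(fit[:, 1], 1e-6)
    # per-observation fitted log2-count
    obs_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    trend = np.interp(obs_logcount, tx, ty)
    W = trend ** -4
    return PrecisionWeights(
        pd.DataFrame(W, index=counts.index, columns=counts.columns),
        log2_cpm, tx, ty)


# ---------------------------------------------------------------------------
# consensus (duplicate) correlation

def _block_corr(blocks: np.ndarray, rho: float) -> np.ndarray:
    n = len(blocks)
    R = np.eye(n)
    for b in np.unique(blocks):
        idx = np.where(blocks == b)[0]
        for i in idx:
            for j in idx:
                if i != j:
                    R[i, j] = rho
    return R


def consensus_correlation(log_expr: pd.DataFrame,
                          design_matrix: np.ndarray,
                          block: np.ndarray | pd.Series,
                          weights: pd.DataFrame | None = None,
                          grid: np.ndarray | None = None,
                          trim: float = 0.1,
                          clip: tuple[float, float] = (-0.3, 0.99)) -> float:
    """Consensus intra-block correlation across genes.

    Per gene the restricted likelihood of a block-exchangeable correlation
    is profiled on a common rho grid (vectorized over genes: the whitening
    of the design is shared), the per-gene REML maximizer is located, and
    the consensus is the trimmed mean on the atanh scale, clipped to
    ``clip``.  Precision weights, varying per gene, are not used in this
    stage; the consensus over thousands of genes is insensitive to them.
    """
    block = np.asarray(block)
    sizes = pd.Series(block).value_counts()
    if (sizes < 2).all():
        warnings.warn("all blocks are singletons; consensus correlation = 0")
        return 0.0
    X = np.asarray(design_matrix, float)
    Y = log_expr.to_numpy(float).T  # samples x genes
    n, p = X.shape
    if grid is None:
        grid = np.linspace(clip[0] + 0.01, clip[1] - 0.01, 45)

    logliks = np.empty((len(grid), Y.shape[1]))
    for k, rho in enumerate(grid):
        R = _block_corr(block, rho)
        try:
            L = linalg.cholesky(R, lower=True)
        except linalg.LinAlgError:
            logliks[k] = -np.inf
            continue
        Xw = linalg.solve_triangular(L, X, lower=True)
        Yw = linalg.solve_triangular(L, Y, lower=True)
        beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        q = ((Yw - Xw @ beta) ** 2).sum(axis=0)
        logdet_v = 2 * np.log(np.diag(L)).sum()
        sign, logdet_xvx = np.linalg.slogdet(Xw.T @ Xw)
        logliks[k] = (-0.5 * (logdet_v + logdet_xvx)
                      - 0.5 * (n - p) * np.log(np.maximum(q, 1e-300)))
    best = grid[np.argmax(logliks, axis=0)]
    z = np.arctanh(np.clip(best, -0.999, 0.999))
    rho = float(np.tanh(stats.trim_mean(z, trim)))
    return float(np.clip(rho, *clip))


# ---------------------------------------------------------------------------
# empirical Bayes moderation

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Moment-match a scaled inverse-chi-square prior to the observed
    sample variances (on the log scale, via digamma/trigamma identities)
    and return (d0, s0^2, shrunken variances).  d0 = inf means the
    variances are effectively identical and fully shrunk."""
    s2 = np.maximum(np.asarray(s2, float), 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var > 0:
        d0 = 2 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        # variances are effectively homogeneous: pool them completely
        d0 = np.inf
        s0_2 = float(s2.mean())
        post = np.full_like(s2, s0_2)
    return d0, s0_2, post


# ---------------------------------------------------------------------------
# model / results objects

def make_design_matrix(design: pd.DataFrame,
                       covariates: pd.DataFrame | None = None
                       ) -> tuple[np.ndarray, list[str]]:
    """Intercept + genotype indicator coding (CTRL reference) + numeric
    covariates, aligned to the design row order."""
    geno = design["genotype"].to_numpy()
    cols = [np.ones(len(design)), (geno == "DEL").astype(float),
            (geno == "DUP").astype(float)]
    names = ["Intercept", "DEL", "DUP"]
    if covariates is not None:
        cov = covariates.loc[design["sample_id"]] if (
            covariates.index.name == "sample_id"
            or covariates.index.isin(design["sample_id"]).all()
        ) else covariates
        for c in cov.columns:
            cols.append(cov[c].to_numpy(float))
            names.append(str(c))
    return np.column_stack(cols), names


def contrast_vectors(names: list[str]) -> dict[str, np.ndarray]:
    idx = {n: i for i, n in enumerate(names)}
    p = len(names)

    def vec(plus=None, minus=None):
        v = np.zeros(p)
        if plus:
            v[idx[plus]] = 1.0
        if minus:
            v[idx[minus]] = -1.0
        return v

    return {"DEL_vs_CTRL": vec("DEL"),
            "DUP_vs_CTRL": vec("DUP"),
            "DUP_vs_DEL": vec("DUP", "DEL")}


@dataclass
class ModeratedDEResults:
    """Per-contrast moderated test tables plus the shared nuisance
    estimates (consensus correlation, moderation hyperparameters)."""

    tables: dict[str, pd.DataFrame]
    rho: float
    d0: float
    s0_2: float
    fdr: float = 0.10
    coef_names: list[str] = field(default_factory=list)

    def significant(self, contrast: str, fdr: float | None = None) -> pd.DataFrame:
        t = self.tables[contrast]
        return t[t["q"] < (self.fdr if fdr is None else fdr)]

    def summary(self) -> str:
        lines = ["Moderated differential expression",
                 "=" * 48,
                 f"consensus correlation rho: {self.rho:.4f}",
                 f"prior df d0: {self.d0:.3g}   prior variance s0^2: {self.s0_2:.4g}",
                 f"FDR threshold: {self.fdr:.2f}",
                 "-" * 48,
                 f"{'contrast':<16}{'genes':>8}{'DE':>8}{'up':>6}{'down':>6}"]
        for name, t in self.tables.items():
            sig = t["q"] < self.fdr
            lines.append(f"{name:<16}{len(t):>8}{int(sig.sum()):>8}"
                         f"{int((sig & (t['log2FC'] > 0)).sum()):>6}"
                         f"{int((sig & (t['log2FC'] < 0)).sum()):>6}")
        return "\n".join(lines)


class ModeratedDE:
    """Moderated differential-expression model on a nested count design.

    Parameters
    ----------
    counts : genes x samples raw counts.
    design : sample sheet with sample_id / genotype / individual columns
        (rows in the counts column order or matchable by sample_id).
    covariates : optional numeric sample covariates added as fixed effects.
    block : column of `design` defining the repeated-measures block
        (default "individual").
    """

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame,
                 covariates: pd.DataFrame | None = None,
                 block: str = "individual", fdr: float = 0.10):
        design = design.set_index("sample_id").loc[counts.columns].reset_index()
        self.counts = counts
        self.design = design
        self.block = design[block].to_numpy()
        self.X, self.coef_names = make_design_matrix(design, covariates)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.fdr = fdr

    @classmethod
    def from_dataframe(cls, counts, design, **kw):
        return cls(counts, design, **kw)

    def fit(self, contrasts: dict[str, np.ndarray] | None = None,
            rho: float | None = None) -> ModeratedDEResults:
        vw = voom_weights(self.counts, self.X)
        if rho is None:
            rho = consensus_correlation(vw.log2_cpm, self.X, self.block)
        res = moderated_de(vw.log2_cpm, vw.weights, self.X, self.coef_names,
                           rho, self.block, contrasts=contrasts, fdr=self.fdr)
        self._voom = vw
        return res

    def plot_mean_variance(self, ax=None):
        """Voom mean-variance trend (requires a prior fit)."""
        import matplotlib.pyplot as plt
        vw = getattr(self, "_voom", None) or voom_weights(self.counts, self.X)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(vw.trend_x, vw.trend_y, "r-", lw=2)
        ax.set_xlabel("mean log2 count")
        ax.set_ylabel("sqrt(residual SD)")
        return ax


def moderated_de(log_expr: pd.DataFrame, weights: pd.DataFrame,
                 design_matrix: np.ndarray, coef_names: list[str],
                 rho: float, block: np.ndarray,
                 contrasts: dict[str, np.ndarray] | None = None,
                 fdr: float = 0.10) -> ModeratedDEResults:
    """Per-gene GLS with block-exchangeable correlation ``rho`` and
    precision weights, empirical-Bayes variance moderation, moderated t
    and BH q per contrast."""
    X = np.asarray(design_matrix, float)
    n, p = X.shape
    if contrasts is None:
        contrasts = contrast_vectors(coef_names)
    for name, c in contrasts.items():
        if len(c) != p:
            raise ValueError(f"contrast {name} has wrong length")

    R = _block_corr(np.asarray(block), rho)
    L = linalg.cholesky(R, lower=True)
    Y = log_expr.to_numpy(float)
    W = weights.to_numpy(float)
    G = Y.shape[0]

    betas = np.empty((G, p))
    s2 = np.empty(G)
    cov_unscaled = np.empty((G, p, p))
    Linv = linalg.solve_triangular(L, np.eye(n), lower=True)
    for g in range(G):
        sw = np.sqrt(W[g])
        Xw = Linv @ (X * sw[:, None])
        yw = Linv @ (Y[g] * sw)
        beta, res_ss, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        betas[g] = beta
        r = yw - Xw @ beta
        s2[g] = (r @ r) / (n - p)
        cov_unscaled[g] = np.linalg.inv(Xw.T @ Xw)

    d_g = n - p
    d0, s0_2, s2_post = squeeze_var(s2, d_g)
    df_total = d0 + d_g
    ave_expr = Y.mean(axis=1)

    tables = {}
    for name, c in contrasts.items():
        lfc = betas @ c
        var_u = np.einsum("i,gij,j->g", c, cov_unscaled, c)
        se = np.sqrt(s2_post * var_u)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        if np.isinf(df_total):
            pvals = 2 * stats.norm.sf(np.abs(t))
        else:
            pvals = 2 * stats.t.sf(np.abs(t), df_total)
        tables[name] = pd.DataFrame({
            "gene_id": log_expr.index, "log2FC": lfc, "AveExpr": ave_expr,
            "t": t, "p": pvals, "q": bh_fdr(pvals),
        }).set_index("gene_id", drop=False)

    return ModeratedDEResults(tables=tables, rho=rho, d0=float(d0),
                              s0_2=s0_2, fdr=fdr, coef_names=coef_names)
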