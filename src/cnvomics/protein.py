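"""TMT proteomics: multi-run normalization and mixed-model differential
protein expression.

Multiplexed TMT runs are merged on the pooled reference channels carried
by every run (duplicate 131N/131C channels of a common peptide pool):
on the log2 scale each run is centred at its per-peptide reference mean
and re-anchored at the grand mean, which removes run offsets exactly while
conserving within-run contrasts.  Repeated measurements of a subject
(clones, replicates, runs) are collapsed to one value per
(peptide, subject) by the median.  Differential expression then fits, per
protein, a linear mixed model with genotype as fixed effect and a random
intercept per peptide — peptides of one protein are repeated measurements
of the same underlying abundance and are not independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .de import bh_fdr

REFERENCE_CHANNELS = ("131N", "131C")
REF_SAMPLE_ID = "REF"


# ---------------------------------------------------------------------------
# normalization and collapse

def normalize_tmt_runs(peptide_table: pd.DataFrame,
                       reference_channels: tuple[str, ...] = REFERENCE_CHANNELS
                       ) -> pd.DataFrame:
    """Merge TMT runs on their pooled reference channels.

    Input is a long table (run_id, channel, sample_id, peptide_id,
    protein_id, intensity) — one frame covering all runs or a list of
    per-run frames.  Intensities are log2-transformed; per run and peptide
    the mean reference-channel log2 intensity is subtracted and the grand
    mean of those reference levels (across runs) added back.  Peptides
    missing from a run stay missing.  Returns the table with a
    ``log2_intensity`` column and an ``is_reference`` flag.
    """
    if isinstance(peptide_table, (list, tuple)):
        peptide_table = pd.concat(peptide_table, ignore_index=True)
    t = peptide_table.copy()
    if (t["intensity"] <= 0).any():
        raise ValueError("intensities must be positive")
    t["is_reference"] = (t["channel"].isin(reference_channels)
                         | (t["sample_id"] == REF_SAMPLE_ID))
    for run, grp in t.groupby("run_id"):
        if not grp["is_reference"].any():
            raise ValueError(f"run {run!r} has no reference channel")
    t["log2_intensity"] = np.log2(t["intensity"])

    refs = t[t["is_reference"]]
    ref_level = refs.groupby(["run_id", "peptide_id"])["log2_intensity"].mean()
    grand = ref_level.groupby("peptide_id").mean()

    key = pd.MultiIndex.from_frame(t[["run_id", "peptide_id"]])
    per_cell_ref = ref_level.reindex(key).to_numpy()
    per_cell_grand = grand.reindex(t["peptide_id"]).to_numpy()
    # ratio before log: equal intensity/reference ratios across runs give
    # exactly equal normalized values, with no log round-off in between
    t["log2_intensity"] = (np.log2(t["intensity"].to_numpy()
                                   / np.exp2(per_cell_ref))
                           + per_cell_grand)
    return t


@dataclass
class NormalizedPeptideMatrix:
    """One log2 value per (peptide, subject) plus the peptide->protein map."""

    matrix: pd.DataFrame             # peptides x subjects
    protein_of: pd.Series            # peptide_id -> protein_id
    genotype_of: pd.Series           # subject -> genotype

    @property
    def proteins(self) -> np.ndarray:
        return self.protein_of.unique()


def collapse_subject_measurements(merged: pd.DataFrame,
                                  design: pd.DataFrame,
                                  subject_col: str = "individual"
                                  ) -> NormalizedPeptideMatrix:
    """Collapse all measurements of a subject (clones x replicates x runs)
    to one value per peptide by the median of the normalized log2
    intensities."""
    bio = merged[~merged["is_reference"]].copy()
    dmap = design.set_index("sample_id")
    bio["subject"] = dmap[subject_col].reindex(bio["sample_id"]).to_numpy()
    if bio["subject"].isna().any():
        missing = bio.loc[bio["subject"].isna(), "sample_id"].unique()[:5]
        raise ValueError(f"samples absent from design: {list(missing)}")
    mat = (bio.groupby(["peptide_id", "subject"])["log2_intensity"]
           .median().unstack("subject"))
    protein_of = (bio.drop_duplicates("peptide_id")
                  .set_index("peptide_id")["protein_id"])
    if (bio.groupby("peptide_id")["protein_id"].nunique() > 1).any():
        raise ValueError("a peptide maps to more than one protein")
    genotype_of = (design.drop_duplicates(subject_col)
                   .set_index(subject_col)["genotype"]
                   .reindex(mat.columns))
    return NormalizedPeptideMatrix(mat, protein_of.loc[mat.index], genotype_of)


def protein_matrix_from_peptides(merged: pd.DataFrame) -> pd.DataFrame:
    """Protein x sample log2 matrix from summed peptide intensities
    (the summarization used for protein co-expression networks)."""
    bio = merged[~merged["is_reference"]]
    linear = np.exp2(bio["log2_intensity"])
    summed = (bio.assign(linear=linear)
              .groupby(["protein_id", "sample_id"])["linear"].sum()
              .unstack("sample_id"))
    return np.log2(summed)


# ---------------------------------------------------------------------------
# per-protein mixed model

_CONTRAST_CODING = {
    # contrast -> (columns of the full fixed design, columns of the reduced)
    "DEL_vs_CTRL": ("full", "no_del"),
    "DUP_vs_CTRL": ("full", "no_dup"),
    "DUP_vs_DEL": ("full", "del_eq_dup"),
}


def _fixed_design(genotype: np.ndarray, coding: str) -> np.ndarray:
    del_i = (genotype == "DEL").astype(float)
    dup_i = (genotype == "DUP").astype(float)
    one = np.ones(len(genotype))
    if coding == "full":
        return np.column_stack([one, del_i, dup_i])
    if coding == "no_del":  # beta_DEL constrained to 0
        return np.column_stack([one, dup_i])
    if coding == "no_dup":
        return np.column_stack([one, del_i])
    if coding == "del_eq_dup":
        return np.column_stack([one, del_i + dup_i])
    raise ValueError(coding)


@dataclass
class ProteinDEResults:
    """Per-contrast mixed-model test tables for all proteins."""

    tables: dict[str, pd.DataFrame]
    fdr: float = 0.10

    def significant(self, contrast: str, fdr: float | None = None) -> pd.DataFrame:
        t = self.tables[contrast]
        return t[t["q"] < (self.fdr if fdr is None else fdr)]

    def summary(self) -> str:
        lines = ["Mixed-model differential protein expression",
                 "=" * 48,
                 f"FDR threshold: {self.fdr:.2f}",
                 f"{'contrast':<16}{'proteins':>10}{'DE':>8}{'OLS-fallback':>14}"]
        for name, t in self.tables.items():
            lines.append(
                f"{name:<16}{len(t):>10}{int((t['q'] < self.fdr).sum()):>8}"
                f"{int((~t['converged']).sum()):>14}")
        return "\n".join(lines)


class ProteinMixedDE:
    """Per-protein linear mixed model y = genotype + (1 | peptide).

    Built from a collapsed `NormalizedPeptideMatrix`; `fit()` REML-fits
    each protein for the effect estimates and variance components and
    uses ML likelihood-ratio refits for contrast p-values (chi-square,
    1 df), BH-corrected across proteins.
    """

    def __init__(self, data: NormalizedPeptideMatrix, fdr: float = 0.10):
        self.data = data
        self.fdr = fdr
        counts = self.data.genotype_of.value_counts()
        if (counts < 2).any():
            raise ValueError("need >= 2 subjects per genotype")

    def fit(self, contrasts: tuple[str, ...] = tuple(_CONTRAST_CODING)
            ) -> ProteinDEResults:
        mat, protein_of = self.data.matrix, self.data.protein_of
        genotype = self.data.genotype_of
        rows: dict[str, list] = {c: [] for c in contrasts}
        for prot in protein_of.unique():
            peps = protein_of.index[protein_of == prot]
            sub = mat.loc[peps].stack(future_stack=True).dropna()
            y = sub.to_numpy(float)
            pep_id = sub.index.get_level_values(0).to_numpy()
            subj = sub.index.get_level_values(1)
            geno = genotype.reindex(subj).to_numpy()
            n_pep = len(peps)
            res = _fit_protein(y, geno, pep_id, n_pep, contrasts)
            for c in contrasts:
                rows[c].append({"protein_id": prot, **res[c],
                                "n_peptides": n_pep})
        tables = {}
        for c in contrasts:
            t = pd.DataFrame(rows[c]).set_index("protein_id", drop=False)
            t["q"] = bh_fdr(t["p"].to_numpy())
            tables[c] = t
        return ProteinDEResults(tables=tables, fdr=self.fdr)


def _contrast_estimate(beta: np.ndarray, contrast: str) -> float:
    # full coding: [intercept, DEL, DUP]
    if contrast == "DEL_vs_CTRL":
        return float(beta[1])
    if contrast == "DUP_vs_CTRL":
        return float(beta[2])
    return float(beta[2] - beta[1])


def _fit_protein(y: np.ndarray, geno: np.ndarray, pep_id: np.ndarray,
                 n_pep: int, contrasts) -> dict[str, dict]:
    """REML estimates + per-contrast ML likelihood-ratio tests for one
    protein; single-peptide proteins and non-converging fits fall back
    to OLS (flagged)."""
    X_full = _fixed_design(geno, "full")
    out: dict[str, dict] = {}
    use_ols = n_pep < 2
    beta = sigma_u2 = sigma_e2 = None
    if not use_ols:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                m = sm.MixedLM(y, X_full, groups=pep_id)
                r = m.fit(reml=True)
                if not r.converged:
                    raise ValueError("REML did not converge")
                beta = np.asarray(r.fe_params)
                sigma_u2 = float(np.asarray(r.cov_re)[0, 0])
                sigma_e2 = float(r.scale)
                ll_full = sm.MixedLM(y, X_full, groups=pep_id).fit(
                    reml=False).llf
            except Exception:
                use_ols = True
    if use_ols:
        beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        resid = y - X_full @ beta
        dof = max(len(y) - X_full.shape[1], 1)
        sigma_u2, sigma_e2 = 0.0, float(resid @ resid / dof)

    for c in contrasts:
        est = _contrast_estimate(beta, c)
        if use_ols:
            p = _ols_contrast_p(y, geno, c)
        else:
            X_red = _fixed_design(geno, _CONTRAST_CODING[c][1])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    ll_red = sm.MixedLM(y, X_red, groups=pep_id).fit(
                        reml=False).llf
                    lr = max(0.0, 2 * (ll_full - ll_red))
                    p = float(stats.chi2.sf(lr, df=1))
                except Exception:
                    p = _ols_contrast_p(y, geno, c)
        out[c] = {"log2FC": est, "sigma_u2": sigma_u2, "sigma_e2": sigma_e2,
                  "p": p, "converged": not use_ols}
    return out


def _ols_contrast_p(y: np.ndarray, geno: np.ndarray, contrast: str) -> float:
    a, b = contrast.split("_vs_")
    ya, yb = y[geno == a], y[geno == b]
    if len(ya) < 2 or len(yb) < 2:
        return float("nan")
    return float(stats.ttest_ind(ya, yb).pvalue)
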