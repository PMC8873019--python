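"""Cross-omics integration and small phenotype computations.

Three self-contained analyses: the correlation between RNA and protein
log2 fold changes over shared gene/protein identifiers (optionally
restricted to the union of RNA- and protein-level discoveries, or
excluding the focal locus), organoid-size binning (small / medium /
large by +-1 SD within a batch, proportions averaged across batches),
and relative qPCR quantification by the delta-delta-Ct method.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def pair_omics(rna_table: pd.DataFrame, protein_table: pd.DataFrame,
               annotations: pd.DataFrame | None = None,
               protein_prefix: str = "P_") -> pd.DataFrame:
    """Join one RNA and one protein DE table into a matched fold-change
    frame keyed by gene id.  Protein ids of the form ``P_<gene>`` map
    directly; an annotation table with is_locus adds the locus flag."""
    prot = protein_table.copy()
    prot["gene_id"] = prot["protein_id"].str.removeprefix(protein_prefix)
    merged = (rna_table[["gene_id", "log2FC", "q"]]
              .rename(columns={"log2FC": "rna_log2FC", "q": "rna_q"})
              .merge(prot[["gene_id", "log2FC", "q"]]
                     .rename(columns={"log2FC": "protein_log2FC",
                                      "q": "protein_q"}),
                     on="gene_id", how="inner"))
    if merged["gene_id"].duplicated().any():
        n = merged["gene_id"].duplicated().sum()
        warnings.warn(f"dropping {n} ambiguous gene/protein mappings")
        merged = merged[~merged["gene_id"].duplicated(keep=False)]
    if annotations is not None:
        locus = annotations.set_index("gene_id")["is_locus"]
        merged["is_locus"] = locus.reindex(merged["gene_id"]).fillna(False).to_numpy()
    else:
        merged["is_locus"] = False
    return merged


def correlate_rna_protein(pairs: pd.DataFrame,
                          subset: str = "all",
                          fdr: float = 0.10) -> tuple[float, float, int]:
    """Pearson correlation of RNA and protein log2 fold changes.

    subset: "all" uses every matched row; "de_union" keeps rows
    discovered at either level (rna_q or protein_q below ``fdr``);
    "exclude_locus" drops focal-locus rows.  Returns (r, p, n).
    """
    df = pairs
    if subset == "de_union":
        df = df[(df["rna_q"] < fdr) | (df["protein_q"] < fdr)]
    elif subset == "exclude_locus":
        df = df[~df["is_locus"]]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if len(df) < 3:
        raise ValueError("need >= 3 matched rows for a correlation")
    r, p = stats.pearsonr(df["rna_log2FC"], df["protein_log2FC"])
    return float(r), float(p), len(df)


def classify_organoid_sizes(diameters: pd.DataFrame,
                            spread: str = "sd") -> pd.DataFrame:
    """Small / medium / large organoid proportions per batch.

    Within each batch, "large" is a diameter strictly above mean + 1
    spread and "small" strictly below mean - 1 spread, where the spread
    is the SD (default) or the SEM (``spread="sem"``).  The last row
    ("average") is the across-batch arithmetic mean of the proportions.
    A zero spread puts every organoid in the medium bin.
    """
    if spread not in ("sd", "sem"):
        raise ValueError("spread must be 'sd' or 'sem'")
    rows = []
    for batch, grp in diameters.groupby("batch"):
        d = grp["diameter_um"].to_numpy(float)
        if len(d) < 3:
            raise ValueError(f"batch {batch!r} has fewer than 3 organoids")
        mu = d.mean()
        s = d.std(ddof=1)
        if spread == "sem":
            s = s / np.sqrt(len(d))
        if s == 0:
            small = large = 0.0
        else:
            large = float((d > mu + s).mean())
            small = float((d < mu - s).mean())
        rows.append({"batch": batch, "small": small,
                     "medium": 1.0 - small - large, "large": large,
                     "n": len(d)})
    out = pd.DataFrame(rows)
    avg = out[["small", "medium", "large"]].mean()
    out = pd.concat([out, pd.DataFrame([{"batch": "average", **avg.to_dict(),
                                         "n": int(out["n"].sum())}])],
                    ignore_index=True)
    return out


def delta_delta_ct(ct_table: pd.DataFrame, target_gene: str,
                   housekeeping_genes: tuple[str, ...] = ("HPRT1", "ACTB"),
                   reference_group: str = "CTRL") -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    Per sample, dCt = Ct(target) - mean Ct(housekeeping); ddCt subtracts
    the reference group's mean dCt; fold change = 2^(-ddCt).  Samples
    missing a housekeeping measurement are dropped with a warning.
    """
    wide = ct_table.pivot_table(index="sample", columns="gene", values="ct")
    groups = ct_table.drop_duplicates("sample").set_index("sample")["group"]
    hk = [g for g in housekeeping_genes if g in wide.columns]
    if not hk:
        raise ValueError("no housekeeping gene present in the Ct table")
    if target_gene not in wide.columns:
        raise ValueError(f"target gene {target_gene!r} absent from Ct table")
    ok = wide[hk].notna().all(axis=1) & wide[target_gene].notna()
    if (~ok).any():
        warnings.warn(f"dropping {(~ok).sum()} samples with missing Ct")
        wide = wide[ok]
    d_ct = wide[target_gene] - wide[hk].mean(axis=1)
    grp = groups.reindex(wide.index)
    if reference_group not in set(grp):
        raise ValueError(f"reference group {reference_group!r} absent")
    dd_ct = d_ct - d_ct[grp == reference_group].mean()
    return pd.DataFrame({"sample": wide.index, "group": grp.to_numpy(),
                         "delta_ct": d_ct.to_numpy(),
                         "delta_delta_ct": dd_ct.to_numpy(),
                         "fold_change": np.exp2(-dd_ct.to_numpy())})
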