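"""Expression analysis: tissue clustering, salt-stress DE calling, qPCR.

Mirrors the expression arm of a gene-family survey: RPKM-style matrices
are log2-transformed, genes are grouped by hierarchical clustering of
their tissue profiles, salt-stress differential expression is called with
a fold-change threshold (> 2, two-sided) and Benjamini-Hochberg FDR
(< 0.05), and qRT-PCR Ct tables are reduced to relative expression with
the 2^-ddCt method against a reference gene and a control condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


def log2_matrix(
    m: pd.DataFrame, pseudocount: float = 1.0, drop_silent: bool = False
) -> pd.DataFrame:
    """log2(value + pseudocount) transform of an abundance matrix.

    ``drop_silent`` removes genes with zero abundance in every sample
    before transforming.  A zero value with pseudocount 0 is an error.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if (m.values < 0).any():
        raise ValueError("abundance matrix contains negative values")
    if drop_silent:
        m = m.loc[(m != 0).any(axis=1)]
    if pseudocount == 0 and (m.values == 0).any():
        raise ValueError("zero values require a positive pseudocount")
    return np.log2(m + pseudocount)


def cluster_tissues(
    log2_m: pd.DataFrame,
    k_groups: int = 6,
    linkage: str = "average",
    metric: str = "correlation",
) -> tuple[pd.Series, np.ndarray]:
    """Group genes by hierarchical clustering of their tissue profiles.

    Default: average linkage on (1 - Pearson correlation) distance.
    Returns the gene -> group labels (1..k_groups) from cutting the
    dendrogram into exactly ``k_groups`` clusters, plus the scipy linkage
    matrix for dendrogram export.
    """
    n = len(log2_m)
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    if not 1 <= k_groups <= n:
        raise ValueError(f"k_groups must be in [1, {n}]")
    if metric == "correlation":
        # explicit correlation distance; constant rows get distance 1
        vals = log2_m.values
        centered = vals - vals.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        unit = centered / safe[:, None]
        corr = unit @ unit.T
        dist = 1.0 - np.clip(corr, -1.0, 1.0)
        dist[norms == 0, :] = 1.0
        dist[:, norms == 0] = 1.0
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        z = hierarchy.linkage(condensed, method=linkage)
    else:
        z = hierarchy.linkage(log2_m.values, method=linkage, metric=metric)
    labels = hierarchy.fcluster(z, t=k_groups, criterion="maxclust")
    return pd.Series(labels, index=log2_m.index, name="group"), z


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick dendrogram."""
    tree = hierarchy.to_tree(z)

    def _fmt(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = _fmt(node.left, node.dist)
        right = _fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return _fmt(tree, tree.dist) + ";"


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    m: pd.DataFrame,
    metadata: pd.DataFrame,
    control: str,
    treated: str,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
    p_values: pd.Series | None = None,
    var_ratio_threshold: float | None = None,
) -> pd.DataFrame:
    """Differential-expression calls for treated vs control.

    Fold change is the ratio of condition means (pseudocount-stabilized);
    the p-value is a two-sided Welch t-test on log2(value + pseudocount)
    unless precomputed ``p_values`` are supplied; BH FDR is applied across
    all genes.  A gene is called iff |log2 fold change| > log2(fc_threshold)
    and FDR < fdr_threshold, two-sided so both up- and down-regulation
    count.  ``var_ratio_threshold`` optionally masks genes whose
    between-condition log2 variance ratio exceeds the threshold.
    """
    for cond in (control, treated):
        if cond not in set(metadata["condition"]):
            raise ValueError(f"condition {cond!r} absent from metadata")
    ctrl_samples = metadata.loc[metadata["condition"] == control, "sample"].tolist()
    trt_samples = metadata.loc[metadata["condition"] == treated, "sample"].tolist()
    c = m[ctrl_samples].values
    t = m[trt_samples].values
    if p_values is None and (c.shape[1] < 2 or t.shape[1] < 2):
        raise ValueError(
            "need >= 2 replicates per condition for the internal test; "
            "supply precomputed p_values otherwise"
        )
    mean_c = c.mean(axis=1)
    mean_t = t.mean(axis=1)
    fc = (mean_t + pseudocount) / (mean_c + pseudocount)
    log2fc = np.log2(fc)
    if p_values is not None:
        p = p_values.reindex(m.index).values.astype(float)
        if np.isnan(p).any():
            raise ValueError("precomputed p_values missing for some genes")
    else:
        log_c = np.log2(c + pseudocount)
        log_t = np.log2(t + pseudocount)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows
            p = stats.ttest_ind(log_t, log_c, axis=1, equal_var=False).pvalue
        p = np.nan_to_num(p, nan=1.0)  # zero-variance identical groups
    fdr = bh_fdr(p)
    called = (np.abs(log2fc) > np.log2(fc_threshold)) & (fdr < fdr_threshold)
    if var_ratio_threshold is not None:
        var_c = np.log2(c + pseudocount).var(axis=1, ddof=1)
        var_t = np.log2(t + pseudocount).var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.maximum(var_c, var_t) / np.minimum(var_c, var_t)
        called &= ~(ratio > var_ratio_threshold)
    return pd.DataFrame(
        dict(
            gene=m.index,
            fold_change=fc,
            log2fc=log2fc,
            p_value=p,
            fdr=fdr,
            called=called,
            direction=np.where(log2fc >= 0, "up", "down"),
        )
    ).set_index("gene")


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str,
    control: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method with per-condition t-tests.

    ``ct`` is a long table with columns gene, sample, condition, ct.
    dCt = Ct_target - Ct_reference per sample; ddCt = mean dCt(condition) -
    mean dCt(control); relative expression = 2^-ddCt.  Significance per
    condition is a two-sided t-test of replicate dCt values against the
    control replicates.  Invariant to a constant Ct offset applied to the
    whole plate.
    """
    required = {"gene", "sample", "condition", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    samples = ct["sample"].unique()
    missing = [s for s in samples if s not in ref.index]
    if missing:
        raise ValueError(f"reference gene not measured in sample(s) {missing}")
    if control not in set(ct["condition"]):
        raise ValueError(f"control condition {control!r} absent from Ct table")
    targets = ct[ct["gene"] != reference_gene].copy()
    targets["dct"] = targets["ct"].values - ref.reindex(targets["sample"]).values
    rows = []
    for gene, gdf in targets.groupby("gene", sort=True):
        ctrl = gdf.loc[gdf["condition"] == control, "dct"].values
        if ctrl.size == 0:
            raise ValueError(f"gene {gene!r} has no control-condition measurements")
        for cond, cdf in gdf.groupby("condition", sort=False):
            ddct = cdf["dct"].mean() - ctrl.mean()
            if cond == control or cdf["dct"].size < 2 or ctrl.size < 2:
                pval = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    pval = float(
                        stats.ttest_ind(cdf["dct"].values, ctrl, equal_var=False).pvalue
                    )
                if np.isnan(pval):
                    pval = 1.0
            rows.append(
                dict(
                    gene=gene, condition=cond, ddct=ddct,
                    relative_expression=2.0 ** -ddct, p_value=pval,
                    significant=bool(pval < alpha) if not np.isnan(pval) else False,
                )
            )
    return pd.DataFrame(rows)
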