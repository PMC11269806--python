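"""Protein-side characterization of sample classes.

Three steps: agglomerative clustering of z-scored protein rows into
"protein clusters" (correlated protein groups that define each sample
class), a differential shortlist filter (peptide support, fold change and
one-way ANOVA), and hypergeometric over-representation of a selected
protein set against named gene sets with Benjamini–Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

from .matrix import IntensityMatrix


@dataclass
class ProteinClusters:
    labels: pd.Series                 # cluster id per protein
    association: pd.DataFrame         # mean z-score per (cluster, sample class)


def _zscore_rows(arr: np.ndarray) -> np.ndarray:
    sd = arr.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance rows present; run QC first")
    return (arr - arr.mean(axis=1, keepdims=True)) / sd


def cluster_proteins(
    m: IntensityMatrix, n_clusters: int, classes: np.ndarray | None = None
) -> ProteinClusters:
    """Average-linkage agglomerative clustering of z-scored protein rows on
    Euclidean distance, cut at ``n_clusters``; association table gives the
    mean row z-score per (protein cluster, sample class)."""
    n_prot = m.shape[0]
    if not (2 <= n_clusters < n_prot):
        raise ValueError(f"n_clusters must lie in [2, {n_prot - 1}]")
    z = _zscore_rows(m.to_array())
    model = AgglomerativeClustering(
        n_clusters=n_clusters, metric="euclidean", linkage="average"
    )
    raw = model.fit_predict(z)
    # renumber clusters by first occurrence for deterministic labels
    remap: dict[int, int] = {}
    labels = np.array([remap.setdefault(c, len(remap) + 1) for c in raw])
    label_s = pd.Series(labels, index=m.values.index, name="protein_cluster")
    if classes is None:
        assoc = pd.DataFrame()
    else:
        classes = np.asarray(classes)
        rows = []
        for cl in sorted(set(labels)):
            zc = z[labels == cl]
            rows.append(
                {f"class_{c}": float(zc[:, classes == c].mean())
                 for c in sorted(set(classes))}
            )
        assoc = pd.DataFrame(rows, index=sorted(set(labels)))
        assoc.index.name = "protein_cluster"
    return ProteinClusters(labels=label_s, association=assoc)


def shortlist_proteins(
    m: IntensityMatrix,
    classes: np.ndarray,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Differential shortlist: peptide support >= min_peptides, max pairwise
    fold change of class means >= min_fold, one-way ANOVA p <= alpha.

    Intensities are log2; the fold change is computed on the natural scale
    as 2**(max class mean − min class mean).  All thresholds are inclusive.
    """
    classes = np.asarray(classes)
    uniq = sorted(set(classes))
    if len(uniq) < 2:
        raise ValueError("need at least 2 classes")
    for c in uniq:
        if (classes == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    arr = m.to_array()
    groups = [arr[:, classes == c] for c in uniq]
    means = np.column_stack([g.mean(axis=1) for g in groups])
    fold = 2.0 ** (means.max(axis=1) - means.min(axis=1))
    fstat, pval = stats.f_oneway(*[g.T for g in groups])
    table = pd.DataFrame(
        {
            "peptide_count": m.peptide_counts.to_numpy(),
            "fold": fold,
            "anova_p": pval,
            **{f"mean_class_{c}": means[:, i] for i, c in enumerate(uniq)},
        },
        index=m.values.index,
    )
    keep = (
        (table["peptide_count"] >= min_peptides)
        & (table["fold"] >= min_fold)
        & (table["anova_p"] <= alpha)
    )
    return table.loc[keep].sort_values("anova_p")


# ----------------------------------------------------------------------
def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: tab-separated name, description, members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *members = parts
            sets[name] = {m for m in members if m}
    return sets


def ora_hypergeometric(
    selected: set[str], universe: set[str], gene_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Hypergeometric over-representation of `selected` within each gene set.

    Sets are intersected with the universe first; p is the upper-tail
    probability of observing at least the overlap; q is Benjamini–Hochberg
    adjusted across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(selected) <= set(universe):
        raise ValueError("selected identifiers must be a subset of the universe")
    M, N = len(universe), len(selected)
    rows = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        n = len(in_universe)
        k = len(in_universe & selected)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {
                "gene_set": name,
                "set_size": n,
                "overlap": k,
                "p": min(p, 1.0),
                "members": ";".join(sorted(in_universe & selected)),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_set")
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q"] = []
    return table.sort_values("p")
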