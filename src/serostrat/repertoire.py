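"""B-cell-receptor repertoire metrics on AIRR-style clonotype tables.

A clonotype is a unique (v_call, j_call, CDR3 amino-acid) combination;
relative frequencies are computed within each (chain, isotype) stratum.
Provided metrics: clonotype counts per stratum, frequency-bin occupancy
(with "hyperexpanded" meaning relative frequency > 0.01), clonotype-
weighted V / J / V–J usage tables, and single-linkage clustering of CDR3
sequences at a normalized edit-distance similarity threshold.
"""

from __future__ import annotations

import re

import edlib
import numpy as np
import pandas as pd

VALID_CHAINS = {"IGH", "IGK", "IGL"}
ISOTYPE_MAP = {"IGHA": "IgA", "IGHD": "IgD", "IGHE": "IgE",
               "IGHG": "IgG", "IGHM": "IgM"}
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

DEFAULT_BINS = [0.0, 1e-4, 1e-3, 0.01, 0.1, 1.0]
HYPEREXPANDED_EDGE = 0.01


class ClonotypeTable:
    """Per-sample clonotype records with derived within-stratum frequencies.

    Accepts an AIRR rearrangement frame (columns locus, c_call, v_call,
    j_call, junction_aa, duplicate_count); records sharing
    (v_call, j_call, junction_aa) within a stratum are merged with summed
    counts.  The junction amino-acid string (terminal residues retained)
    serves as the CDR3.
    """

    REQUIRED = ["locus", "c_call", "v_call", "j_call", "junction_aa",
                "duplicate_count"]

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in records.columns]
        if missing:
            raise ValueError(f"missing AIRR columns: {missing}")
        df = records[self.REQUIRED].copy()
        bad = set(df["locus"]) - VALID_CHAINS
        if bad:
            raise ValueError(f"unknown chain code(s): {sorted(bad)}")
        if (df["duplicate_count"] < 1).any():
            raise ValueError("duplicate_count must be >= 1")
        bad_cdr3 = df["junction_aa"][~df["junction_aa"].astype(str).str.match(_AA_RE)]
        if len(bad_cdr3):
            raise ValueError(f"invalid CDR3 sequence: {bad_cdr3.iloc[0]!r}")
        df["isotype"] = [
            ISOTYPE_MAP.get(str(c)[:4], "") if loc == "IGH" else ""
            for c, loc in zip(df["c_call"], df["locus"])
        ]
        # clonotype identity: (v, j, cdr3); merge duplicates, summing reads
        grouped = (
            df.groupby(["locus", "isotype", "v_call", "j_call", "junction_aa"],
                       sort=False, as_index=False)["duplicate_count"].sum()
        )
        totals = grouped.groupby(["locus", "isotype"])["duplicate_count"].transform("sum")
        grouped["frequency"] = grouped["duplicate_count"] / totals
        self.records = grouped

    def stratum(self, chain: str, isotype: str = "") -> pd.DataFrame:
        r = self.records
        return r[(r["locus"] == chain) & (r["isotype"] == isotype)]


def clonotype_summary(t: ClonotypeTable) -> pd.DataFrame:
    """Distinct clonotype count and total reads per (chain, isotype)."""
    return (
        t.records.groupby(["locus", "isotype"])
        .agg(n_clonotypes=("junction_aa", "size"),
             total_reads=("duplicate_count", "sum"))
        .reset_index()
    )


def frequency_bins(
    t: ClonotypeTable,
    bins: list[float] | None = None,
    chain: str = "IGH",
    isotype: str = "IgG",
) -> pd.Series:
    """Repertoire occupancy per frequency bin for one stratum.

    occupancy(bin) = summed frequency of clonotypes whose frequency falls
    in the half-open bin (lo, hi]; occupancies sum to 1.  The top two
    default bins (frequency > 0.01) constitute the hyperexpanded fraction.
    """
    edges = np.asarray(DEFAULT_BINS if bins is None else bins, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    freqs = t.stratum(chain, isotype)["frequency"].to_numpy()
    labels = [f"({edges[i]:g},{edges[i+1]:g}]" for i in range(len(edges) - 1)]
    idx = np.searchsorted(edges, freqs, side="left") - 1
    idx = np.clip(idx, 0, len(labels) - 1)
    occ = pd.Series(0.0, index=labels)
    for i, f in zip(idx, freqs):
        occ.iloc[i] += f
    return occ


def hyperexpanded_occupancy(
    t: ClonotypeTable, chain: str = "IGH", isotype: str = "IgG",
    edge: float = HYPEREXPANDED_EDGE,
) -> float:
    """Summed frequency of clonotypes with relative frequency > edge."""
    freqs = t.stratum(chain, isotype)["frequency"].to_numpy()
    return float(freqs[freqs > edge].sum())


def vj_usage(
    t: ClonotypeTable, chain: str = "IGH", isotype: str = "IgG"
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Clonotype-weighted V, J and V–J pair usage (each table sums to 1).

    Every distinct clonotype counts once, regardless of read depth; the
    V–J table is indexed by "V/J" strings and its marginals reproduce the
    V and J tables exactly.
    """
    s = t.stratum(chain, isotype)
    n = len(s)
    if n == 0:
        return pd.Series(dtype=float), pd.Series(dtype=float), pd.Series(dtype=float)
    v = s["v_call"].value_counts() / n
    j = s["j_call"].value_counts() / n
    vj = (s["v_call"] + "/" + s["j_call"]).value_counts() / n
    return v.sort_index(), j.sort_index(), vj.sort_values(ascending=False)


def cluster_cdr3(sequences: list[str], threshold: float = 0.8) -> np.ndarray:
    """Single-linkage CDR3 clusters at normalized edit-distance similarity.

    similarity(a, b) = 1 − levenshtein(a, b) / max(len(a), len(b)); an edge
    joins two sequences when similarity >= threshold and clusters are the
    connected components.  Labels are ordered by first occurrence.
    """
    if len(sequences) == 0:
        raise ValueError("no sequences")
    if any(not s for s in sequences):
        raise ValueError("empty CDR3 sequence")
    n = len(sequences)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for jdx in range(i + 1, n):
            a, b = sequences[i], sequences[jdx]
            d = edlib.align(a, b)["editDistance"]
            if 1.0 - d / max(len(a), len(b)) >= threshold:
                ri, rj = find(i), find(jdx)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    remap: dict[int, int] = {}
    return np.array([remap.setdefault(r, len(remap)) for r in roots])
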