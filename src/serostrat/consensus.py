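"""Subsampled spherical k-means consensus partitioning with rule-based
best-k selection.

The sample-stratification core of the package.  Features (protein rows)
are ranked by ATC — the mean absolute Pearson correlation of a row to all
other rows — and the top fraction is retained.  For each candidate k, the
feature rows are repeatedly subsampled, all samples are partitioned by
spherical k-means (cosine similarity on unit-normalized sample vectors),
and the co-clustering fractions form the consensus matrix.  Per-k
stability is summarised by 1-PAC (one minus the proportion of ambiguous
consensus entries), mean silhouette on the consensus distance, concordance
of individual partitions with the voted consensus classes, and the
pair-set Jaccard index against the previous k.  Three decision rules pick
the best k:

1. discard any k whose Jaccard index against k-1 exceeds 0.95 (the extra
   partition adds nothing);
2. among survivors with 1-PAC > 0.9, take the maximum k as best and mark
   the others optional;
3. otherwise take the majority vote among the argmax of 1-PAC, mean
   silhouette and concordance (1-PAC wins a three-way disagreement).

`ConsensusPartition` is the model object; `fit()` returns a
`ConsensusResult` with the estimates, per-sample confidence and a
`summary()` table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_samples

from .matrix import IntensityMatrix


@dataclass
class PartitionConfig:
    k_min: int = 2
    k_max: int = 6
    n_repeats: int = 50
    subsample_frac: float = 0.8
    top_frac: float = 0.5
    n_starts: int = 10
    seed: int = 0
    pac_interval: tuple[float, float] = (0.1, 0.9)
    jaccard_cut: float = 0.95
    one_minus_pac_cut: float = 0.9
    confident_silhouette: float = 0.5
    max_iter: int = 100

    def __post_init__(self):
        if not (0.0 < self.subsample_frac <= 1.0):
            raise ValueError("subsample_frac must lie in (0,1]")
        if self.pac_interval[0] >= self.pac_interval[1]:
            raise ValueError("pac_interval must be an increasing pair")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


@dataclass
class ConsensusRun:
    k: int
    partitions: np.ndarray       # (n_repeats, n_samples) int labels
    consensus: np.ndarray        # (n_samples, n_samples) co-clustering fractions


@dataclass
class KMetrics:
    k: int
    one_minus_pac: float
    mean_silhouette: float
    concordance: float
    jaccard_prev: float | None = None


# ----------------------------------------------------------------------
# feature ranking
def atc_scores(m: IntensityMatrix) -> np.ndarray:
    """Ability-to-correlate score per row: mean |Pearson r| to all other rows."""
    arr = m.to_array()
    if arr.shape[0] < 3:
        raise ValueError("ATC needs at least 3 rows")
    if np.isnan(arr).any():
        raise ValueError("ATC requires a fully imputed matrix")
    sd = arr.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance rows present; run QC first")
    cor = np.corrcoef(arr)
    np.fill_diagonal(cor, np.nan)
    return np.nanmean(np.abs(cor), axis=1)


def select_top_features(m: IntensityMatrix, top_frac: float = 0.5) -> IntensityMatrix:
    """Keep the ceil(top_frac * n) rows with highest ATC; ties keep the
    earlier row.  Original row order is preserved among the kept rows."""
    scores = atc_scores(m)
    n_keep = int(np.ceil(top_frac * len(scores)))
    if n_keep < 2:
        raise ValueError("top_frac keeps fewer than 2 rows")
    order = np.argsort(-scores, kind="stable")   # stable: earlier index wins ties
    keep = np.zeros(len(scores), dtype=bool)
    keep[order[:n_keep]] = True
    return m.subset_rows(keep)


# ----------------------------------------------------------------------
# spherical k-means
def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero-norm sample vector")
    return x / norms


def spherical_kmeans(
    samples: np.ndarray,
    k: int,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 100,
) -> np.ndarray:
    """Cluster unit-normalized sample vectors by cosine similarity.

    Centroids are re-normalized to unit length each iteration; the restart
    with the largest total cosine similarity to assigned centroids wins.
    Deterministic given the seed.
    """
    x = _unit_rows(np.asarray(samples, dtype=float))
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    rng = np.random.default_rng(seed)
    best_labels, best_obj = None, -np.inf
    for _ in range(n_starts):
        centroids = x[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1, dtype=int)
        for _it in range(max_iter):
            sim = x @ centroids.T            # (n, k) cosine similarities
            new_labels = sim.argmax(axis=1)
            worst_first = np.argsort(sim.max(axis=1))
            taken = 0
            for c in range(k):               # revive empty clusters
                if not (new_labels == c).any():
                    new_labels[worst_first[taken]] = c
                    taken += 1
            if (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                members = x[labels == c]
                if len(members) == 0:
                    continue
                mean = members.mean(axis=0)
                norm = np.linalg.norm(mean)
                centroids[c] = mean / norm if norm > 0 else x[rng.integers(n)]
        obj = (x * centroids[labels]).sum()
        if obj > best_obj:
            best_obj, best_labels = obj, labels.copy()
    return best_labels


# ----------------------------------------------------------------------
def consensus_for_k(m: IntensityMatrix, k: int, config: PartitionConfig) -> ConsensusRun:
    """Feature-subsampled consensus: every repeat keeps all samples, draws
    ceil(subsample_frac * rows) feature rows without replacement, z-scores
    rows and partitions the unit-normalized sample columns."""
    arr = m.to_array()
    n_rows, n_samples = arr.shape
    n_sub = int(np.ceil(config.subsample_frac * n_rows))
    rng = np.random.default_rng(config.seed + 1000 * k)
    partitions = np.zeros((config.n_repeats, n_samples), dtype=int)
    co = np.zeros((n_samples, n_samples))
    for r in range(config.n_repeats):
        rows = rng.choice(n_rows, size=n_sub, replace=False)
        sub = arr[rows]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        labels = spherical_kmeans(
            z.T, k, n_starts=config.n_starts,
            seed=int(rng.integers(2**31)), max_iter=config.max_iter,
        )
        partitions[r] = labels
        co += labels[:, None] == labels[None, :]
    consensus = co / config.n_repeats
    np.fill_diagonal(consensus, 1.0)
    return ConsensusRun(k=k, partitions=partitions, consensus=consensus)


def pac_score(run: ConsensusRun, pac_interval: tuple[float, float] = (0.1, 0.9)) -> float:
    """1 − PAC, where PAC is the fraction of strictly-upper-triangle
    consensus entries falling strictly inside the ambiguous interval."""
    x1, x2 = pac_interval
    iu = np.triu_indices(run.consensus.shape[0], k=1)
    c = run.consensus[iu]
    pac = np.mean((c > x1) & (c < x2)) if c.size else 0.0
    return 1.0 - float(pac)


def _relabel_to_reference(labels: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Hungarian maximum-agreement relabeling of `labels` onto `reference`."""
    contingency = np.zeros((k, k))
    for a, b in zip(labels, reference):
        contingency[a, b] += 1
    row, col = linear_sum_assignment(-contingency)
    mapping = dict(zip(row, col))
    return np.array([mapping[a] for a in labels])


def consensus_classes(run: ConsensusRun) -> tuple[np.ndarray, np.ndarray, float]:
    """Voted classes, per-sample silhouettes and concordance.

    Each repeat's partition is relabeled onto the first repeat by Hungarian
    matching on the contingency table, then each sample takes the majority
    class (ties → lowest class index).  Silhouettes use 1 − consensus as
    the distance; concordance is the mean over repeats of the fraction of
    samples whose relabeled class equals the voted class.
    """
    n_repeats, n_samples = run.partitions.shape
    k = run.k
    reference = run.partitions[0]
    relabeled = np.zeros_like(run.partitions)
    for r in range(n_repeats):
        relabeled[r] = _relabel_to_reference(run.partitions[r], reference, k)
    votes = np.zeros((n_samples, k), dtype=int)
    for r in range(n_repeats):
        votes[np.arange(n_samples), relabeled[r]] += 1
    classes = votes.argmax(axis=1)          # argmax ties → lowest index
    concordance = float((relabeled == classes[None, :]).mean())
    present = np.unique(classes)
    if len(present) < k:
        # degenerate partition: renumber compactly
        remap = {c: i for i, c in enumerate(present)}
        classes = np.array([remap[c] for c in classes])
    if len(present) > 1:
        dist = 1.0 - run.consensus
        np.fill_diagonal(dist, 0.0)
        sil = silhouette_samples(dist, classes, metric="precomputed")
    else:
        sil = np.zeros(n_samples)
    return classes, sil, concordance


def jaccard_index(p1: np.ndarray, p2: np.ndarray) -> float:
    """Jaccard index over co-clustered sample pairs; 1 when both partitions
    have no co-clustered pair (all singletons)."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions must cover the same samples")
    same1 = p1[:, None] == p1[None, :]
    same2 = p2[:, None] == p2[None, :]
    iu = np.triu_indices(len(p1), k=1)
    a, b = same1[iu], same2[iu]
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def select_best_k(
    metrics: list[KMetrics], config: PartitionConfig
) -> tuple[int, list[int]]:
    """Apply the three best-k rules; returns (best_k, optional_k)."""
    survivors = [
        m for m in metrics
        if m.jaccard_prev is None or m.jaccard_prev <= config.jaccard_cut
    ]
    if not survivors:
        raise ValueError(
            "no candidate k survives the Jaccard redundancy rule: "
            + ", ".join(f"k={m.k}: jaccard_prev={m.jaccard_prev}" for m in metrics)
        )
    stable = [m for m in survivors if m.one_minus_pac > config.one_minus_pac_cut]
    if stable:
        best = max(m.k for m in stable)
        optional = sorted(m.k for m in stable if m.k != best)
        return best, optional
    # rule 3: majority vote among the three stability argmaxes
    by_pac = max(survivors, key=lambda m: (m.one_minus_pac, -m.k)).k
    by_sil = max(survivors, key=lambda m: (m.mean_silhouette, -m.k)).k
    by_con = max(survivors, key=lambda m: (m.concordance, -m.k)).k
    counts = Counter([by_pac, by_sil, by_con])
    top, n_votes = counts.most_common(1)[0]
    best = top if n_votes >= 2 else by_pac
    return best, []


# ----------------------------------------------------------------------
@dataclass
class ConsensusResult:
    """Fitted consensus partition: best k, sample classes and diagnostics."""

    best_k: int
    optional_k: list[int]
    classes: np.ndarray                 # labels in 1..best_k
    sample_silhouette: np.ndarray
    confident: np.ndarray
    metrics: list[KMetrics]
    sample_ids: list[str]
    weak_structure: bool
    runs: dict[int, ConsensusRun] = field(default_factory=dict, repr=False)
    config: PartitionConfig | None = None

    @property
    def class_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.classes, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}

    @property
    def n_confident(self) -> int:
        return int(self.confident.sum())

    def summary(self) -> str:
        lines = [
            "Consensus partition summary",
            "=" * 62,
            f"{'k':>3} {'1-PAC':>8} {'mean sil':>9} {'concord':>8} {'jac(k-1)':>9}",
        ]
        for m in self.metrics:
            jac = f"{m.jaccard_prev:.3f}" if m.jaccard_prev is not None else "   -"
            flag = "  <- best" if m.k == self.best_k else (
                "  (optional)" if m.k in self.optional_k else "")
            lines.append(
                f"{m.k:>3} {m.one_minus_pac:>8.3f} {m.mean_silhouette:>9.3f} "
                f"{m.concordance:>8.3f} {jac:>9}{flag}"
            )
        lines.append("-" * 62)
        sizes = ", ".join(f"PS{l}: {n}" for l, n in self.class_sizes.items())
        lines.append(f"best k = {self.best_k}; class sizes: {sizes}")
        lines.append(
            f"confidently assigned (silhouette >= "
            f"{self.config.confident_silhouette if self.config else 0.5}): "
            f"{self.n_confident} of {len(self.classes)}"
        )
        if self.weak_structure:
            lines.append("warning: weak structure (no k reached the 1-PAC cut)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "best_k": int(self.best_k),
            "optional_k": [int(k) for k in self.optional_k],
            "weak_structure": bool(self.weak_structure),
            "classes": {
                s: int(c) for s, c in zip(self.sample_ids, self.classes)
            },
            "sample_silhouette": {
                s: float(v) for s, v in zip(self.sample_ids, self.sample_silhouette)
            },
            "confident": {
                s: bool(v) for s, v in zip(self.sample_ids, self.confident)
            },
            "metrics": [
                {k: (None if v is None else float(v)) if k != "k" else int(v)
                 for k, v in asdict(m).items()}
                for m in self.metrics
            ],
        }


class ConsensusPartition:
    """Consensus-partition model over a post-QC intensity matrix.

    Usage::

        model = ConsensusPartition(matrix, PartitionConfig(seed=1))
        result = model.fit()
        print(result.summary())
    """

    def __init__(self, matrix: IntensityMatrix, config: PartitionConfig | None = None):
        self.matrix = matrix
        self.config = config or PartitionConfig()

    def fit(self) -> ConsensusResult:
        cfg = self.config
        top = select_top_features(self.matrix, cfg.top_frac)
        runs: dict[int, ConsensusRun] = {}
        metrics: list[KMetrics] = []
        voted: dict[int, np.ndarray] = {}
        sils: dict[int, np.ndarray] = {}
        for k in range(cfg.k_min, cfg.k_max + 1):
            run = consensus_for_k(top, k, cfg)
            classes, sil, concord = consensus_classes(run)
            voted[k], sils[k] = classes, sil
            jac = jaccard_index(classes, voted[k - 1]) if k > cfg.k_min else None
            metrics.append(
                KMetrics(
                    k=k,
                    one_minus_pac=pac_score(run, cfg.pac_interval),
                    mean_silhouette=float(sil.mean()),
                    concordance=concord,
                    jaccard_prev=jac,
                )
            )
            runs[k] = run
        best_k, optional_k = select_best_k(metrics, cfg)
        classes = voted[best_k] + 1          # classes reported in 1..best_k
        sil = sils[best_k]
        confident = sil >= cfg.confident_silhouette
        weak = max(m.one_minus_pac for m in metrics) <= cfg.one_minus_pac_cut
        return ConsensusResult(
            best_k=best_k,
            optional_k=optional_k,
            classes=classes,
            sample_silhouette=sil,
            confident=confident,
            metrics=metrics,
            sample_ids=self.matrix.sample_ids,
            weak_structure=weak,
            runs=runs,
            config=cfg,
        )


def run_consensus_pipeline(
    m: IntensityMatrix, config: PartitionConfig | None = None
) -> ConsensusResult:
    """Functional wrapper: ATC ranking → top features → consensus over the
    k range → metrics → rule-based best k → voted classes with confidence."""
    return ConsensusPartition(m, config).fit()
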