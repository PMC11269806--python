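"""Synthetic study-data generators.

These generators emulate the statistical structure a serum-proteome
stratification study assumes: a log-intensity protein matrix with planted
patient groups and correlated protein blocks, intensity-dependent
missingness and heavy-tailed outliers; clinical metadata with one
"severe" group shifted upward on the QMG / MG-ADL severity scales and a
steroid dose history; B-cell-receptor repertoires with power-law clone
sizes and group-dependent hyperexpansion; and a membrane-attack-complex
(MAC) cell-assay readout elevated in the severe group.

Every generator is a pure function of its configuration and seed: the same
seed reproduces bit-identical output.  Planted labels are returned as a
:class:`SyntheticTruth` so that recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_V_GENES = [
    "IGHV3-7", "IGHV3-23", "IGHV4-39", "IGHV4-59", "IGHV1-69",
    "IGHV3-30", "IGHV4-34", "IGHV5-51",
]
DEFAULT_J_GENES = ["IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6"]


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 140 patients, 432 proteins, 4 planted groups.

    ``block_effect`` is the mean log2-intensity shift of a protein block in
    its associated group, in units of the within-group noise SD.
    ``block_cor_sd`` is the SD of the shared per-(block, sample) latent
    factor that makes proteins of one block co-vary beyond the correlation
    already induced by the group shift; the default (a quarter of the noise
    SD) keeps the residual within-group axis well below the group effect,
    so planted groups stay internally unstructured while blocks remain
    strongly intercorrelated (r ~ 0.6 at the default block effect).
    """

    n_samples: int = 140
    n_proteins: int = 432
    n_groups: int = 4
    n_blocks: int = 4
    block_effect: float = 3.0
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    seed: int = 0
    # secondary knobs -------------------------------------------------
    block_cor_sd: float | None = None     # defaults to noise_sd / 2
    block_frac: float = 0.15              # fraction of proteins per block
    severe_group: int | None = None       # defaults to min(2, n_groups-1)
    mcar_weight: float = 0.5              # MCAR share of the missingness mixture
    severity_shift: float = 5.0           # QMG / MG-ADL shift of the severe group
    mac_shift: float = 30.0               # MAC %-point shift of the severe group
    mac_sd: float = 12.0
    hyper_band: tuple[float, float] = (0.10, 0.20)
    n_clones: int = 1500
    read_depth: int = 50000
    zipf_exponent: float = 1.2
    samples_per_group_repertoire: int = 3
    v_genes: list[str] = field(default_factory=lambda: list(DEFAULT_V_GENES))
    j_genes: list[str] = field(default_factory=lambda: list(DEFAULT_J_GENES))

    def __post_init__(self):
        if self.n_samples < 1 or self.n_proteins < 1:
            raise ConfigurationError("n_samples and n_proteins must be positive")
        if not (1 <= self.n_groups <= self.n_samples):
            raise ConfigurationError("need 1 <= n_groups <= n_samples")
        if not (1 <= self.n_blocks <= self.n_proteins):
            raise ConfigurationError("need 1 <= n_blocks <= n_proteins")
        for name in ("missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0,1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.block_effect < 0:
            raise ConfigurationError("block_effect must be non-negative")
        if self.block_cor_sd is None:
            self.block_cor_sd = 0.25 * self.noise_sd
        if self.severe_group is None:
            self.severe_group = min(2, self.n_groups - 1)
        if not (0 <= self.severe_group < self.n_groups):
            raise ConfigurationError("severe_group out of range")


@dataclass
class SyntheticTruth:
    """Planted labels: group per sample, block per protein (0 = background),
    and which blocks are elevated in which group."""

    sample_group: np.ndarray
    protein_block: np.ndarray
    group_block_map: dict[int, list[int]]
    severe_group: int

    def to_dict(self) -> dict:
        return {
            "sample_group": [int(g) for g in self.sample_group],
            "protein_block": [int(b) for b in self.protein_block],
            "group_block_map": {str(k): v for k, v in self.group_block_map.items()},
            "severe_group": int(self.severe_group),
        }


# ----------------------------------------------------------------------
def _assign_groups(n_samples: int, n_groups: int) -> np.ndarray:
    """Round-robin group assignment: sizes differ by at most one."""
    return np.arange(n_samples) % n_groups


def generate_proteome(config: SyntheticConfig) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Planted-block log2-intensity matrix with missingness and outliers.

    Model per entry: baseline(protein) + block-in-group shift
    + shared block factor + Gaussian noise.  Missing entries are a
    half/half mixture of completely-at-random and intensity-dependent
    (logistic weight decreasing in log intensity); outliers add
    ±(5–10)×noise_sd.
    """
    rng = np.random.default_rng(config.seed)
    P, S = config.n_proteins, config.n_samples
    groups = _assign_groups(S, config.n_groups)

    # protein blocks: n_blocks contiguous blocks of block_frac*P proteins each
    block_size = max(2, int(round(config.block_frac * P)))
    if config.n_blocks * block_size > P:
        block_size = max(1, P // config.n_blocks)
    protein_block = np.zeros(P, dtype=int)
    for b in range(config.n_blocks):
        protein_block[b * block_size:(b + 1) * block_size] = b + 1
    group_block_map = {
        g: [b + 1 for b in range(config.n_blocks) if b % config.n_groups == g]
        for g in range(config.n_groups)
    }

    baseline = rng.normal(20.0, 2.0, size=P)
    noise = rng.normal(0.0, config.noise_sd, size=(P, S))
    values = baseline[:, None] + noise

    # shared latent factor per (block, sample): within-block correlation
    latent = rng.normal(0.0, config.block_cor_sd, size=(config.n_blocks, S))
    for b in range(1, config.n_blocks + 1):
        values[protein_block == b] += latent[b - 1]

    # block x group elevation
    shift = config.block_effect * config.noise_sd
    for g, blocks in group_block_map.items():
        cols = groups == g
        for b in blocks:
            values[np.ix_(protein_block == b, cols)] += shift

    # outliers
    if config.outlier_rate > 0:
        out_mask = rng.random((P, S)) < config.outlier_rate
        signs = rng.choice([-1.0, 1.0], size=(P, S))
        mags = rng.uniform(5.0, 10.0, size=(P, S)) * config.noise_sd
        values = values + out_mask * signs * mags

    # missingness: MCAR + intensity-dependent logistic mixture
    if config.missing_rate > 0:
        w = config.mcar_weight
        p_mcar = np.full((P, S), config.missing_rate * w)
        med = np.median(values)
        scale = max(values.std(), 1e-12)
        logistic = 1.0 / (1.0 + np.exp((values - med) / scale))
        logistic *= config.missing_rate * (1.0 - w) / logistic.mean()
        p_miss = np.clip(p_mcar + logistic, 0.0, 1.0)
        miss_mask = rng.random((P, S)) < p_miss
        values = np.where(miss_mask, np.nan, values)

    peptide_counts = 1 + rng.poisson(3.0, size=P)
    protein_ids = [f"P{i:04d}" for i in range(P)]
    sample_ids = [f"S{i:03d}" for i in range(S)]
    matrix = IntensityMatrix(
        pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        pd.Series(peptide_counts, index=protein_ids),
    )
    truth = SyntheticTruth(groups, protein_block, group_block_map,
                           config.severe_group)
    return matrix, truth


# ----------------------------------------------------------------------
def generate_clinical(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Clinical metadata table keyed by sample.

    Baseline QMG and MG-ADL are drawn from group-shifted distributions (the
    designated severe group is shifted up by ``severity_shift``); onset age
    strictly below 50 years labels early-onset disease (EOMG), 50 or above
    late-onset (LOMG).  A 183-day daily steroid-dose history with random
    gaps and a follow-up score are attached; follow-up improvement is larger
    in the severe group, emulating preferential treatment response.
    """
    rng = np.random.default_rng(config.seed + 1)
    S = config.n_samples
    groups = np.asarray(truth.sample_group)
    if groups.shape[0] != S:
        raise ValueError("truth does not match config sample count")
    if groups.max() >= config.n_groups:
        raise ValueError(f"unknown group label {groups.max()}")
    severe = groups == truth.severe_group

    age = np.clip(rng.normal(61.5, 15.0, S), 18, 95).round().astype(int)
    onset_age = np.clip(age - rng.integers(0, 15, S), 10, None).astype(int)
    sex = rng.choice(["F", "M"], size=S)
    thymoma = rng.random(S) < 0.21

    qmg = np.clip(rng.normal(4.0, 3.0, S) + config.severity_shift * severe,
                  0, 39).round().astype(int)
    mgadl = np.clip(rng.normal(5.0, 3.0, S) + config.severity_shift * severe,
                    0, 24).round().astype(int)

    # steroid history over a 183-day pre-baseline window, JSON day->mg
    doses = []
    on_steroids = rng.random(S) < 0.55
    for i in range(S):
        if not on_steroids[i]:
            doses.append("{}")
            continue
        coverage = rng.uniform(0.5, 1.0)
        days = rng.choice(183, size=int(round(coverage * 183)), replace=False)
        base = float(rng.choice([2, 4, 5, 6, 8, 10, 15, 20]))
        if severe[i]:
            base *= 1.5
        doses.append("{" + ",".join(f'"{int(d)}":{base}' for d in sorted(days)) + "}")

    # follow-up scores for a subset: severe group improves more
    has_fu = rng.random(S) < 0.3
    improvement = np.where(severe, rng.normal(4.0, 2.0, S), rng.normal(1.5, 2.0, S))
    mgadl_fu = np.clip(mgadl - improvement.round(), 0, 24).astype(int)
    qmg_fu = np.clip(qmg - improvement.round(), 0, 39).astype(int)

    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(S)],
            "group": groups,
            "age": age,
            "onset_age": onset_age,
            "onset_class": np.where(onset_age < 50, "EOMG", "LOMG"),
            "sex": sex,
            "thymoma": thymoma,
            "qmg_baseline": qmg,
            "mgadl_baseline": mgadl,
            "steroid_doses": doses,
            "mgadl_followup": np.where(has_fu, mgadl_fu, -1),
            "qmg_followup": np.where(has_fu, qmg_fu, -1),
        }
    ).set_index("sample_id")
    return df


# ----------------------------------------------------------------------
def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    return "C" + "".join(rng.choice(list(AA_ALPHABET), size=length - 2)) + "W"


def _mutate(rng: np.random.Generator, seq: str, n: int) -> str:
    s = list(seq)
    for pos in rng.choice(np.arange(1, len(s) - 1), size=n, replace=False):
        s[pos] = rng.choice(list(AA_ALPHABET))
    return "".join(s)


def _one_repertoire(
    rng: np.random.Generator,
    config: SyntheticConfig,
    hyper_occupancy: float,
    locus: str,
    isotype: str | None,
    v_genes: list[str],
    j_genes: list[str],
    top_pair: tuple[str, str] | None,
) -> pd.DataFrame:
    """Clone-frequency vector: optional hyperexpanded clones carrying
    ``hyper_occupancy`` of the repertoire, remainder a Zipf tail capped at
    frequency 0.008 so tail clones stay below the hyperexpansion edge
    (0.01) even under multinomial sampling noise.  Observed counts are a
    multinomial draw at the configured read depth; unobserved clones are
    dropped, so repertoires that concentrate mass in expanded clones yield
    fewer distinct clonotypes at equal depth."""
    n = config.n_clones
    ranks = np.arange(1, n + 1, dtype=float)
    tail = ranks ** (-config.zipf_exponent)
    hyper_freqs: list[float] = []
    if hyper_occupancy > 0.01:
        n_hyper = max(1, int(hyper_occupancy // 0.04) + 1)
        parts = rng.dirichlet(np.full(n_hyper, 5.0)) * hyper_occupancy
        # keep every hyper clone above the 0.01 edge
        parts = np.maximum(parts, 0.011)
        parts *= hyper_occupancy / parts.sum()
        hyper_freqs = list(parts)
    tail *= (1.0 - sum(hyper_freqs)) / tail.sum()
    # clamp tail clones below the hyperexpansion edge, renormalize over tail
    cap = 0.008
    for _ in range(50):
        over = tail > cap
        if not over.any():
            break
        excess = (tail[over] - cap).sum()
        tail[over] = cap
        under = ~over
        tail[under] += excess * tail[under] / tail[under].sum()
    freqs = np.array(hyper_freqs + list(tail))
    counts = rng.multinomial(config.read_depth, freqs / freqs.sum())
    observed = counts > 0
    n_hyper_obs = int(observed[: len(hyper_freqs)].sum())
    freqs, counts = freqs[observed], counts[observed]

    n_total = len(freqs)
    v = rng.choice(v_genes, size=n_total)
    j = rng.choice(j_genes, size=n_total)
    if top_pair is not None and n_hyper_obs:
        v[:n_hyper_obs], j[:n_hyper_obs] = top_pair
    lengths = rng.integers(10, 20, size=n_total)
    cdr3 = np.empty(n_total, dtype=object)
    if n_hyper_obs:
        motif = _random_cdr3(rng, 14)
        for i in range(n_hyper_obs):
            cdr3[i] = _mutate(rng, motif, 1)
    n_tail = n_total - n_hyper_obs
    if n_tail:
        # vectorized random inner residues, sliced to per-clone lengths
        max_len = int(lengths.max())
        chars = rng.integers(0, len(AA_ALPHABET), size=(n_tail, max_len))
        alphabet = np.array(list(AA_ALPHABET))
        for off, i in enumerate(range(n_hyper_obs, n_total)):
            inner = alphabet[chars[off, : int(lengths[i]) - 2]]
            cdr3[i] = "C" + "".join(inner) + "W"
    return pd.DataFrame(
        {
            "sequence_id": [f"seq{i}" for i in range(n_total)],
            "locus": locus,
            "c_call": isotype if isotype else locus[:3] + "C",
            "v_call": v,
            "j_call": j,
            "junction_aa": cdr3,
            "duplicate_count": counts,
        }
    )


def generate_repertoires(
    truth: SyntheticTruth, config: SyntheticConfig
) -> dict[str, pd.DataFrame]:
    """AIRR-style clonotype tables for a per-group subset of samples.

    Severe-group repertoires place 10–20% (``hyper_band``) of heavy-chain
    IgG mass in hyperexpanded clones (relative frequency > 0.01) sharing a
    CDR3 motif and a fixed V–J pair (IGHV3-7/IGHJ4); other groups stay in
    the 0–5% occupancy range seen in non-severe patients.  Light-chain
    (IGK/IGL) repertoires are appended without hyperexpansion.
    """
    if not config.v_genes or not config.j_genes:
        raise ConfigurationError("gene lists must be non-empty")
    rng = np.random.default_rng(config.seed + 2)
    groups = np.asarray(truth.sample_group)
    out: dict[str, pd.DataFrame] = {}
    for g in range(config.n_groups):
        members = np.where(groups == g)[0][: config.samples_per_group_repertoire]
        for idx in members:
            if g == truth.severe_group:
                occ = rng.uniform(*config.hyper_band)
                top_pair = ("IGHV3-7", "IGHJ4")
            else:
                occ = rng.uniform(0.0, 0.05)
                top_pair = None
            parts = [
                _one_repertoire(rng, config, occ, "IGH", "IGHG",
                                config.v_genes, config.j_genes, top_pair)
            ]
            for locus, vg, jg in (
                ("IGK", ["IGKV1-39", "IGKV3-20", "IGKV4-1"], ["IGKJ1", "IGKJ2"]),
                ("IGL", ["IGLV1-44", "IGLV2-14"], ["IGLJ2", "IGLJ3"]),
            ):
                parts.append(
                    _one_repertoire(rng, config, 0.0, locus, None, vg, jg, None)
                )
            table = pd.concat(parts, ignore_index=True)
            table["sequence_id"] = [f"seq{i}" for i in range(len(table))]
            out[f"S{idx:03d}"] = table
    return out


# ----------------------------------------------------------------------
def generate_mac_readouts(
    truth: SyntheticTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """MAC-formation percentages with a severe-group mean shift.

    Baseline readouts are Normal(25, mac_sd) clipped to [0, 100]; the
    severe group is shifted up by ``mac_shift`` percentage points.
    Responder labels for a follow-up subset are drawn from a logistic link
    on the MAC level, P(responder) = expit((mac − 50) / 10).
    """
    rng = np.random.default_rng(config.seed + 3)
    groups = np.asarray(truth.sample_group)
    S = len(groups)
    severe = groups == truth.severe_group
    mac = rng.normal(25.0, config.mac_sd, S) + config.mac_shift * severe
    mac = np.clip(mac, 0.0, 100.0)
    p_resp = 1.0 / (1.0 + np.exp(-(mac - 50.0) / 10.0))
    in_followup = rng.random(S) < 0.25
    responder = rng.random(S) < p_resp
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(S)],
            "group": groups,
            "mac_percent": mac,
            "in_followup": in_followup,
            "responder": np.where(in_followup, responder, False),
        }
    ).set_index("sample_id")
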