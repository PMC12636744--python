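"""Alpha/beta diversity, ordination, PERMANOVA and intra/inter distances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, norm, rankdata

from .errors import ModelError, ValidationError
from .io import AbundanceTable


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValidationError("dissimilarity matrix diagonal must be 0")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValidationError("dissimilarities must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def richness(profile) -> int:
    """Count of strictly positive entries."""
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValidationError("profile must be non-negative")
    return int((p > 0).sum())


def _proportions(profile) -> np.ndarray:
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValidationError("profile must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValidationError("all-zero profile")
    return p / total


def shannon(profile, base: float | None = None) -> float:
    """Shannon entropy of the proportions; natural log by default."""
    p = _proportions(profile)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def inverse_simpson(profile) -> float:
    p = _proportions(profile)
    return float(1.0 / (p ** 2).sum())


def alpha_metrics(table: AbundanceTable, shannon_base: float | None = None
                  ) -> pd.DataFrame:
    rows = {}
    for s in table.sample_ids:
        prof = table.values.loc[s].to_numpy()
        rows[s] = {"richness": richness(prof),
                   "shannon": shannon(prof, base=shannon_base),
                   "inverse_simpson": inverse_simpson(prof)}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


# ---------------------------------------------------------------------------
# beta diversity and ordination
# ---------------------------------------------------------------------------


def bray_curtis(table: AbundanceTable) -> DissimilarityMatrix:
    v = table.values.to_numpy(dtype=float)
    zero = v.sum(axis=1) == 0
    if zero.any():
        bad = np.asarray(table.sample_ids)[zero][0]
        raise ValidationError(f"sample {bad!r} is all-zero")
    d = squareform(pdist(v, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(sample_ids=table.sample_ids,
                               values=np.clip(d, 0.0, 1.0))


def classical_mds(d: DissimilarityMatrix, k: int = 2) -> pd.DataFrame:
    """Torgerson double-centering MDS.

    Axes are ordered by eigenvalue, components with non-positive
    eigenvalues are dropped, and each axis is oriented so that its
    largest-magnitude loading is positive.
    """
    n = len(d.sample_ids)
    if k >= n:
        raise ValidationError(f"k={k} must be < number of samples ({n})")
    d2 = d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = min(k, int((evals > 1e-10).sum()))
    coords = evecs[:, :keep] * np.sqrt(evals[:keep])
    for a in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    return pd.DataFrame(coords, index=d.sample_ids,
                        columns=[f"MDS{i + 1}" for i in range(coords.shape[1])])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray,
              ss_total: float) -> float:
    n = len(labels)
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    a = len(groups)
    if ss_within == 0:
        return np.inf
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova(d: DissimilarityMatrix, labels, n_permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with seeded permutations.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations).
    """
    labels = np.asarray(pd.Series(labels))
    if len(labels) != len(d.sample_ids):
        raise ValidationError("labels length must match sample count")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")

    d2 = d.values ** 2
    n = len(labels)
    ss_total = d2.sum() / (2.0 * n)
    f_obs = _pseudo_f(d2, labels, groups, ss_total)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm, groups, ss_total) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# intra- vs inter-individual distances
# ---------------------------------------------------------------------------


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z tests on rank sums with a tie correction, BH-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = rankdata(pooled)
    n_tot = len(pooled)
    mean_ranks, sizes = {}, {}
    at = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[at:at + k].mean()
        sizes[g] = k
        at += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt((n_tot * (n_tot + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2 * norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_value": p})
    df = pd.DataFrame(rows)
    # Benjamini-Hochberg over the pairwise family
    m = len(df)
    order = np.argsort(df["p_value"].to_numpy(), kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_i, idx in zip(range(m, 0, -1), order[::-1]):
        prev = min(prev, df["p_value"].iloc[idx] * m / rank_i)
        q[idx] = prev
    df["q_value"] = q
    return df


def intra_inter_comparison(d: DissimilarityMatrix, subject_ids, cluster_labels,
                           subsample: int | None = None,
                           seed: int | None = None):
    """Classify sample pairs intra vs inter (split by cluster concordance),
    then Kruskal-Wallis across the groups with Dunn post-hoc tests.

    Returns (grouped distances, Kruskal-Wallis dict, Dunn DataFrame).
    """
    subjects = np.asarray(pd.Series(subject_ids))
    clusters = np.asarray(pd.Series(cluster_labels))
    n = len(d.sample_ids)
    if len(subjects) != n or len(clusters) != n:
        raise ValidationError("subject_ids / cluster_labels length mismatch")

    groups: dict[str, list[float]] = {
        "intra": [], "inter_same_cluster0": [], "inter_same_cluster1": [],
        "inter_discordant": []}
    for i in range(n):
        for j in range(i + 1, n):
            dist = d.values[i, j]
            if subjects[i] == subjects[j]:
                groups["intra"].append(dist)
            elif clusters[i] != clusters[j]:
                groups["inter_discordant"].append(dist)
            elif clusters[i] == 0:
                groups["inter_same_cluster0"].append(dist)
            else:
                groups["inter_same_cluster1"].append(dist)
    if not groups["intra"]:
        raise ModelError("no intra-individual pairs (need repeated subjects)")
    arrays = {g: np.asarray(v) for g, v in groups.items() if len(v) > 0}
    if subsample is not None:
        rng = np.random.default_rng(seed)
        arrays = {g: (v if len(v) <= subsample
                      else rng.choice(v, size=subsample, replace=False))
                  for g, v in arrays.items()}
    h, p = kruskal(*arrays.values())
    kw = {"H": float(h), "p_value": float(p), "groups": list(arrays)}
    dunn = _dunn_posthoc(arrays)
    return arrays, kw, dunn
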