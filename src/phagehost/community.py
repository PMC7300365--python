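"""Community-level diversity, ordination and core-set computations.

Alpha diversity (richness, Gini-Simpson, Shannon, Pielou's J evenness),
Bray-Curtis beta diversity with principal-coordinate ordination, a
distance-based permutation test for a grouping effect (pseudo-F, the
PERMANOVA statistic), exclusive set intersections across sampling
locations (UpSet semantics, the all-location intersection being the core
virome), and the prevalence/abundance rule for core features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "DiversityResult",
    "DistanceMatrix",
    "OrdinationResult",
    "SetIntersections",
    "alpha_diversity",
    "bray_curtis_matrix",
    "pcoa",
    "permutation_group_test",
    "location_taxon_sets",
    "set_intersections",
    "core_features",
]


@dataclass
class AbundanceTable:
    """Taxon-by-sample read counts with an optional sample -> location map."""

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray
    sample_to_location: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.taxa), len(self.samples)):
            raise ValueError("counts shape inconsistent with taxa/sample lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)

    def require_locations(self) -> dict[str, str]:
        if self.sample_to_location is None:
            raise ValueError("table has no sample -> location map")
        missing = [s for s in self.samples if s not in self.sample_to_location]
        if missing:
            raise ValueError(f"samples without a location label: {missing}")
        return self.sample_to_location


@dataclass
class DiversityResult:
    """Per-sample alpha diversity and column means.

    ``per_sample`` has one row per sample with columns richness,
    gini_simpson, shannon and pielou_j (NaN where undefined, i.e. a
    single-taxon sample).
    """

    per_sample: pd.DataFrame
    mean_richness: float
    mean_gini_simpson: float
    mean_shannon: float
    mean_pielou_j: float


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass
class SetIntersections:
    """Exclusive (UpSet-style) intersection sizes over location sets."""

    # sorted location-name tuple -> number of taxa present in exactly that set
    exclusive: dict[tuple[str, ...], int]
    core: list[str]  # taxa present in every location set


def alpha_diversity(table: AbundanceTable) -> DiversityResult:
    """Richness, Gini-Simpson (1 - sum p_i^2), Shannon H and Pielou's J
    (H / ln S) for every sample, plus means over samples.

    Pielou's J is undefined for a single-taxon sample and reported as NaN;
    an all-zero sample is an error.
    """
    rows = []
    for j, s in enumerate(table.samples):
        col = table.counts[:, j]
        total = col.sum()
        if total == 0:
            raise ValueError(f"sample {s!r} has zero total count")
        p = col[col > 0] / total
        S = int((col > 0).sum())
        gini = 1.0 - float((p**2).sum())
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / math.log(S) if S >= 2 else float("nan")
        rows.append((s, S, gini, shannon, pielou))
    df = pd.DataFrame(
        rows, columns=["sample", "richness", "gini_simpson", "shannon", "pielou_j"]
    ).set_index("sample")
    return DiversityResult(
        per_sample=df,
        mean_richness=float(df["richness"].mean()),
        mean_gini_simpson=float(df["gini_simpson"].mean()),
        mean_shannon=float(df["shannon"].mean()),
        mean_pielou_j=float(df["pielou_j"].mean(skipna=True)),
    )


def bray_curtis_matrix(table: AbundanceTable) -> tuple[DistanceMatrix, float]:
    """Bray-Curtis dissimilarity BC_jk = sum|x_j - x_k| / sum(x_j + x_k)
    on raw counts, plus the mean over off-diagonal pairs."""
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    totals = table.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero) >= 2:
        bad = [table.samples[i] for i in zero]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    condensed = pdist(table.counts.T.astype(float), metric="braycurtis")
    D = DistanceMatrix(sample_ids=list(table.samples), values=squareform(condensed))
    return D, float(condensed.mean())


def pcoa(D: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling (principal-coordinate analysis).

    The squared distance matrix is double-centred, eigendecomposed, and
    coordinates are eigenvectors scaled by the square root of their
    eigenvalue.  Only positive-eigenvalue axes are kept (the magnitude of
    any negative eigenvalues is logged); each axis's sign is fixed so its
    first nonzero loading is positive.
    """
    n = len(D.sample_ids)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.values**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0]) if n else 0.0)
    positive = eigvals > tol
    neg_mag = float(-eigvals[eigvals < -tol].sum())
    if neg_mag > 0:
        logger.info("dropped negative eigenvalues of total magnitude %.3g", neg_mag)
    eigvals_pos = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(eigvals_pos)
    if n_axes > len(eigvals_pos):
        logger.warning(
            "requested %d axes but only %d positive eigenvalues; truncating",
            n_axes, len(eigvals_pos),
        )
        n_axes = len(eigvals_pos)
    coords = coords[:, :n_axes]
    eigvals_pos = eigvals_pos[:n_axes]
    # sign convention: first nonzero loading of each axis positive
    for a in range(coords.shape[1]):
        nz = np.flatnonzero(np.abs(coords[:, a]) > 1e-12)
        if len(nz) and coords[nz[0], a] < 0:
            coords[:, a] = -coords[:, a]
    total = float(eigvals[eigvals > tol].sum())
    prop = eigvals_pos / total if total > 0 else np.zeros_like(eigvals_pos)
    return OrdinationResult(
        sample_ids=list(D.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals_pos,
        proportion_explained=prop,
    )


def _pseudo_f(D2: np.ndarray, labels: np.ndarray) -> float:
    """Distance-based pseudo-F from squared distances and group labels."""
    n = len(labels)
    groups = np.unique(labels)
    g = len(groups)
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for grp in groups:
        idx = np.flatnonzero(labels == grp)
        if len(idx) >= 2:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return float("inf") if ss_between > 0 else 0.0
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permutation_group_test(
    D: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for a grouping effect on a distance matrix.

    The statistic is the distance-based pseudo-F (as in PERMANOVA); the
    p-value is the add-one one-sided tail over seeded permutations of the
    group labels: p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    labels = np.array([groups[s] for s in D.sample_ids])
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups with samples")
    D2 = D.values**2
    f_obs = _pseudo_f(D2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(D2, perm) >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(f_obs), float(p)


def location_taxon_sets(table: AbundanceTable) -> dict[str, set[str]]:
    """Taxon set of each sampling location: the union over its samples of
    taxa with a nonzero count."""
    locations = table.require_locations()
    sets: dict[str, set[str]] = {}
    for j, s in enumerate(table.samples):
        loc = locations[s]
        present = {table.taxa[i] for i in np.flatnonzero(table.counts[:, j] > 0)}
        sets.setdefault(loc, set()).update(present)
    return sets


def set_intersections(sets: Mapping[str, set[str]]) -> SetIntersections:
    """Exclusive intersection sizes for every non-empty location combination.

    A taxon counts toward exactly one combination: the set of locations it
    occurs in (UpSet semantics).  The all-location combination is the plain
    intersection — the core; singleton combinations count location-unique
    taxa.  Sizes over all combinations partition the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 location sets")
    locs = sorted(sets)
    membership: dict[str, tuple[str, ...]] = {}
    for taxon in set().union(*sets.values()):
        membership[taxon] = tuple(sorted(l for l in locs if taxon in sets[l]))
    exclusive = {
        tuple(sorted(combo)): 0
        for r in range(1, len(locs) + 1)
        for combo in combinations(locs, r)
    }
    for combo in membership.values():
        exclusive[combo] += 1
    core = sorted(t for t, combo in membership.items() if len(combo) == len(locs))
    return SetIntersections(exclusive=exclusive, core=core)


def core_features(
    table: AbundanceTable,
    min_rel_abund: float = 0.0025,
    min_prevalence: float = 0.75,
) -> list[str]:
    """Features whose relative abundance exceeds ``min_rel_abund``
    (strictly) in at least ``min_prevalence`` of the samples (prevalence
    count rounded up)."""
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = [table.samples[j] for j in np.flatnonzero(totals == 0)]
        raise ValueError(f"samples with zero total count: {bad}")
    rel = table.counts / totals
    needed = math.ceil(min_prevalence * len(table.samples))
    hits = (rel > min_rel_abund).sum(axis=1)
    return [t for t, h in zip(table.taxa, hits) if h >= needed]
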