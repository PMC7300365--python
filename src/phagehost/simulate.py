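"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Every generator is deterministic for a fixed seed and records its ground
truth, so each downstream stage can be tested for exact parameter recovery
in the noiseless limit: contigs with known host genera, CRISPR spacers that
are mutated excisions of those contigs, bipartite matrices with planted
nested or modular structure, and multi-site abundance tables with a planted
core set plus site-specific taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import SequenceRecord
from .network import BipartiteMatrix

__all__ = [
    "SyntheticTruth",
    "NYC_LOCATIONS",
    "simulate_contigs",
    "simulate_crispr_spacers",
    "simulate_nested_matrix",
    "simulate_modular_matrix",
    "simulate_abundance",
    "child_seeds",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# The 16-sample / 8-location-set design of the NYC sewage survey: each
# sampling location is one set; several sets pool more than one sample.
NYC_LOCATIONS: dict[str, str] = {
    "MN_1": "Manhattan",
    "BQM_1": "Brooklyn/Queens/Manhattan",
    "BQ_1": "Brooklyn/Queens",
    "BX_1": "Bronx",
    "BXM_1": "Bronx/Manhattan",
    "SI_1": "Staten Island",
    "SI_2": "Staten Island",
    "BK_1": "Brooklyn",
    "BK_2": "Brooklyn",
    "BK_3": "Brooklyn",
    "BK_4": "Brooklyn",
    "Q_1": "Queens",
    "Q_2": "Queens",
    "Q_3": "Queens",
    "Q_4": "Queens",
    "Q_5": "Queens",
}


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for recovery tests."""

    contig_to_genus: dict[str, str] = field(default_factory=dict)
    # spacer id -> (source contig, 0-based position, strand, n substitutions)
    spacer_to_contig: dict[str, tuple[str, int, str, int]] = field(default_factory=dict)
    # every spacer's attributed source genus (decoys included)
    spacer_to_genus: dict[str, str] = field(default_factory=dict)
    planted_partition: Optional[dict[str, int]] = None
    planted_nested_order: Optional[tuple[list[int], list[int]]] = None


def child_seeds(root_seed: int, n: int) -> list[int]:
    """Fan a root seed out to ``n`` independent child seeds (< 2**31)."""
    return [int(s) for s in np.random.SeedSequence(root_seed).generate_state(n) % (2**31)]


def simulate_contigs(
    n: int,
    len_min: int = 1000,
    len_max: int = 5000,
    gc: float = 0.5,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Random phage contigs with i.i.d. bases at the given GC fraction.

    Lengths are uniform on [len_min, len_max]; reproducible for a fixed
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= len_min <= len_max:
        raise ValueError("need 1 <= len_min <= len_max")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    width = max(4, len(str(n)))
    for i in range(n):
        length = int(rng.integers(len_min, len_max + 1))
        seq = bytes(rng.choice(_BASES, size=length, p=p)).decode()
        records.append(SequenceRecord(id=f"contig_{i:0{width}d}", seq=seq))
    return records


_OTHER = {
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_crispr_spacers(
    contigs: Sequence[SequenceRecord],
    n_per_genus: int,
    genera: Sequence[str],
    spacer_len: int = 32,
    mutation_rate: float = 0.0,
    decoy_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Spacers excised from contigs by their (synthetic) host bacteria.

    Each genus owns a disjoint subset of the contigs as "its" infecting
    phages; a spacer is a ``spacer_len`` substring of one of them, on a
    uniform strand, with i.i.d. substitutions at ``mutation_rate``.  A
    ``decoy_fraction`` of all spacers are instead pure random sequences
    attributed to a random genus with no source contig recorded.
    """
    if not contigs or not genera:
        raise ValueError("need at least one contig and one genus")
    if len(contigs) < len(genera):
        raise ValueError("need at least one contig per genus")
    shortest = min(len(c) for c in contigs)
    if spacer_len > shortest:
        raise ValueError(
            f"spacer_len {spacer_len} exceeds shortest contig length {shortest}"
        )
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    # disjoint contiguous chunks of the contig list, one per genus
    bounds = np.linspace(0, len(contigs), len(genera) + 1).astype(int)
    genus_contigs = {
        g: list(contigs[bounds[gi]:bounds[gi + 1]]) for gi, g in enumerate(genera)
    }
    for g, owned in genus_contigs.items():
        for c in owned:
            truth.contig_to_genus[c.id] = g
    total = n_per_genus * len(genera)
    n_decoy = int(round(decoy_fraction * total))
    decoy_at = set(rng.choice(total, size=n_decoy, replace=False).tolist())
    assigned_genus = [g for g in genera for _ in range(n_per_genus)]
    spacers: list[SequenceRecord] = []
    for idx, g in enumerate(assigned_genus):
        sid = f"spacer_{idx + 1:05d}"
        truth.spacer_to_genus[sid] = g
        if idx in decoy_at:
            # decoy: random sequence with no source contig in the set
            seq = bytes(rng.choice(_BASES, size=spacer_len)).decode()
            spacers.append(SequenceRecord(id=sid, seq=seq))
            continue
        owned = genus_contigs[g]
        contig = owned[int(rng.integers(len(owned)))]
        pos = int(rng.integers(0, len(contig) - spacer_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = contig.seq[pos:pos + spacer_len]
        if strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        n_mut = 0
        if mutation_rate > 0:
            chars = list(seq)
            hits = np.flatnonzero(rng.random(spacer_len) < mutation_rate)
            for h in hits:
                chars[h] = _OTHER[chars[h]][int(rng.integers(3))]
            n_mut = len(hits)
            seq = "".join(chars)
        spacers.append(SequenceRecord(id=sid, seq=seq))
        truth.spacer_to_contig[sid] = (contig.id, pos, strand, n_mut)
    return spacers, truth


def _nested_thresholds(R: int, C: int, m_target: int) -> np.ndarray:
    """Non-increasing row thresholds t with t[0] = C, t[-1] >= 1 and
    sum(t) = m_target; shaped like the isocline of perfect nestedness at
    this fill (the staircase a maximally nested community would show)."""
    from .network import _isocline_exponent

    p = _isocline_exponent(m_target / (R * C))
    y = (np.arange(R) + 0.5) / R
    x = (np.arange(C) + 0.5) / C
    t = (x[None, :] ** p + y[:, None] ** p < 1.0).sum(axis=1)
    t = np.minimum.accumulate(np.clip(t, 1, C))
    t[0] = C
    # walk the total onto the target while preserving monotonicity
    guard = 0
    while t.sum() != m_target:
        guard += 1
        if guard > 10 * R * C:
            raise RuntimeError("threshold adjustment failed to converge")
        diff = m_target - t.sum()
        if diff > 0:
            for i in range(R - 1, 0, -1):
                if t[i] < t[i - 1] and t[i] < C:
                    t[i] += 1
                    break
            else:
                raise RuntimeError("cannot raise any threshold")
        else:
            for i in range(R - 1, 0, -1):
                if t[i] > 1 and (i == R - 1 or t[i] > t[i + 1]):
                    t[i] -= 1
                    break
            else:
                raise RuntimeError("cannot lower any threshold")
    return t


def simulate_nested_matrix(
    R: int,
    C: int,
    fill: float = 0.3,
    noise: float = 0.0,
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[BipartiteMatrix, SyntheticTruth]:
    """Perfectly nested base matrix with independent cell-flip noise.

    The base matrix is a staircase: cell (i, j) = 1 iff j < t_i for a
    non-increasing threshold vector realising the target fill.  Each cell
    is then flipped with probability ``noise``; draws leaving an empty row
    or column are regenerated (bounded retries).
    """
    if R < 2 or C < 2:
        raise ValueError("R and C must be >= 2")
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    m_target = int(round(fill * R * C))
    if not (C + (R - 1) <= m_target <= R * C):
        raise ValueError(
            f"fill {fill} infeasible for perfect nesting at ({R}, {C}): "
            f"need edge count in [{C + R - 1}, {R * C}], got {m_target}"
        )
    t = _nested_thresholds(R, C, m_target)
    base = (np.arange(C)[None, :] < t[:, None]).astype(np.int8)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        if noise > 0:
            flips = rng.random((R, C)) < noise
            A = np.where(flips, 1 - base, base).astype(np.int8)
        else:
            A = base.copy()
        if A.sum(axis=1).all() and A.sum(axis=0).all():
            break
    else:
        raise RuntimeError(
            f"no noisy matrix without empty margins in {max_retries} tries"
        )
    M = BipartiteMatrix(
        A=A,
        row_labels=[f"genus_{i:03d}" for i in range(R)],
        col_labels=[f"VC_{j:03d}" for j in range(C)],
    )
    truth = SyntheticTruth(
        planted_nested_order=(list(range(R)), list(range(C)))
    )
    return M, truth


def simulate_modular_matrix(
    module_sizes: Sequence[tuple[int, int]],
    p_within: float,
    p_between: float,
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[BipartiteMatrix, SyntheticTruth]:
    """Planted-block bipartite matrix.

    Cells inside a planted (rows x cols) block are Bernoulli(p_within),
    cells outside are Bernoulli(p_between); the planted partition is
    recorded in the truth.  Draws with empty margins are regenerated.
    """
    if not module_sizes or any(r < 1 or c < 1 for r, c in module_sizes):
        raise ValueError("module sizes must be positive (rows, cols) pairs")
    if not 0.0 <= p_between < p_within <= 1.0:
        raise ValueError("need 0 <= p_between < p_within <= 1")
    R = sum(r for r, _ in module_sizes)
    C = sum(c for _, c in module_sizes)
    row_mod = np.concatenate(
        [np.full(r, t) for t, (r, _) in enumerate(module_sizes)]
    )
    col_mod = np.concatenate(
        [np.full(c, t) for t, (_, c) in enumerate(module_sizes)]
    )
    within = row_mod[:, None] == col_mod[None, :]
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        P = np.where(within, p_within, p_between)
        A = (rng.random((R, C)) < P).astype(np.int8)
        if A.sum(axis=1).all() and A.sum(axis=0).all():
            break
    else:
        raise RuntimeError(
            f"no modular matrix without empty margins in {max_retries} tries"
        )
    row_labels = [f"genus_{i:03d}" for i in range(R)]
    col_labels = [f"VC_{j:03d}" for j in range(C)]
    partition = {lab: int(t) for lab, t in zip(row_labels, row_mod)}
    partition.update({lab: int(t) for lab, t in zip(col_labels, col_mod)})
    M = BipartiteMatrix(A=A, row_labels=row_labels, col_labels=col_labels)
    return M, SyntheticTruth(planted_partition=partition)


def simulate_abundance(
    n_samples: int = 16,
    n_taxa: int = 200,
    n_core: int = 38,
    depth: int = 50000,
    dispersion: float = 2.0,
    core_boost: float = 3.0,
    seed: int = 0,
    locations: Optional[Mapping[str, str]] = None,
):
    """Multi-site taxon count table with a planted core set.

    Per-taxon intensities are log-normal with sigma = ``dispersion``
    (uneven communities dominated by a few taxa); each sample draws
    ``depth`` reads multinomially.  The first ``n_core`` taxa (ids
    ``taxon_core_*``) are present in every sample — one read is reserved
    for each before the multinomial draw, so column sums still equal
    ``depth`` — and their log-mean intensity is raised by ``core_boost``,
    making the community everywhere dominated by the same ubiquitous
    taxa (compositionally similar samples despite site-specific tails).
    Every other taxon is masked to a proper subset of the sampling
    locations, making it site-specific.
    """
    from .community import AbundanceTable

    if n_samples < 1 or n_taxa < 1:
        raise ValueError("n_samples and n_taxa must be >= 1")
    if not 0 <= n_core <= n_taxa:
        raise ValueError("need 0 <= n_core <= n_taxa")
    if depth < n_core:
        raise ValueError("depth must be >= n_core")
    if locations is None:
        samples = [f"S{i + 1:02d}" for i in range(n_samples)]
        locations = {s: "site_1" for s in samples}
    else:
        locations = dict(locations)
        samples = list(locations)
        if len(samples) != n_samples:
            raise ValueError("locations must map exactly n_samples samples")
    loc_names = sorted(set(locations.values()))
    rng = np.random.default_rng(seed)
    taxa = [f"taxon_core_{i + 1:03d}" for i in range(n_core)]
    taxa += [f"taxon_acc_{i + 1:03d}" for i in range(n_taxa - n_core)]
    mu = np.where(np.arange(n_taxa) < n_core, core_boost, 0.0)
    intensity = rng.lognormal(mean=mu, sigma=dispersion)
    # site-specific taxa: each accessory taxon lives in a proper subset
    mask = np.ones((n_taxa, n_samples), dtype=bool)
    if len(loc_names) >= 2:
        for i in range(n_core, n_taxa):
            n_in = int(rng.integers(1, len(loc_names)))
            chosen = set(rng.choice(loc_names, size=n_in, replace=False))
            for j, s in enumerate(samples):
                mask[i, j] = locations[s] in chosen
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        lam = np.where(mask[:, j], intensity, 0.0)
        if n_core:
            counts[:n_core, j] += 1
        p = lam / lam.sum()
        counts[:, j] += rng.multinomial(depth - n_core, p)
    return AbundanceTable(
        taxa=taxa, samples=samples, counts=counts, sample_to_location=dict(locations)
    )
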