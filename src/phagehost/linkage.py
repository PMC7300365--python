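"""Phage-host prediction from CRISPR spacers.

CRISPR spacers are short sequences a bacterium excised from a phage that
once infected it, so a spacer aligning to a viral contig links that contig
to the spacer's source genus.  The stages here: full-length ungapped
spacer-to-contig matching with the <2 bp mismatch retention rule, greedy
CD-HIT-style sequence clustering (for the spacer/repeat cluster-size
statistics), greedy best-match host assignment, and construction of the
binary genus x virus-cluster interaction matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import SequenceRecord
from .network import BipartiteMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SpacerMatch",
    "HostAssignment",
    "SequenceCluster",
    "ScoreParams",
    "find_spacer_matches",
    "cluster_sequences",
    "assign_hosts",
    "build_interaction_matrix",
]


@dataclass(frozen=True)
class ScoreParams:
    """Ungapped DNA scoring constants (conventional BLASTN-like values).

    Only the rank order matters for the greedy host-assignment rule; with
    full-length ungapped matches that order reduces to fewest mismatches
    first for any sane choice of constants.
    """

    reward: float = 1.0
    penalty: float = 3.0
    lam: float = 1.28
    k: float = 0.46


@dataclass(frozen=True)
class SpacerMatch:
    """One full-length ungapped placement of a spacer on a contig.

    ``start`` is a 0-based offset on the contig forward strand; strand
    ``-`` means the reverse complement of the spacer matched there.
    Gaps are always 0 (indels are not modelled).
    """

    spacer_id: str
    contig_id: str
    start: int
    strand: str
    align_length: int
    mismatches: int
    gaps: int
    percent_identity: float
    raw_score: float
    bit_score: float
    e_value: float


@dataclass(frozen=True)
class HostAssignment:
    contig_id: str
    host_genus: str
    best_match: SpacerMatch
    n_supporting_matches: int


@dataclass
class SequenceCluster:
    representative_id: str
    member_ids: list[str]
    identity_threshold: float

    @property
    def size(self) -> int:
        return len(self.member_ids)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _window_mismatches(contig_bytes: np.ndarray, query: str) -> np.ndarray:
    """Hamming mismatches of ``query`` against every window of the contig.

    N (in either sequence) mismatches everything, including another N.
    """
    L = len(query)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(contig_bytes, L)
    eq = windows == q
    n_byte = ord("N")
    valid = (windows != n_byte) & (q != n_byte)
    return L - (eq & valid).sum(axis=1)


def find_spacer_matches(
    spacer: SequenceRecord,
    contigs: Sequence[SequenceRecord],
    max_mismatch: int = 1,
    score: ScoreParams = ScoreParams(),
) -> list[SpacerMatch]:
    """All full-length ungapped placements of a spacer with few mismatches.

    Both strands are searched; placements with Hamming mismatches up to
    ``max_mismatch`` (default 1, the "<2 bp" retention rule) are reported,
    sorted by (contig_id, start, strand).  The E value uses the total
    number of contig bases searched as the database size.
    """
    if len(spacer) < 8:
        raise ValueError(f"spacer {spacer.id!r} shorter than 8 bp")
    if not contigs:
        raise ValueError("no contigs to search")
    L = len(spacer)
    total_bases = sum(len(c) for c in contigs)
    queries = {"+": spacer.seq, "-": _revcomp(spacer.seq)}
    matches: list[SpacerMatch] = []
    for contig in contigs:
        if len(contig) < L:
            continue
        cbytes = np.frombuffer(contig.seq.encode(), dtype=np.uint8)
        for strand, query in queries.items():
            mms = _window_mismatches(cbytes, query)
            for start in np.flatnonzero(mms <= max_mismatch):
                mm = int(mms[start])
                n_match = L - mm
                raw = score.reward * n_match - score.penalty * mm
                bits = (score.lam * raw - math.log(score.k)) / math.log(2.0)
                evalue = score.k * L * total_bases * math.exp(-score.lam * raw)
                matches.append(
                    SpacerMatch(
                        spacer_id=spacer.id,
                        contig_id=contig.id,
                        start=int(start),
                        strand=strand,
                        align_length=L,
                        mismatches=mm,
                        gaps=0,
                        percent_identity=100.0 * n_match / L,
                        raw_score=raw,
                        bit_score=bits,
                        e_value=evalue,
                    )
                )
    matches.sort(key=lambda m: (m.contig_id, m.start, m.strand))
    return matches


def _best_ungapped_identity(short: str, long: str) -> float:
    """Identical positions in the best ungapped placement of the shorter
    sequence within the longer, divided by the shorter length."""
    ls = len(short)
    sb = np.frombuffer(short.encode(), dtype=np.uint8)
    lb = np.frombuffer(long.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(lb, ls)
    return float((windows == sb).sum(axis=1).max()) / ls


def cluster_sequences(
    seqs: Sequence[SequenceRecord], identity: float = 0.90
) -> tuple[list[SequenceCluster], float]:
    """Greedy incremental clustering in the style of CD-HIT.

    Sequences are taken longest-first (ties by id); each joins the first
    existing cluster whose representative matches at or above the identity
    threshold, otherwise it founds a new cluster.  The representative is
    always the longest (first) member.  Returns the clusters and the mean
    cluster size; empty input yields an empty result.
    """
    if not 0.5 < identity <= 1.0:
        raise ValueError("identity must be in (0.5, 1.0]")
    if not seqs:
        return [], float("nan")
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    clusters: list[SequenceCluster] = []
    reps: list[SequenceRecord] = []
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            if _best_ungapped_identity(rec.seq, rep.seq) >= identity:
                cluster.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(
                SequenceCluster(
                    representative_id=rec.id,
                    member_ids=[rec.id],
                    identity_threshold=identity,
                )
            )
            reps.append(rec)
    mean_size = sum(c.size for c in clusters) / len(clusters)
    return clusters, mean_size


def assign_hosts(
    matches: Sequence[SpacerMatch], spacer_to_genus: Mapping[str, str]
) -> list[HostAssignment]:
    """Greedy host call per contig from its retained spacer matches.

    Matches are ranked by highest bit score, lowest E value, highest
    percent identity, longest alignment, fewest mismatches+gaps; remaining
    ties break deterministically by genus name then spacer id.  The top
    match's source genus becomes the contig's predicted host.  Matches
    from spacers with no known source genus are dropped (count logged).
    Order of the input never affects the result.
    """
    known = [m for m in matches if m.spacer_id in spacer_to_genus]
    n_dropped = len(matches) - len(known)
    if n_dropped:
        logger.info("dropped %d matches from spacers with unknown genus", n_dropped)
    by_contig: dict[str, list[SpacerMatch]] = {}
    for m in known:
        by_contig.setdefault(m.contig_id, []).append(m)
    assignments = []
    for contig_id in sorted(by_contig):
        ranked = sorted(
            by_contig[contig_id],
            key=lambda m: (
                -m.bit_score,
                m.e_value,
                -m.percent_identity,
                -m.align_length,
                m.mismatches + m.gaps,
                spacer_to_genus[m.spacer_id],
                m.spacer_id,
            ),
        )
        best = ranked[0]
        genus = spacer_to_genus[best.spacer_id]
        supporting = sum(1 for m in ranked if spacer_to_genus[m.spacer_id] == genus)
        assignments.append(
            HostAssignment(
                contig_id=contig_id,
                host_genus=genus,
                best_match=best,
                n_supporting_matches=supporting,
            )
        )
    return assignments


def build_interaction_matrix(
    assignments: Sequence[HostAssignment], contig_to_vc: Mapping[str, str]
) -> BipartiteMatrix:
    """Binary genus x virus-cluster matrix from per-contig host calls.

    cell(genus, VC) = 1 iff at least one contig of that VC was assigned
    the genus.  Contigs missing from the VC mapping are dropped with a
    logged count; labels are sorted ascending and all-zero margins cannot
    occur by construction.
    """
    if not assignments:
        raise ValueError("no interactions: empty assignment list")
    edges = set()
    n_missing = 0
    for a in assignments:
        vc = contig_to_vc.get(a.contig_id)
        if vc is None:
            n_missing += 1
            continue
        edges.add((a.host_genus, vc))
    if n_missing:
        logger.info("dropped %d assignments without a VC mapping", n_missing)
    if not edges:
        raise ValueError("no interactions after VC mapping")
    genera = sorted({g for g, _ in edges})
    vcs = sorted({v for _, v in edges})
    A = np.zeros((len(genera), len(vcs)), dtype=np.int8)
    gi = {g: i for i, g in enumerate(genera)}
    vj = {v: j for j, v in enumerate(vcs)}
    for g, v in edges:
        A[gi[g], vj[v]] = 1
    return BipartiteMatrix(A=A, row_labels=genera, col_labels=vcs)
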