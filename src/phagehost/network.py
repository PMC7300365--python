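"""Bipartite infection-network statistics.

The phage-host interaction structure is summarised as a binary matrix with
bacterial genera as rows and virus clusters (VCs) as columns.  This module
computes the two classic nestedness measures — the nestedness temperature
(NTC) and the overlap/decreasing-fill metric (NODF) — Barber's bipartite
modularity Qb with an LP-BRIM optimiser (label propagation followed by
bipartite recursively induced module refinement), and significance against
the equiprobable null model (every cell an independent Bernoulli draw at
the observed fill).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteMatrix",
    "NestednessResult",
    "ModularityResult",
    "NullTestResult",
    "pack_matrix",
    "nodf",
    "ntc_temperature",
    "nestedness",
    "barber_qb",
    "lp_brim",
    "null_test",
]

# Maximum expected unexpectedness of a random matrix; normalises the mean
# squared isocline distance onto the 0-100 temperature scale.
U_MAX = 0.04145


@dataclass
class BipartiteMatrix:
    """Binary genus x virus-cluster interaction matrix with labels.

    ``A`` is a 0/1 matrix of shape (R, C); ``row_labels`` are bacterial
    genera, ``col_labels`` are virus-cluster ids.  Degree vectors ``k``
    (rows), ``d`` (columns), edge count ``m`` and ``fill`` are derived.
    """

    A: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.ndim != 2:
            raise ValueError("adjacency must be 2-dimensional")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("adjacency cells must be 0 or 1")
        self.A = self.A.astype(np.int8)
        r, c = self.A.shape
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lists inconsistent with matrix shape")
        if len(set(self.row_labels)) != r:
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != c:
            raise ValueError("duplicate column labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    @property
    def k(self) -> np.ndarray:
        """Row degrees k_i = sum_j A_ij."""
        return self.A.sum(axis=1)

    @property
    def d(self) -> np.ndarray:
        """Column degrees d_j = sum_i A_ij."""
        return self.A.sum(axis=0)

    @property
    def m(self) -> int:
        return int(self.A.sum())

    @property
    def fill(self) -> float:
        r, c = self.A.shape
        return self.m / (r * c)

    def permuted(self, row_order: Sequence[int], col_order: Sequence[int]) -> "BipartiteMatrix":
        ro = list(row_order)
        co = list(col_order)
        return BipartiteMatrix(
            A=self.A[np.ix_(ro, co)],
            row_labels=[self.row_labels[i] for i in ro],
            col_labels=[self.col_labels[j] for j in co],
        )

    def check_for_statistics(self) -> None:
        r, c = self.A.shape
        if r < 2 or c < 2:
            raise ValueError(f"matrix {r}x{c} too small for network statistics")
        if (self.k == 0).any():
            empty = [self.row_labels[i] for i in np.flatnonzero(self.k == 0)]
            raise ValueError(f"empty rows not allowed: {empty}")
        if (self.d == 0).any():
            empty = [self.col_labels[j] for j in np.flatnonzero(self.d == 0)]
            raise ValueError(f"empty columns not allowed: {empty}")


@dataclass
class NestednessResult:
    T: float
    n_ntc: float
    nodf: float
    nodf_rows: float
    nodf_cols: float
    row_order: list[int]
    col_order: list[int]


@dataclass
class ModularityResult:
    row_modules: dict[str, int]
    col_modules: dict[str, int]
    qb: float
    n_modules: int
    n_restarts: int
    best_restart_seed: int


@dataclass
class NullTestResult:
    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    z: float | None
    p_empirical: float
    n_iterations: int
    model_name: str
    seed: int


# ---------------------------------------------------------------------------
# nestedness temperature


def _isocline_exponent(phi: float) -> float:
    """Exponent p of the isocline x**p + y**p = 1 whose upper-left area
    equals the fill phi; the area is Gamma(1+1/p)^2 / Gamma(1+2/p),
    monotone increasing in p."""
    from scipy.optimize import brentq
    from scipy.special import gammaln

    def area(p: float) -> float:
        return float(np.exp(2 * gammaln(1 + 1 / p) - gammaln(1 + 2 / p)))

    return brentq(lambda p: area(p) - phi, 1e-3, 1e3, xtol=1e-10)


def _temperature_of(A: np.ndarray) -> float:
    """Temperature of the matrix in its *current* row/column order.

    Each cell maps to the unit square (x rightwards over columns, y
    downwards over rows, so the packed matrix's densest corner is the
    origin).  The isocline of perfect nestedness is the superellipse
    x**p + y**p = 1 with p chosen so the area on its origin side equals
    the fill; it meets the axes at the far end of the first row and first
    column, matching staircase matrices with full first margins.
    Presences outside the isocline and absences inside it are unexpected
    and contribute their squared distance from the isocline, measured
    along the cell's main diagonal and normalised by that diagonal's
    length within the square.
    """
    A = np.asarray(A)
    r, c = A.shape
    phi = A.sum() / (r * c)
    if phi == 0.0 or phi == 1.0:
        return 0.0
    p = _isocline_exponent(phi)
    x = (np.arange(c) + 0.5) / c
    y = (np.arange(r) + 0.5) / r
    X, Y = np.meshgrid(x, y)
    inside = X**p + Y**p < 1.0  # presence expected
    unexpected = np.where(inside, A == 0, A == 1)
    # diagonal through each cell in direction (1, 1): t in [t_lo, t_hi]
    t_lo = -np.minimum(X, Y)
    t_hi = np.minimum(1 - X, 1 - Y)
    # the crossing g(t) = (x+t)^p + (y+t)^p = 1 is unique: bisection
    lo, hi = t_lo.copy(), t_hi.copy()
    for _ in range(60):
        mid = (lo + hi) / 2
        g = (X + mid) ** p + (Y + mid) ** p
        lo = np.where(g < 1.0, mid, lo)
        hi = np.where(g < 1.0, hi, mid)
    t_star = (lo + hi) / 2
    d_frac = np.abs(t_star) / (t_hi - t_lo)
    u = np.where(unexpected, d_frac**2, 0.0)
    U = float(u.sum()) / (r * c)
    return float(np.clip(100.0 * U / U_MAX, 0.0, 100.0))


def pack_matrix(M: BipartiteMatrix, max_sweeps: int = 20):
    """Sort the matrix toward minimal temperature ("maximally packed").

    Rows and columns are first sorted by decreasing degree (ties by
    increasing original index), then a deterministic hill-climb accepts any
    adjacent row or column transposition that lowers the temperature.

    Returns ``(packed, row_order, col_order)`` where the orders index into
    the original matrix.
    """
    M.check_for_statistics()
    row_order, col_order = _pack_orders(M.A, max_sweeps)
    return M.permuted(row_order, col_order), row_order, col_order


def _pack_orders(A: np.ndarray, max_sweeps: int = 20) -> tuple[list[int], list[int]]:
    """Row/column orders of the packed matrix (see :func:`pack_matrix`)."""
    r, c = A.shape
    row_order = list(np.lexsort((np.arange(r), -A.sum(axis=1))))
    col_order = list(np.lexsort((np.arange(c), -A.sum(axis=0))))
    A = A[np.ix_(row_order, col_order)]
    t = _temperature_of(A)
    for _ in range(max_sweeps):
        improved = False
        for i in range(r - 1):
            A[[i, i + 1]] = A[[i + 1, i]]
            t_new = _temperature_of(A)
            if t_new < t - 1e-12:
                t = t_new
                row_order[i], row_order[i + 1] = row_order[i + 1], row_order[i]
                improved = True
            else:
                A[[i, i + 1]] = A[[i + 1, i]]
        for j in range(c - 1):
            A[:, [j, j + 1]] = A[:, [j + 1, j]]
            t_new = _temperature_of(A)
            if t_new < t - 1e-12:
                t = t_new
                col_order[j], col_order[j + 1] = col_order[j + 1], col_order[j]
                improved = True
            else:
                A[:, [j, j + 1]] = A[:, [j + 1, j]]
        if not improved:
            break
    return row_order, col_order


def ntc_temperature(M: BipartiteMatrix) -> tuple[float, float]:
    """Nestedness temperature T (0-100) and N_NTC = (100 - T)/100.

    Computed on the packed matrix; T = 0 for completely full or empty
    matrices, where no cell can be unexpected.
    """
    M.check_for_statistics()
    T = _packed_temperature(M.A)
    return T, (100.0 - T) / 100.0


def _packed_temperature(A: np.ndarray) -> float:
    ro, co = _pack_orders(A)
    return _temperature_of(A[np.ix_(ro, co)])


# ---------------------------------------------------------------------------
# NODF


def _nodf_axis(A: np.ndarray) -> tuple[float, float]:
    """Sum of pair scores and pair count along the row axis of ``A``."""
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=1)
    overlap = A @ A.T
    n = A.shape[0]
    decreasing = (k[:, None] > k[None, :]) & (k[None, :] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(decreasing, 100.0 * overlap / k[None, :], 0.0)
    return float(scores.sum()), n * (n - 1) / 2


def nodf(M: BipartiteMatrix, percent: bool = False) -> tuple[float, float, float]:
    """NODF nestedness: (overall, rows, cols), 0-1 scale by default.

    For each unordered pair of rows whose degrees strictly decrease, the
    pair score is the overlap of the sparser row with the denser one,
    relative to the sparser degree; equal-degree pairs score zero.  Same
    over columns.  The overall value is the grand mean over all
    C(R,2) + C(C,2) pairs.  Order-invariant.
    """
    M.check_for_statistics()
    row_total, row_pairs = _nodf_axis(M.A)
    col_total, col_pairs = _nodf_axis(M.A.T)
    scale = 1.0 if percent else 0.01
    return (
        (row_total + col_total) / (row_pairs + col_pairs) * scale,
        row_total / row_pairs * scale,
        col_total / col_pairs * scale,
    )


def _nodf_value(A: np.ndarray) -> float:
    """NODF (0-1) straight from an array; zero-degree margins score 0."""
    row_total, row_pairs = _nodf_axis(A)
    col_total, col_pairs = _nodf_axis(A.T)
    return (row_total + col_total) / (row_pairs + col_pairs) / 100.0


def nestedness(M: BipartiteMatrix) -> NestednessResult:
    """Full nestedness summary: temperature, N_NTC, NODF and packing."""
    M.check_for_statistics()
    packed, row_order, col_order = pack_matrix(M)
    T = _temperature_of(packed.A)
    overall, rows, cols = nodf(M)
    return NestednessResult(
        T=T,
        n_ntc=(100.0 - T) / 100.0,
        nodf=overall,
        nodf_rows=rows,
        nodf_cols=cols,
        row_order=row_order,
        col_order=col_order,
    )


# ---------------------------------------------------------------------------
# modularity


def _qb_from_arrays(A: np.ndarray, g: np.ndarray, h: np.ndarray) -> float:
    k = A.sum(axis=1, dtype=float)
    d = A.sum(axis=0, dtype=float)
    m = float(A.sum())
    B = A - np.outer(k, d) / m
    delta = g[:, None] == h[None, :]
    return float((B * delta).sum() / m)


def barber_qb(
    M: BipartiteMatrix,
    row_modules: Mapping[str, int],
    col_modules: Mapping[str, int],
) -> float:
    """Barber's bipartite modularity of a given partition.

    Qb = (1/m) sum_ij (A_ij - k_i d_j / m) [g_i = h_j].  The all-in-one
    partition scores exactly zero.
    """
    M.check_for_statistics()
    missing = [x for x in M.row_labels if x not in row_modules]
    missing += [x for x in M.col_labels if x not in col_modules]
    if missing:
        raise ValueError(f"unlabeled nodes: {missing[:5]}")
    g = np.array([row_modules[x] for x in M.row_labels])
    h = np.array([col_modules[x] for x in M.col_labels])
    return _qb_from_arrays(M.A, g, h)


def _label_propagation(A: np.ndarray, rng: np.random.Generator, max_iter: int):
    """Initial modules by label propagation from unique column labels."""
    r, c = A.shape
    g = np.full(r, -1)  # row labels, unset
    h = np.arange(c)  # one unique label per column
    nodes = [("r", i) for i in range(r)] + [("c", j) for j in range(c)]
    for _ in range(max_iter):
        changed = False
        order = rng.permutation(len(nodes))
        for idx in order:
            side, i = nodes[idx]
            if side == "r":
                weights = np.bincount(h, weights=A[i, :], minlength=c)
                # ties broken uniformly at random (seeded): deterministic
                # smallest-label ties collapse dense matrices into a single
                # module, which BRIM cannot split afterwards
                cand = np.flatnonzero(weights == weights.max())
                if g[i] not in cand:
                    g[i] = int(cand[rng.integers(len(cand))])
                    changed = True
            else:
                labelled = g >= 0
                if not labelled.any() or A[labelled, i].sum() == 0:
                    continue
                weights = np.bincount(
                    g[labelled], weights=A[labelled, i], minlength=c
                )
                cand = np.flatnonzero(weights == weights.max())
                if h[i] not in cand:
                    h[i] = int(cand[rng.integers(len(cand))])
                    changed = True
        if not changed:
            break
    return g, h


def _brim_refine(A: np.ndarray, g: np.ndarray, h: np.ndarray, max_iter: int):
    """Alternately reassign rows then columns to their best module until
    Qb stops increasing."""
    k = A.sum(axis=1, dtype=float)
    d = A.sum(axis=0, dtype=float)
    m = float(A.sum())
    B = A - np.outer(k, d) / m
    q = _qb_from_arrays(A, g, h)
    for _ in range(max_iter):
        n_lab = int(max(g.max(), h.max())) + 1
        # rows move to the best module among those holding >=1 column
        col_member = np.zeros((A.shape[1], n_lab))
        col_member[np.arange(A.shape[1]), h] = 1.0
        row_scores = B @ col_member  # (R, n_lab)
        active = np.flatnonzero(col_member.sum(axis=0) > 0)
        g = active[np.argmax(row_scores[:, active], axis=1)]
        # columns move symmetrically among modules holding >=1 row
        row_member = np.zeros((A.shape[0], n_lab))
        row_member[np.arange(A.shape[0]), g] = 1.0
        col_scores = B.T @ row_member
        active = np.flatnonzero(row_member.sum(axis=0) > 0)
        h = active[np.argmax(col_scores[:, active], axis=1)]
        q_new = _qb_from_arrays(A, g, h)
        # each sweep reassigns every node to its additive-best module, so
        # qb is non-decreasing; stop when it stalls
        if q_new <= q + 1e-12:
            q = max(q, q_new)
            break
        q = q_new
    return g, h, q


def lp_brim(
    M: BipartiteMatrix,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 100,
) -> ModularityResult:
    """Maximise Barber's Qb with label propagation + BRIM refinement.

    Each restart runs seeded label propagation to an initial partition and
    then BRIM hill-climbing; the best Qb over restarts is returned with the
    child seed that produced it.  Fully deterministic for a fixed seed.
    """
    M.check_for_statistics()
    q, g, h, best_seed = _lp_brim_core(M.A, seed, n_restarts, max_iter)
    # compact module ids in order of first appearance (rows, then columns)
    remap: dict[int, int] = {}
    for lab in list(g) + list(h):
        if lab not in remap:
            remap[lab] = len(remap)
    g = np.array([remap[x] for x in g])
    h = np.array([remap[x] for x in h])
    return ModularityResult(
        row_modules={lab: int(mod) for lab, mod in zip(M.row_labels, g)},
        col_modules={lab: int(mod) for lab, mod in zip(M.col_labels, h)},
        qb=float(q),
        n_modules=len(set(g) | set(h)),
        n_restarts=n_restarts,
        best_restart_seed=best_seed,
    )


def _lp_brim_core(A: np.ndarray, seed: int, n_restarts: int, max_iter: int):
    """Best (qb, row labels, col labels, restart seed) over seeded restarts."""
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    r, c = A.shape
    best = None
    for rs in restart_seeds:
        rng = np.random.default_rng(int(rs))
        g0, h0 = _label_propagation(A, rng, max_iter)
        candidates = [(g0, h0)]
        # diversification: LP collapses near-complete matrices into one
        # module, which BRIM cannot split; a random initial labelling per
        # restart lets the hill-climb reach partitions LP never proposes
        candidates.append((rng.integers(0, c, r), rng.integers(0, c, c)))
        for ginit, hinit in candidates:
            g, h, q = _brim_refine(A, np.asarray(ginit), np.asarray(hinit), max_iter)
            if best is None or q > best[0] + 1e-12:
                best = (q, g, h, int(rs))
    return best


# ---------------------------------------------------------------------------
# null model


def _equiprobable_draw(
    shape: tuple[int, int], fill: float, rng: np.random.Generator, max_retries: int
) -> np.ndarray:
    """Bernoulli(fill) matrix; draws with empty margins are redrawn up to
    ``max_retries`` times.

    At sparse fills an empty margin is almost certain in every draw, so
    after the bound the last draw is accepted as-is — the statistics are
    all well defined with empty rows or columns (zero-degree pairs simply
    contribute nothing), and unconditional draws are what the classic
    equiprobable model prescribes.
    """
    for _ in range(max_retries):
        A = (rng.random(shape) < fill).astype(np.int8)
        if A.sum() and A.sum(axis=1).all() and A.sum(axis=0).all():
            return A
    if A.sum() == 0:  # pathological fills only; keep m > 0 for the formulas
        A.flat[int(rng.integers(A.size))] = 1
    return A


def null_test(
    M: BipartiteMatrix,
    statistic: str,
    model: str = "equiprobable",
    n_iterations: int = 10000,
    seed: int = 0,
    null_restarts: int = 5,
    max_retries: int = 100,
) -> NullTestResult:
    """Significance of a network statistic against the equiprobable null.

    Null matrices have every cell drawn independently at the observed fill
    (draws with an empty row or column are rejected and redrawn).  The
    one-sided empirical p uses add-one smoothing:
    p = (1 + #{null >= observed}) / (n_iterations + 1).
    """
    if model != "equiprobable":
        raise ValueError(f"unknown null model {model!r}")
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    M.check_for_statistics()

    def compute(A: np.ndarray, stat_seed: int) -> float:
        if statistic == "nodf":
            return _nodf_value(A)
        if statistic == "n_ntc":
            return (100.0 - _packed_temperature(A)) / 100.0
        if statistic == "qb":
            return _lp_brim_core(A, stat_seed, null_restarts, 100)[0]
        raise ValueError(f"unknown statistic {statistic!r}")

    ss = np.random.SeedSequence(seed)
    stat_seeds = ss.generate_state(n_iterations + 1) % (2**31)
    observed = compute(M.A, int(stat_seeds[-1]))
    rng = np.random.default_rng(ss.spawn(1)[0])
    shape, fill = M.shape, M.fill
    nulls = np.empty(n_iterations)
    for it in range(n_iterations):
        A = _equiprobable_draw(shape, fill, rng, max_retries)
        nulls[it] = compute(A, int(stat_seeds[it]))
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    z = (observed - null_mean) / null_sd if null_sd > 0 else None
    p = (1 + int((nulls >= observed).sum())) / (n_iterations + 1)
    return NullTestResult(
        statistic_name=statistic,
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_empirical=p,
        n_iterations=n_iterations,
        model_name=model,
        seed=seed,
    )
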