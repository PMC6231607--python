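"""Structural-balance partitioning of signed networks.

Generalized balance theory predicts that a signed network organizes into
classes with positive ties inside classes and negative ties between them.
A partition's departure from that ideal is the balance score

    R = alpha * N_c + (1 - alpha) * P_c

where ``N_c`` counts negative edges within classes, ``P_c`` positive edges
between classes, and ``alpha`` weights the two kinds of inconsistency.  A
perfectly balanced partition has R = 0.

The optimizer is a relocation-method local search: each repetition starts
from a fresh random feasible partition into exactly K classes (every class
at least ``min_size`` nodes) and applies single-node relocations and
two-node exchanges until no move strictly decreases R.  Steepest descent is
the default; a first-improvement mode trades determinism of the descent path
for speed on large networks.  Repetitions within a trial are pooled: the
trial reports the minimum R found and every distinct partition (after
canonical relabeling) achieving it, so "did this K admit a unique optimum?"
is answerable exactly as the sweep bookkeeping requires.

For small networks :func:`exhaustive_optimum` enumerates every feasible
partition and serves as the oracle the heuristic is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ties import SignedNetwork

__all__ = [
    "SignedPartition",
    "TrialResult",
    "SweepResult",
    "balance_score",
    "optimize_partition",
    "exhaustive_optimum",
    "sweep_classes",
    "select_model",
]

_EPS = 1e-9


@dataclass(frozen=True)
class SignedPartition:
    """A class assignment with its balance diagnostics."""

    assignment: dict[str, int]
    n_classes: int
    r_score: float
    n_c: int
    p_c: int
    alpha_w: float

    def class_sizes(self) -> list[int]:
        sizes = [0] * self.n_classes
        for c in self.assignment.values():
            sizes[c - 1] += 1
        return sizes


@dataclass(frozen=True)
class TrialResult:
    """One optimization trial: pooled best over its repetitions."""

    n_classes: int
    best_r: float
    partitions: tuple[tuple[int, ...], ...]  # canonical labels over sorted nodes
    nodes: tuple[str, ...]
    repetitions: int
    alpha_w: float

    @property
    def unique(self) -> bool:
        return len(self.partitions) == 1

    @property
    def n_solutions(self) -> int:
        return len(self.partitions)

    def best_partition(self, network: SignedNetwork) -> SignedPartition:
        assignment = {v: c for v, c in zip(self.nodes, self.partitions[0])}
        r, n_c, p_c = balance_score(network, assignment, self.alpha_w)
        return SignedPartition(
            assignment=assignment,
            n_classes=self.n_classes,
            r_score=r,
            n_c=n_c,
            p_c=p_c,
            alpha_w=self.alpha_w,
        )


@dataclass
class SweepResult:
    """Trials across a range of class counts, with sweep bookkeeping."""

    trials: dict[int, list[TrialResult]] = field(default_factory=dict)

    def records(self) -> pd.DataFrame:
        """Per-(K, trial) rows: best R, solution count, smallest class size."""
        rows = []
        for k_classes, trial_list in sorted(self.trials.items()):
            for t, tr in enumerate(trial_list):
                sizes = np.bincount(tr.partitions[0], minlength=k_classes + 1)[1:]
                rows.append(
                    {
                        "n_classes": k_classes,
                        "trial": t,
                        "best_r": tr.best_r,
                        "n_solutions": tr.n_solutions,
                        "unique": tr.unique,
                        "smallest_class": int(sizes.min()),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Per-K: median R, outlier trials (non-unique), mean solutions among outliers."""
        rec = self.records()
        rows = []
        for k_classes, grp in rec.groupby("n_classes"):
            outliers = grp[~grp["unique"]]
            rows.append(
                {
                    "n_classes": int(k_classes),
                    "median_r": float(grp["best_r"].median()),
                    "trials": len(grp),
                    "outliers": len(outliers),
                    "mean_solutions_outliers": (
                        float(outliers["n_solutions"].mean()) if len(outliers) else 0.0
                    ),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# internal array representation
# ---------------------------------------------------------------------------

class _Instance:
    """Index-based view of a signed network for the optimizer."""

    def __init__(self, network: SignedNetwork):
        self.nodes = tuple(sorted(network.nodes))
        index = {v: i for i, v in enumerate(self.nodes)}
        pos, neg = [], []
        for (u, v), sign in network.edges.items():
            (pos if sign > 0 else neg).append((index[u], index[v]))
        self.pos = np.array(pos, dtype=np.int64).reshape(-1, 2)
        self.neg = np.array(neg, dtype=np.int64).reshape(-1, 2)
        self.n = len(self.nodes)

    def counts(self, a: np.ndarray) -> tuple[int, int]:
        n_c = int((a[self.neg[:, 0]] == a[self.neg[:, 1]]).sum()) if len(self.neg) else 0
        p_c = int((a[self.pos[:, 0]] != a[self.pos[:, 1]]).sum()) if len(self.pos) else 0
        return n_c, p_c

    def score(self, a: np.ndarray, alpha_w: float) -> float:
        n_c, p_c = self.counts(a)
        return alpha_w * n_c + (1 - alpha_w) * p_c


def _canonical(a: np.ndarray) -> tuple[int, ...]:
    """Relabel classes 1..K by first occurrence over node order."""
    relabel: dict[int, int] = {}
    out = []
    for c in a:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out.append(relabel[c])
    return tuple(out)


def balance_score(
    network: SignedNetwork, assignment: dict[str, int], alpha_w: float = 0.5
) -> tuple[float, int, int]:
    """Return (R, N_c, P_c) for an assignment covering every network node."""
    missing = set(network.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses {len(missing)} node(s), e.g. {sorted(missing)[:3]}")
    n_c = p_c = 0
    for (u, v), sign in network.edges.items():
        same = assignment[u] == assignment[v]
        if sign < 0 and same:
            n_c += 1
        elif sign > 0 and not same:
            p_c += 1
    return alpha_w * n_c + (1 - alpha_w) * p_c, n_c, p_c


# ---------------------------------------------------------------------------
# local search
# ---------------------------------------------------------------------------

def _random_feasible(inst: _Instance, k_classes: int, min_size: int, rng) -> np.ndarray:
    order = rng.permutation(inst.n)
    a = np.empty(inst.n, dtype=np.int64)
    dealt = k_classes * min_size
    a[order[:dealt]] = np.arange(dealt) % k_classes
    a[order[dealt:]] = rng.integers(0, k_classes, size=inst.n - dealt)
    return a


def _degree_matrices(inst: _Instance, a: np.ndarray, k_classes: int):
    pos = np.zeros((inst.n, k_classes), dtype=np.int64)
    neg = np.zeros((inst.n, k_classes), dtype=np.int64)
    if len(inst.pos):
        np.add.at(pos, (inst.pos[:, 0], a[inst.pos[:, 1]]), 1)
        np.add.at(pos, (inst.pos[:, 1], a[inst.pos[:, 0]]), 1)
    if len(inst.neg):
        np.add.at(neg, (inst.neg[:, 0], a[inst.neg[:, 1]]), 1)
        np.add.at(neg, (inst.neg[:, 1], a[inst.neg[:, 0]]), 1)
    return pos, neg


def _descend(
    inst: _Instance,
    a: np.ndarray,
    k_classes: int,
    min_size: int,
    alpha_w: float,
    *,
    first_improvement: bool = False,
) -> float:
    """In-place local search; returns the final R.

    Moves: single-node relocation (source class must stay >= min_size) and
    exchange of two nodes in different classes (sizes unchanged).  Every
    accepted move strictly decreases R, so termination is guaranteed.
    """
    pos, neg = _degree_matrices(inst, a, k_classes)
    sizes = np.bincount(a, minlength=k_classes)
    floor = max(min_size, 1)  # classes must also stay non-empty
    arange = np.arange(inst.n)
    # adjacency lists for incremental degree-matrix updates
    adj_pos: list[list[int]] = [[] for _ in range(inst.n)]
    adj_neg: list[list[int]] = [[] for _ in range(inst.n)]
    for u, v in inst.pos:
        adj_pos[u].append(v)
        adj_pos[v].append(u)
    for u, v in inst.neg:
        adj_neg[u].append(v)
        adj_neg[v].append(u)
    adj_pos_arr = [np.array(x, dtype=np.int64) for x in adj_pos]
    adj_neg_arr = [np.array(x, dtype=np.int64) for x in adj_neg]

    def apply_move(u: int, target: int) -> None:
        src = a[u]
        for nbrs, mat in ((adj_pos_arr[u], pos), (adj_neg_arr[u], neg)):
            if len(nbrs):
                np.add.at(mat, (nbrs, src), -1)
                np.add.at(mat, (nbrs, target), 1)
        sizes[src] -= 1
        sizes[target] += 1
        a[u] = target

    while True:
        cur = a
        # relocation deltas: D[u, c] = cost of moving u into class c
        d = alpha_w * (neg - neg[arange, cur][:, None]) + (1 - alpha_w) * (
            pos[arange, cur][:, None] - pos
        )
        d_reloc = d.copy()
        d_reloc[arange, cur] = np.inf
        d_reloc[sizes[cur] <= floor, :] = np.inf  # source class would shrink
        best_reloc = d_reloc.min() if d_reloc.size else np.inf
        if first_improvement and best_reloc < -_EPS:
            # take the best relocation without pricing exchanges
            u, c = np.unravel_index(np.argmin(d_reloc), d_reloc.shape)
            apply_move(int(u), int(c))
            continue
        # exchange deltas: E[u, v] = D[u, a_v] + D[v, a_u] + pair correction
        m = d[:, cur]  # m[u, v] = D[u, a_v]
        e = m + m.T
        if len(inst.pos):
            e[inst.pos[:, 0], inst.pos[:, 1]] += 2 * (1 - alpha_w)
            e[inst.pos[:, 1], inst.pos[:, 0]] += 2 * (1 - alpha_w)
        if len(inst.neg):
            e[inst.neg[:, 0], inst.neg[:, 1]] -= 2 * alpha_w
            e[inst.neg[:, 1], inst.neg[:, 0]] -= 2 * alpha_w
        e[cur[:, None] == cur[None, :]] = np.inf  # same class (incl. diagonal)
        best_ex = e.min() if e.size else np.inf
        best = min(best_reloc, best_ex)
        if best >= -_EPS:
            break
        if best_reloc <= best_ex:
            u, c = np.unravel_index(np.argmin(d_reloc), d_reloc.shape)
            apply_move(int(u), int(c))
        else:
            u, v = np.unravel_index(np.argmin(e), e.shape)
            cu, cv = int(a[u]), int(a[v])
            apply_move(int(u), cv)
            apply_move(int(v), cu)
    return inst.score(a, alpha_w)  # exact recount, no float drift


def optimize_partition(
    network: SignedNetwork,
    n_classes: int,
    *,
    min_size: int = 3,
    repetitions: int = 100,
    alpha_w: float = 0.5,
    seed: int | None = None,
    first_improvement: bool = False,
) -> TrialResult:
    """Run ``repetitions`` random-restart local searches; pool the best.

    Each repetition draws a fresh random feasible start.  The result carries
    every distinct optimal partition found (canonical class labels), so a
    trial is "unique" exactly when all repetitions that reached the best R
    agree on one partition.
    """
    inst = _Instance(network)
    if n_classes * min_size > inst.n:
        raise ValueError(
            f"infeasible: {n_classes} classes x min_size {min_size} > {inst.n} nodes"
        )
    if repetitions < 1:
        raise ValueError("need repetitions >= 1")
    rng = np.random.default_rng(seed)
    best_r = np.inf
    optima: dict[tuple[int, ...], None] = {}
    for _ in range(repetitions):
        a = _random_feasible(inst, n_classes, min_size, rng)
        r = _descend(inst, a, n_classes, min_size, alpha_w,
                     first_improvement=first_improvement)
        if r < best_r - _EPS:
            best_r = r
            optima = {_canonical(a): None}
        elif abs(r - best_r) <= _EPS:
            optima[_canonical(a)] = None
    return TrialResult(
        n_classes=n_classes,
        best_r=float(best_r),
        partitions=tuple(sorted(optima)),
        nodes=inst.nodes,
        repetitions=repetitions,
        alpha_w=alpha_w,
    )


def exhaustive_optimum(
    network: SignedNetwork,
    n_classes: int,
    *,
    min_size: int = 1,
    alpha_w: float = 0.5,
    max_nodes: int = 14,
) -> tuple[float, tuple[tuple[int, ...], ...], tuple[str, ...]]:
    """Global optimum by enumerating every partition into exactly K classes.

    Returns ``(R*, canonical optimal partitions, node order)``.  Guarded to
    small instances; intended as the test oracle for the heuristic.
    """
    inst = _Instance(network)
    if inst.n > max_nodes:
        raise ValueError(f"enumeration guarded to <= {max_nodes} nodes, got {inst.n}")
    if n_classes * min_size > inst.n:
        raise ValueError("infeasible class-count / min-size combination")
    n, k = inst.n, n_classes
    total = k**n
    best_r = np.inf
    optima: dict[tuple[int, ...], None] = {}
    chunk = 1 << 18
    powers = k ** np.arange(n)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.int64)
        a = (codes[:, None] // powers[None, :]) % k  # rows: assignments
        valid = np.ones(len(codes), dtype=bool)
        for c in range(k):
            valid &= (a == c).sum(axis=1) >= min_size
        if not valid.any():
            continue
        a = a[valid]
        r = np.zeros(len(a))
        if len(inst.neg):
            r += alpha_w * (a[:, inst.neg[:, 0]] == a[:, inst.neg[:, 1]]).sum(axis=1)
        if len(inst.pos):
            r += (1 - alpha_w) * (a[:, inst.pos[:, 0]] != a[:, inst.pos[:, 1]]).sum(axis=1)
        lo = r.min()
        if lo < best_r - _EPS:
            best_r = lo
            optima = {}
        if lo <= best_r + _EPS:
            for row in a[np.abs(r - best_r) <= _EPS]:
                optima[_canonical(row)] = None
    return float(best_r), tuple(sorted(optima)), inst.nodes


def sweep_classes(
    network: SignedNetwork,
    k_range: range | list[int],
    *,
    trials: int = 10,
    repetitions: int = 100,
    min_size: int = 3,
    alpha_w: float = 0.5,
    base_seed: int = 0,
) -> SweepResult:
    """Repeat trials of the optimizer for each class count in ``k_range``.

    Trial ``t`` at any K uses seed ``base_seed + t``, so enlarging the range
    never reshuffles earlier trials.
    """
    result = SweepResult()
    for k_classes in k_range:
        result.trials[k_classes] = [
            optimize_partition(
                network,
                k_classes,
                min_size=min_size,
                repetitions=repetitions,
                alpha_w=alpha_w,
                seed=base_seed + t,
            )
            for t in range(trials)
        ]
    return result


def select_model(sweep: SweepResult) -> int:
    """Recommend K: minimize median R, break ties by fewer outliers, then smaller K."""
    summary = sweep.summary()
    if summary.empty:
        raise ValueError("empty sweep")
    ordered = summary.sort_values(
        ["median_r", "outliers", "n_classes"], kind="stable"
    )
    return int(ordered.iloc[0]["n_classes"])
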