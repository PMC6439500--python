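"""Iterative-reallocation clustering with likelihood-based assignment.

The procedure randomly partitions all genotypes into k groups (ignoring
sample labels), then repeatedly recomputes group allele frequencies and
reassigns every individual to its maximum-likelihood group (leave-one-out
when scoring an individual against its own group).  Repeated runs per k
yield a plateau record — runs converging on the identical partition — from
which the number of populations K is estimated.  Reference-based allocation
tables and mean-LLOD significance tests (log10 likelihood ratio of best
versus second-best group, with a source-resampling null) support the source
search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, FreqEntry, GenotypeDataset

__all__ = [
    "ClusterPartition",
    "PlateauRecord",
    "AllocationResult",
    "genotype_log_likelihood",
    "single_run_reallocation",
    "multi_run_plateau",
    "allocation_table",
    "llod_significance",
]

#: Plateau length at or above which a k qualifies as a K estimate.
PLATEAU_THRESHOLD = 6


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

class _Encoded:
    """Dataset recoded to per-locus 0-based allele indices for fast
    frequency/likelihood arithmetic."""

    def __init__(self, ds: GenotypeDataset) -> None:
        self.n = ds.n_individuals
        self.L = ds.n_loci
        self.alleles: list[np.ndarray] = []
        self.a1 = np.full((self.n, self.L), -1, dtype=np.int64)
        self.a2 = np.full((self.n, self.L), -1, dtype=np.int64)
        for j in range(ds.n_loci):
            col = ds.calls[:, j, :]
            typed = col[:, 0] != MISSING
            alleles = np.unique(col[typed])
            self.alleles.append(alleles)
            if typed.any():
                self.a1[typed, j] = np.searchsorted(alleles, col[typed, 0])
                self.a2[typed, j] = np.searchsorted(alleles, col[typed, 1])
        self.typed = self.a1 >= 0

    def counts_for(self, members: np.ndarray) -> list[np.ndarray]:
        """Per-locus allele-copy counts over a member index array."""
        out = []
        for j in range(self.L):
            A = len(self.alleles[j])
            m = members[self.typed[members, j]]
            c = np.bincount(self.a1[m, j], minlength=A) + np.bincount(
                self.a2[m, j], minlength=A
            )
            out.append(c.astype(np.int64))
        return out


def _loglik_matrix(enc: _Encoded, assign: np.ndarray, k: int) -> np.ndarray:
    """log10 likelihood of every individual in every group, leave-one-out
    for the group an individual currently belongs to.

    Zero-frequency alleles take the pseudo-frequency 1/(2N+1) where N is
    the group's typed-genotype count at the locus.
    """
    n = enc.n
    ll = np.zeros((n, k))
    for j in range(enc.L):
        A = len(enc.alleles[j])
        if A == 0:
            continue
        counts = np.zeros((k, A), dtype=np.int64)
        typed_j = enc.typed[:, j]
        for g in range(k):
            m = np.flatnonzero((assign == g) & typed_j)
            if m.size:
                counts[g] = np.bincount(enc.a1[m, j], minlength=A) + np.bincount(
                    enc.a2[m, j], minlength=A
                )
        tot = counts.sum(axis=1)  # 2 * typed genotypes per group
        idx = np.flatnonzero(typed_j)
        x, y = enc.a1[idx, j], enc.a2[idx, j]
        own = assign[idx]
        # per-individual adjusted counts for its own group (leave-one-out)
        c_x = counts[:, x].T.astype(float)       # (n_typed, k)
        c_y = counts[:, y].T.astype(float)
        t = np.broadcast_to(tot.astype(float), (idx.size, k)).copy()
        rows = np.arange(idx.size)
        hom = x == y
        c_x[rows, own] -= np.where(hom, 2, 1)
        c_y[rows, own] -= np.where(hom, 2, 1)
        t[rows, own] -= 2
        with np.errstate(divide="ignore", invalid="ignore"):
            p_x = np.where(c_x > 0, c_x / np.maximum(t, 1), 1.0 / (t + 1))
            p_y = np.where(c_y > 0, c_y / np.maximum(t, 1), 1.0 / (t + 1))
            contrib = np.where(
                hom[:, None], 2 * np.log10(p_x), np.log10(2 * p_x * p_y)
            )
        ll[idx] += contrib
    return ll


def genotype_log_likelihood(
    calls: np.ndarray | dict[str, tuple[int, int] | None],
    freqs: dict[str, FreqEntry],
    leave_one_out: bool = False,
) -> float:
    """log10 likelihood of one multilocus genotype against a group's allele
    frequencies.

    ``calls`` maps locus name to an allele pair (or None when missing);
    ``freqs`` maps locus name to the group's :class:`FreqEntry`.  A
    heterozygote a/b contributes ``log10(2 p_a p_b)``, a homozygote a/a
    ``log10(p_a^2)``; alleles unseen in the group take the pseudo-frequency
    ``1/(2N + 1)``.  With ``leave_one_out``, the individual's own copies
    are removed from the group counts first (use only when the individual
    is a member of the group).
    """
    if isinstance(calls, np.ndarray):
        raise TypeError("pass calls as a {locus: (a, b) | None} mapping")
    total = 0.0
    any_locus = False
    for locus, pair in calls.items():
        if pair is None or locus not in freqs:
            continue
        entry = freqs[locus]
        a, b = pair
        n2 = 2 * entry.n_typed
        counts = {int(al): entry.freq_of(int(al)) * n2 for al in entry.alleles}
        if leave_one_out:
            counts[a] = counts.get(a, 0) - 1
            counts[b] = counts.get(b, 0) - 1
            n2 -= 2
        if n2 <= 0:
            continue

        def p_of(al: int) -> float:
            c = counts.get(al, 0.0)
            return c / n2 if c > 0.5 else 1.0 / (n2 + 1)

        if a == b:
            total += 2 * np.log10(p_of(a))
        else:
            total += np.log10(2 * p_of(a) * p_of(b))
        any_locus = True
    if not any_locus:
        raise ValueError("individual typed at no locus shared with the group")
    return float(total)


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

@dataclass
class ClusterPartition:
    """One run's final k-group partition with its mean LLOD."""

    k: int
    assignment: dict[str, int]      # individual -> group index (1..k)
    mean_llod: float
    n_iterations_run: int

    def canonical(self) -> tuple[int, ...]:
        """Group labels renumbered by first appearance — identical for any
        relabeling of the same partition."""
        remap: dict[int, int] = {}
        out = []
        for ind in self.assignment:
            g = self.assignment[ind]
            if g not in remap:
                remap[g] = len(remap) + 1
            out.append(remap[g])
        return tuple(out)


def _mean_llod(ll: np.ndarray) -> float:
    if ll.shape[1] < 2:
        return 0.0
    part = np.partition(ll, ll.shape[1] - 2, axis=1)
    return float(np.mean(part[:, -1] - part[:, -2]))


class _RunState:
    """Padded per-group allele counts supporting incremental updates during
    a sequential reallocation pass."""

    def __init__(self, enc: _Encoded, assign: np.ndarray, k: int) -> None:
        self.enc = enc
        self.k = k
        L = enc.L
        a_max = max((len(a) for a in enc.alleles), default=1) or 1
        self.counts = np.zeros((k, L, a_max))
        self.tot = np.zeros((k, L))
        self.cols = np.arange(L)
        for i in range(enc.n):
            self.add(i, assign[i])

    def _contrib(self, i: int):
        enc = self.enc
        t = enc.typed[i]
        x = np.where(t, enc.a1[i], 0)
        y = np.where(t, enc.a2[i], 0)
        return t, x, y

    def add(self, i: int, g: int, sign: float = 1.0) -> None:
        t, x, y = self._contrib(i)
        np.add.at(self.counts[g], (self.cols[t], x[t]), sign)
        np.add.at(self.counts[g], (self.cols[t], y[t]), sign)
        self.tot[g, t] += 2 * sign

    def remove(self, i: int, g: int) -> None:
        self.add(i, g, sign=-1.0)

    def loglik_row(self, i: int, own: int | None) -> np.ndarray:
        """log10 likelihood of individual i against every group, with the
        individual's own copies removed from group ``own`` first."""
        enc = self.enc
        t, x, y = self._contrib(i)
        cx = self.counts[:, self.cols, x].copy()          # (k, L)
        cy = self.counts[:, self.cols, y].copy()
        tot = self.tot.copy()
        if own is not None:
            hom = x == y
            sub = np.where(hom, 2.0, 1.0)
            cx[own] -= sub
            cy[own] -= np.where(hom, 2.0, 1.0)
            tot[own] -= 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            safe_tot = np.maximum(tot, 1.0)
            px = np.where(cx > 0, cx / safe_tot, 1.0 / (tot + 1.0))
            py = np.where(cy > 0, cy / safe_tot, 1.0 / (tot + 1.0))
            contrib = np.where(x == y, 2 * np.log10(px), np.log10(2 * px * py))
        return (contrib * t).sum(axis=1)


def single_run_reallocation(
    ds: GenotypeDataset, k: int, n_iter: int = 20, seed: int = 0
) -> ClusterPartition:
    """One reallocation run: random initial k-partition, then up to
    ``n_iter`` sequential reassignment passes.

    Each pass visits individuals in a fresh seeded random order and moves
    each to its maximum-likelihood group (leave-one-out against its
    current group), updating group frequencies immediately; exact
    likelihood ties break by a seeded jitter.  Groups emptied during a
    pass are respawned from the largest group's worst-fitting member.
    The returned mean LLOD is the average over individuals of
    log10(L_best / L_second_best).
    """
    if k < 1 or k > ds.n_individuals:
        raise ValueError("k must lie in [1, n_individuals]")
    enc = _Encoded(ds)
    rng = np.random.default_rng(seed)
    n = enc.n
    assign = rng.integers(k, size=n)
    state = _RunState(enc, assign, k)
    iterations = 0
    for _ in range(n_iter):
        iterations += 1
        moved = 0
        for i in rng.permutation(n):
            g0 = assign[i]
            ll = state.loglik_row(i, own=g0)
            g1 = int(np.argmax(ll + rng.uniform(0.0, 1e-9, size=k)))
            if g1 != g0:
                state.remove(i, g0)
                state.add(i, g1)
                assign[i] = g1
                moved += 1
        # respawn any emptied group from the largest group's worst member
        sizes = np.bincount(assign, minlength=k)
        for g in range(k):
            if sizes[g] == 0:
                big = int(np.argmax(sizes))
                members = np.flatnonzero(assign == big)
                worst = min(
                    members, key=lambda m: state.loglik_row(m, own=big)[big]
                )
                state.remove(worst, big)
                state.add(worst, g)
                assign[worst] = g
                sizes = np.bincount(assign, minlength=k)
                moved += 1
        if moved == 0:
            break
    ll = _loglik_matrix(enc, assign, k)
    return ClusterPartition(
        k=k,
        assignment={ind: int(g) + 1 for ind, g in zip(ds.individuals, assign)},
        mean_llod=_mean_llod(ll),
        n_iterations_run=iterations,
    )


@dataclass
class PlateauRecord:
    """Multi-run record per k: canonical partitions, plateau lengths, and
    the resulting K estimate (None = undecided)."""

    k_values: list[int]
    runs: dict[int, list[ClusterPartition]]
    plateau_lengths: dict[int, int]        # identical-partition run from the top
    K_estimate: int | None
    undecided_between: tuple[int, int] | None = None
    threshold: int = PLATEAU_THRESHOLD
    largest_identical: dict[int, int] | None = None  # biggest identical set per k


def multi_run_plateau(
    ds: GenotypeDataset,
    k_range: tuple[int, int] = (2, 4),
    n_runs: int = 50,
    n_iter: int = 20,
    seed: int = 0,
) -> PlateauRecord:
    """Repeated reallocation runs per k and plateau-based K estimation.

    Runs at each k are sorted by mean LLOD (descending); the plateau
    length is the number of consecutive runs from the top sharing the
    top run's canonical partition.  K is the largest k whose plateau
    reaches the threshold; no qualifying k means K = 1 (no structure
    detectable); two adjacent qualifying k with equal plateau lengths is
    recorded as undecided between them.
    """
    k_min, k_max = k_range
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max > max(2, ds.n_individuals // 2):
        raise ValueError("k_max must be <= n_individuals / 2")
    rng = np.random.default_rng(seed)
    runs: dict[int, list[ClusterPartition]] = {}
    plateau: dict[int, int] = {}
    largest_identical: dict[int, int] = {}
    for k in range(k_min, k_max + 1):
        parts = [
            single_run_reallocation(ds, k, n_iter=n_iter, seed=int(rng.integers(2**31)))
            for _ in range(n_runs)
        ]
        parts = sorted(parts, key=lambda p: p.mean_llod, reverse=True)
        runs[k] = parts
        top = parts[0].canonical()
        length = 1
        for p in parts[1:]:
            if p.canonical() != top:
                break
            length += 1
        plateau[k] = length
        tally: dict[tuple[int, ...], int] = {}
        for p in parts:
            c = p.canonical()
            tally[c] = tally.get(c, 0) + 1
        largest_identical[k] = max(tally.values())
    qualifying = [k for k in plateau if plateau[k] >= PLATEAU_THRESHOLD]
    undecided = None
    if not qualifying:
        K: int | None = 1
    else:
        k_star = max(qualifying)
        if k_star - 1 in qualifying and plateau[k_star - 1] == plateau[k_star]:
            K = None
            undecided = (k_star - 1, k_star)
        else:
            K = k_star
    return PlateauRecord(
        k_values=list(range(k_min, k_max + 1)),
        runs=runs,
        plateau_lengths=plateau,
        K_estimate=K,
        undecided_between=undecided,
        largest_identical=largest_identical,
    )


# ---------------------------------------------------------------------------
# Allocation tables and LLOD significance
# ---------------------------------------------------------------------------

@dataclass
class AllocationResult:
    """Reference-allocation summary for one novel sample."""

    novel_sample: str
    references: list[str]
    co_allocation: dict[str, float]        # fraction of each reference sharing
                                           # the novel's majority cluster
    allocation_fractions: dict[str, float] # supervised max-likelihood shares
    mean_llod: float
    best_reference: str
    p_value: float | None = None
    warnings: list[str] = field(default_factory=list)


def _group_counts_for_pop(enc: _Encoded, idx: np.ndarray) -> list[np.ndarray]:
    return enc.counts_for(idx)


def _score_against(
    enc: _Encoded,
    indiv: np.ndarray,
    counts: list[np.ndarray],
    loo_members: set[int] | None = None,
) -> np.ndarray:
    """log10 likelihood of individuals ``indiv`` against a reference whose
    per-locus allele counts are ``counts``; members listed in
    ``loo_members`` are scored leave-one-out."""
    out = np.zeros(indiv.size)
    for j in range(enc.L):
        c = counts[j].astype(float)
        tot = c.sum()
        for pos, i in enumerate(indiv):
            if not enc.typed[i, j]:
                continue
            x, y = enc.a1[i, j], enc.a2[i, j]
            cx, cy, t = c[x], c[y], tot
            if loo_members and i in loo_members:
                sub = 2 if x == y else 1
                cx -= sub
                cy -= sub
                t -= 2
            if t <= 0:
                continue
            px = cx / t if cx > 0 else 1.0 / (t + 1)
            py = cy / t if cy > 0 else 1.0 / (t + 1)
            if x == y:
                out[pos] += 2 * np.log10(px)
            else:
                out[pos] += np.log10(2 * px * py)
    return out


def allocation_table(
    novel: str,
    references: list[str],
    ds: GenotypeDataset,
    k: int = 2,
    n_runs: int = 10,
    seed: int = 0,
) -> AllocationResult:
    """Cluster the novel sample with its candidate sources at k and report
    co-allocation.

    Unsupervised runs (best of ``n_runs`` by total likelihood) give, per
    reference sample, its co-allocation with the novel sample: the overlap
    between the reference's and the novel's distributions over clusters
    (sum over clusters of the smaller fraction), normalised by the novel's
    largest cluster fraction so that a reference perfectly aligned with
    one of the novel's clusters scores 1.  When the novel sample
    concentrates in one cluster this reduces to the fraction of the
    reference sharing that majority cluster; when the novel splits between
    clusters (the admixture signature) candidates aligned with either
    part keep full scores.  A supervised pass allocates each
    novel individual to its maximum-likelihood reference (leave-one-out
    never applies: the novel is not part of any reference), yielding
    allocation fractions that sum to 1 and the mean LLOD against the best
    reference.
    """
    if novel in references:
        raise ValueError("novel sample must be disjoint from references")
    sub = ds.subset(populations=[novel] + references)
    enc = _Encoded(sub)
    pops = np.asarray(sub.populations)
    warnings = [
        f"reference {r!r} has fewer than 5 individuals (unstable frequencies)"
        for r in references
        if (pops == r).sum() < 5
    ]
    rng = np.random.default_rng(seed)
    best_part, best_ll = None, -np.inf
    for _ in range(n_runs):
        part = single_run_reallocation(sub, k, seed=int(rng.integers(2**31)))
        groups = np.array([part.assignment[i] for i in sub.individuals])
        ll = _loglik_matrix(enc, groups - 1, k)
        total = float(ll[np.arange(enc.n), groups - 1].sum())
        if total > best_ll:
            best_ll, best_part = total, part
    assert best_part is not None
    groups = np.array([best_part.assignment[i] for i in sub.individuals])
    novel_mask = pops == novel
    novel_frac = np.bincount(groups[novel_mask], minlength=k + 1) / novel_mask.sum()
    co_alloc = {}
    for r in references:
        ref_frac = np.bincount(groups[pops == r], minlength=k + 1) / (pops == r).sum()
        overlap = float(np.minimum(novel_frac, ref_frac).sum())
        co_alloc[r] = min(1.0, overlap / novel_frac.max())

    # supervised allocation against reference frequency profiles
    ref_counts = {r: enc.counts_for(np.flatnonzero(pops == r)) for r in references}
    novel_idx = np.flatnonzero(novel_mask)
    scores = np.column_stack(
        [_score_against(enc, novel_idx, ref_counts[r]) for r in references]
    )
    best = np.argmax(scores, axis=1)
    fractions = {
        r: float(np.mean(best == j)) for j, r in enumerate(references)
    }
    best_ref = references[int(np.bincount(best, minlength=len(references)).argmax())]
    if scores.shape[1] >= 2:
        part_sorted = np.sort(scores, axis=1)
        mean_llod = float(np.mean(part_sorted[:, -1] - part_sorted[:, -2]))
    else:
        mean_llod = 0.0
    return AllocationResult(
        novel_sample=novel,
        references=list(references),
        co_allocation=co_alloc,
        allocation_fractions=fractions,
        mean_llod=mean_llod,
        best_reference=best_ref,
        warnings=warnings,
    )


def llod_significance(
    novel: str,
    source: str,
    ds: GenotypeDataset,
    n_boot: int = 199,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean LLOD of the novel sample against a putative source, with a
    source-resampling null.

    The observed statistic is the mean over novel individuals of
    log10(L_best / L_second) between the novel sample's own frequency
    profile (leave-one-out) and the source's.  The null rebuilds the novel
    sample ``n_boot`` times by drawing genotypes from the source's allele
    frequencies (random union of gametes); p is the fraction of null mean
    LLODs at least the observed.  A high p means the novel sample is
    indistinguishable from a random draw out of the source.
    """
    if n_boot < 199:
        raise ValueError("n_boot must be >= 199")
    sub = ds.subset(populations=[novel, source])
    enc = _Encoded(sub)
    pops = np.asarray(sub.populations)
    novel_idx = np.flatnonzero(pops == novel)
    source_idx = np.flatnonzero(pops == source)
    src_counts = enc.counts_for(source_idx)
    for j, c in enumerate(src_counts):
        if c.sum() == 0:
            raise ValueError(f"source has no typed genotypes at locus {j}")

    def mean_llod_of(view, idx: np.ndarray, own_counts: list[np.ndarray]) -> float:
        ll_own = _score_against(view, idx, own_counts, loo_members=set(idx.tolist()))
        ll_src = _score_against(view, idx, src_counts)
        return float(np.mean(np.maximum(ll_own, ll_src) - np.minimum(ll_own, ll_src)))

    obs = mean_llod_of(enc, novel_idx, enc.counts_for(novel_idx))

    rng = np.random.default_rng(seed)
    n_nov = novel_idx.size
    hits = 0
    src_freqs = [c / c.sum() for c in src_counts]
    for _ in range(n_boot):
        # pseudo-novel drawn from the source's allele frequencies
        pseudo_a1 = np.empty((n_nov, enc.L), dtype=np.int64)
        pseudo_a2 = np.empty((n_nov, enc.L), dtype=np.int64)
        for j in range(enc.L):
            A = len(src_freqs[j])
            pseudo_a1[:, j] = rng.choice(A, size=n_nov, p=src_freqs[j])
            pseudo_a2[:, j] = rng.choice(A, size=n_nov, p=src_freqs[j])
        pseudo = _PseudoEncoded(enc, pseudo_a1, pseudo_a2)
        idx = np.arange(n_nov)
        stat = mean_llod_of(pseudo, idx, pseudo.counts_for(idx))
        if stat >= obs - 1e-12:
            hits += 1
    return obs, (hits + 1) / (n_boot + 1)


class _PseudoEncoded:
    """Encoded view over simulated genotypes sharing an existing allele
    space (used by the LLOD resampling null)."""

    def __init__(self, parent: _Encoded, a1: np.ndarray, a2: np.ndarray) -> None:
        self.L = parent.L
        self.alleles = parent.alleles
        self.a1 = a1
        self.a2 = a2
        self.typed = np.ones(a1.shape, dtype=bool)
        self.n = a1.shape[0]

    def counts_for(self, members: np.ndarray) -> list[np.ndarray]:
        out = []
        for j in range(self.L):
            A = len(self.alleles[j])
            c = np.bincount(self.a1[members, j], minlength=A) + np.bincount(
                self.a2[members, j], minlength=A
            )
            out.append(c.astype(np.int64))
        return out
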