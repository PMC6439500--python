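"""Iterative source-population search with a DAPC complement.

Given a novel (introduced) sample and a set of historically plausible
candidate sources, the search repeatedly clusters the novel sample with the
surviving candidates at k = 2 and discards candidates that are not mainly
co-allocated with the novel sample's majority cluster, until a single
source remains, no candidate can be discarded (an admixture signal — the
novel population draws on several sources), or every candidate is discarded
(the true source was not among those tested).  Ambiguous outcomes are
complemented by a discriminant analysis of principal components (DAPC)
centroid ordering, which is advisory and never auto-discards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data import MISSING, GenotypeDataset
from .clustering import ClusterPartition, allocation_table, llod_significance

__all__ = [
    "SourceSearchTrace",
    "DapcModel",
    "iterative_source_search",
    "dapc_fit",
    "dapc_complement",
]


@dataclass
class SearchRound:
    candidates: list[str]
    co_allocation: dict[str, float]
    discarded: list[str]
    rule: str


@dataclass
class SourceSearchTrace:
    """Audit record of one iterative source search."""

    novel: str
    rounds: list[SearchRound]
    final_sources: list[str]
    outcome: str                       # single_source | multiple_sources | untested_source
    ambiguity_flag: bool
    significance: dict[str, tuple[float, float]] = field(default_factory=dict)
    dapc_ranking: list[tuple[str, float]] | None = None
    threshold: float = 0.5


def iterative_source_search(
    novel: str,
    candidates: list[str],
    ds: GenotypeDataset,
    co_allocation_threshold: float = 0.5,
    seed: int = 0,
    batch_discard: bool = False,
    n_boot: int = 199,
) -> SourceSearchTrace:
    """Iteratively narrow candidate sources by k = 2 co-allocation.

    Each round clusters the novel sample with the surviving candidates at
    k = 2; candidates whose co-allocation fraction with the novel sample's
    majority cluster falls below the threshold are eliminated — by default
    one per round (the worst), or all at once with ``batch_discard``.
    Termination outcomes: one candidate left (single source), no candidate
    discardable with several left (multiple sources; ambiguity flag set),
    or all discarded (untested source).  Mean-LLOD significance against
    each final source closes the trace.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if novel in candidates:
        raise ValueError("novel sample cannot be its own candidate")
    rng = np.random.default_rng(seed)
    current = list(candidates)
    rounds: list[SearchRound] = []
    outcome = "multiple_sources"
    if len(current) == 1:
        # trivial trace: significance only
        outcome = "single_source"
    else:
        for _ in range(len(candidates)):
            alloc = allocation_table(
                novel, current, ds, k=2, seed=int(rng.integers(2**31))
            )
            below = [r for r in current if alloc.co_allocation[r] < co_allocation_threshold]
            if not below:
                rounds.append(SearchRound(list(current), dict(alloc.co_allocation), [], "no candidate below threshold"))
                outcome = "single_source" if len(current) == 1 else "multiple_sources"
                break
            if batch_discard:
                drop = below
                rule = f"co-allocation < {co_allocation_threshold} (batch)"
            else:
                drop = [min(below, key=lambda r: alloc.co_allocation[r])]
                rule = f"lowest co-allocation < {co_allocation_threshold}"
            rounds.append(SearchRound(list(current), dict(alloc.co_allocation), list(drop), rule))
            current = [r for r in current if r not in drop]
            if len(current) == 0:
                outcome = "untested_source"
                break
            if len(current) == 1:
                alloc = allocation_table(
                    novel, current, ds, k=2, seed=int(rng.integers(2**31))
                )
                frac = alloc.co_allocation[current[0]]
                if frac < co_allocation_threshold:
                    rounds.append(SearchRound(list(current), dict(alloc.co_allocation),
                                              list(current), "last candidate below threshold"))
                    current = []
                    outcome = "untested_source"
                else:
                    rounds.append(SearchRound(list(current), dict(alloc.co_allocation), [],
                                              "single candidate retained"))
                    outcome = "single_source"
                break

    significance = {
        s: llod_significance(novel, s, ds, n_boot=n_boot, seed=int(rng.integers(2**31)))
        for s in current
    }
    return SourceSearchTrace(
        novel=novel,
        rounds=rounds,
        final_sources=current,
        outcome=outcome,
        ambiguity_flag=len(current) > 1,
        significance=significance,
        threshold=co_allocation_threshold,
    )


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DapcModel:
    """Discriminant analysis of principal components.

    ``coordinates`` holds individual scores on the discriminant axes;
    ``assignment_accuracy`` is the percent agreement of the self-assignment
    contingency table.
    """

    n_pca_retained: int
    n_discriminants: int
    coordinates: pd.DataFrame          # index = individuals, columns LD1..
    centroids: pd.DataFrame            # index = groups
    assignment_accuracy: float
    groups: list[str]
    explained_variance: np.ndarray


def _dosage_matrix(ds: GenotypeDataset, labels: np.ndarray) -> np.ndarray:
    """Individual x allele dosage matrix (0/1/2 copies); missing genotypes
    imputed with the group mean dosage."""
    cols = []
    for j in range(ds.n_loci):
        col = ds.calls[:, j, :]
        typed = col[:, 0] != MISSING
        alleles = np.unique(col[typed]) if typed.any() else np.array([], dtype=int)
        block = np.zeros((ds.n_individuals, len(alleles)))
        for idx, al in enumerate(alleles):
            block[:, idx] = (col[:, 0] == al).astype(float) + (col[:, 1] == al)
        if (~typed).any():
            for g in np.unique(labels):
                members = (labels == g) & typed
                fill = block[members].mean(axis=0) if members.any() else block[typed].mean(axis=0)
                rows = (labels == g) & ~typed
                block[rows] = fill
        cols.append(block)
    return np.concatenate(cols, axis=1)


def dapc_fit(
    ds: GenotypeDataset,
    groups: list[str] | ClusterPartition | None = None,
    n_pca: int | str = "auto",
    seed: int = 0,
) -> DapcModel:
    """Fit a DAPC: PCA reduction of the centred/scaled dosage matrix
    followed by linear discriminant analysis on the group labels.

    ``groups`` defaults to the dataset's population labels; a
    :class:`ClusterPartition` may be passed to use inferred clusters.
    ``n_pca='auto'`` retains the smallest number of components explaining
    at least 90% of the variance, capped at n/3.
    """
    if groups is None:
        labels = np.asarray(ds.populations)
    elif isinstance(groups, ClusterPartition):
        labels = np.asarray([str(groups.assignment[i]) for i in ds.individuals])
    else:
        labels = np.asarray([str(g) for g in groups])
    group_names = list(dict.fromkeys(labels))
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups")
    if ds.n_individuals <= len(group_names):
        raise ValueError("need more individuals than groups")
    X = _dosage_matrix(ds, labels)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    max_pc = max(1, min(ds.n_individuals - 1, X.shape[1]))
    pca = PCA(n_components=max_pc, random_state=seed)
    scores = pca.fit_transform(X)
    if n_pca == "auto":
        cum = np.cumsum(pca.explained_variance_ratio_)
        want = int(np.searchsorted(cum, 0.90) + 1)
        cap = max(1, ds.n_individuals // 3)
        n_keep = min(want, cap, max_pc)
    else:
        n_keep = int(n_pca)
        if n_keep >= ds.n_individuals:
            raise ValueError("n_pca must be < n_individuals")
        n_keep = min(n_keep, max_pc)
    kept = scores[:, :n_keep]
    n_disc = min(len(group_names) - 1, n_keep)
    lda = LinearDiscriminantAnalysis(n_components=n_disc)
    coords = lda.fit_transform(kept, labels)
    pred = lda.predict(kept)
    accuracy = 100.0 * float(np.mean(pred == labels))
    coord_df = pd.DataFrame(
        coords, index=ds.individuals, columns=[f"LD{i+1}" for i in range(n_disc)]
    )
    centroids = coord_df.groupby(pd.Series(labels, index=coord_df.index)).mean().loc[group_names]
    return DapcModel(
        n_pca_retained=n_keep,
        n_discriminants=n_disc,
        coordinates=coord_df,
        centroids=centroids,
        assignment_accuracy=accuracy,
        groups=group_names,
        explained_variance=pca.explained_variance_ratio_[:n_keep],
    )


def dapc_complement(
    trace: SourceSearchTrace,
    ds: GenotypeDataset,
    seed: int = 0,
) -> SourceSearchTrace:
    """Adjudicate an ambiguous search by DAPC centroid proximity.

    Fits a DAPC on the novel sample plus the remaining candidates and
    appends a nearest-centroid ordering (candidate, distance to the novel
    centroid) to the trace.  Advisory only — candidates are never
    discarded here.  A no-op when the trace is unambiguous.
    """
    if not trace.ambiguity_flag:
        return trace
    sub = ds.subset(populations=[trace.novel] + trace.final_sources)
    model = dapc_fit(sub, seed=seed)
    novel_c = model.centroids.loc[trace.novel].to_numpy()
    ranking = sorted(
        (
            (cand, float(np.linalg.norm(model.centroids.loc[cand].to_numpy() - novel_c)))
            for cand in trace.final_sources
        ),
        key=lambda t: t[1],
    )
    trace.dapc_ranking = ranking
    return trace
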