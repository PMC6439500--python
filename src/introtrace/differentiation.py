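"""Pairwise population differentiation: Weir-Cockerham F_ST and Jost's D.

Both matrices are computed pairwise (each cell uses only that pair's
samples), combined across loci — F_ST by summing Weir-Cockerham variance
components, Jost's D by a harmonic (default) or arithmetic mean of the
per-locus unbiased D estimates.  A permutation test (shuffling individuals
between the pair) supplies significance; the reporting layer marks cells at
or above the 0.2 display rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeDataset

__all__ = [
    "DifferentiationMatrix",
    "pairwise_fst",
    "pairwise_jost_d",
    "permutation_significance",
    "differentiation_report",
]


@dataclass
class DifferentiationMatrix:
    """Symmetric differentiation matrix (diagonal 0) with display flags."""

    statistic: str                      # "FST" or "JostD"
    populations: list[str]
    values: pd.DataFrame                # symmetric, diagonal exactly 0
    clamped: list[tuple[str, str]] = field(default_factory=list)
    undefined: list[tuple[str, str]] = field(default_factory=list)
    p_perm: pd.DataFrame | None = None

    def flags(self, threshold: float = 0.2) -> pd.DataFrame:
        """Boolean mask of cells at or above the display threshold."""
        return (self.values >= threshold) & ~np.eye(len(self.populations), dtype=bool)

    def value(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(pair_calls: list[np.ndarray]) -> tuple[float, float]:
    """Weir-Cockerham (1984) variance components for one locus and r
    populations; returns (sum_a, sum_a+b+c) over alleles."""
    r = len(pair_calls)
    typed = [c[c[:, 0] != MISSING] for c in pair_calls]
    ns = np.array([t.shape[0] for t in typed], dtype=float)
    if (ns < 1).any() or ns.sum() < 2:
        return 0.0, 0.0
    alleles = np.unique(np.concatenate([t.ravel() for t in typed]))
    if len(alleles) < 2:
        return 0.0, 0.0
    n_bar = ns.mean()
    if n_bar <= 1:
        return 0.0, 0.0
    n_c = (r * n_bar - np.sum(ns**2) / (r * n_bar)) / (r - 1)
    sum_a = sum_all = 0.0
    for al in alleles:
        p_i = np.array([np.mean(t.ravel() == al) for t in typed])
        h_i = np.array([np.mean((t[:, 0] != t[:, 1]) & np.any(t == al, axis=1)) for t in typed])
        p_bar = float(np.sum(ns * p_i) / (r * n_bar))
        s2 = float(np.sum(ns * (p_i - p_bar) ** 2) / ((r - 1) * n_bar))
        h_bar = float(np.sum(ns * h_i) / (r * n_bar))
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0
            )
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
        sum_a += a
        sum_all += a + b + c
    return sum_a, sum_all


def _pair_calls(ds: GenotypeDataset, pop_a: str, pop_b: str, locus_j: int) -> list[np.ndarray]:
    pops = np.asarray(ds.populations)
    return [ds.calls[pops == p][:, locus_j, :] for p in (pop_a, pop_b)]


def _fst_pair(ds: GenotypeDataset, a: str, b: str) -> float:
    num = den = 0.0
    for j in range(ds.n_loci):
        va, vall = _wc_components(_pair_calls(ds, a, b, j))
        num += va
        den += vall
    return num / den if den != 0 else np.nan


def pairwise_fst(ds: GenotypeDataset) -> DifferentiationMatrix:
    """Pairwise Weir-Cockerham theta; loci combined by summing variance
    components.  Small negative estimates are reported as computed."""
    pops = ds.population_labels()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    vals = pd.DataFrame(0.0, index=pops, columns=pops)
    undefined = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            theta = _fst_pair(ds, a, b)
            if np.isnan(theta):
                undefined.append((a, b))
                theta = np.nan
            vals.loc[a, b] = vals.loc[b, a] = theta
    return DifferentiationMatrix("FST", pops, vals, undefined=undefined)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def _jost_d_locus(
    pair_calls: list[np.ndarray], sample_correction: bool = True
) -> float | None:
    """Unbiased two-population Jost's D for one locus; None when
    uninformative (untyped or H_S = 1)."""
    typed = [c[c[:, 0] != MISSING] for c in pair_calls]
    ns = np.array([t.shape[0] for t in typed], dtype=float)
    if (ns < 1).any():
        return None
    alleles = np.unique(np.concatenate([t.ravel() for t in typed]))
    P = np.array([[np.mean(t.ravel() == al) for al in alleles] for t in typed])
    hs_plain = float(np.mean(1.0 - np.sum(P**2, axis=1)))
    p_bar = P.mean(axis=0)
    ht_plain = float(1.0 - np.sum(p_bar**2))
    if sample_correction:
        n_harm = len(ns) / np.sum(1.0 / ns)
        hs = (2 * n_harm / (2 * n_harm - 1)) * hs_plain
        ht = ht_plain + hs / (2 * n_harm * len(ns))
    else:
        hs, ht = hs_plain, ht_plain
    if hs >= 1.0:
        return None
    r = len(ns)
    return (r / (r - 1)) * (ht - hs) / (1.0 - hs)


def _combine_d(per_locus: list[float], how: str) -> float:
    d = np.array(per_locus, dtype=float)
    if how == "arithmetic":
        return float(np.mean(d))
    if how != "harmonic":
        raise ValueError("combine must be 'harmonic' or 'arithmetic'")
    # harmonic combination through the (1 + 1/D) transform: stays defined
    # at D = 0 (the reciprocal of 1 + 1/0 is 0) and equals D when all loci
    # agree
    d = np.maximum(d, 0.0)
    recip = np.where(d > 0, d / (d + 1.0), 0.0)   # 1 / (1 + 1/D)
    s = recip.mean()
    if s <= 0:
        return 0.0
    harm = 1.0 / s
    return float(1.0 / (harm - 1.0)) if harm > 1.0 else 1.0


def pairwise_jost_d(
    ds: GenotypeDataset,
    combine: str = "harmonic",
    sample_correction: bool = True,
) -> DifferentiationMatrix:
    """Pairwise Jost's D_est (unbiased two-population form per locus).

    Negative per-pair estimates are clamped to 0 and flagged (D is a
    proportion of allelic variation); loci with H_S = 1 are excluded.
    ``sample_correction=False`` treats sample frequencies as parametric
    (the closed-form limit used by the oracle tests).
    """
    pops = ds.population_labels()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    vals = pd.DataFrame(0.0, index=pops, columns=pops)
    clamped, undefined = [], []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            per_locus = []
            for j in range(ds.n_loci):
                d = _jost_d_locus(_pair_calls(ds, a, b, j), sample_correction)
                if d is not None:
                    per_locus.append(d)
            if not per_locus:
                undefined.append((a, b))
                vals.loc[a, b] = vals.loc[b, a] = np.nan
                continue
            d_multi = _combine_d(per_locus, combine)
            if d_multi < 0:
                clamped.append((a, b))
                d_multi = 0.0
            d_multi = min(d_multi, 1.0)
            vals.loc[a, b] = vals.loc[b, a] = d_multi
    return DifferentiationMatrix("JostD", pops, vals, clamped=clamped, undefined=undefined)


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def permutation_significance(
    ds: GenotypeDataset,
    statistic: str = "FST",
    n_perm: int = 999,
    seed: int = 0,
    combine: str = "harmonic",
) -> pd.DataFrame:
    """Permutation p-values per population pair.

    Individuals are shuffled between the two populations of each pair;
    p is the fraction of permuted statistics at least the observed
    ((b+1)/(m+1) corrected).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if statistic not in ("FST", "JostD"):
        raise ValueError("statistic must be 'FST' or 'JostD'")
    pops = ds.population_labels()
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(np.nan, index=pops, columns=pops)

    def pair_stat(sub: GenotypeDataset, a: str, b: str) -> float:
        if statistic == "FST":
            return _fst_pair(sub, a, b)
        per_locus = [
            d for j in range(sub.n_loci)
            if (d := _jost_d_locus(_pair_calls(sub, a, b, j))) is not None
        ]
        return _combine_d(per_locus, combine) if per_locus else np.nan

    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            sub = ds.subset(populations=[a, b])
            obs = pair_stat(sub, a, b)
            if np.isnan(obs):
                continue
            labels = list(sub.populations)
            hits = 0
            for _ in range(n_perm):
                perm = [labels[k] for k in rng.permutation(len(labels))]
                shuffled = GenotypeDataset(sub.individuals, perm, sub.loci, sub.calls)
                if pair_stat(shuffled, a, b) >= obs - 1e-12:
                    hits += 1
            p = (hits + 1) / (n_perm + 1)
            out.loc[a, b] = out.loc[b, a] = p
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def differentiation_report(
    fst: DifferentiationMatrix,
    jost_d: DifferentiationMatrix,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Lower-triangle rendering of both matrices (2-decimal rounding,
    cells >= threshold marked with a trailing ``*``)."""
    if fst.populations != jost_d.populations:
        raise ValueError("matrices cover different population sets")
    pops = fst.populations
    blocks = []
    for mat in (fst, jost_d):
        rows = []
        for i, a in enumerate(pops):
            row: dict[str, object] = {"statistic": mat.statistic, "population": a}
            for j, b in enumerate(pops):
                if j > i:
                    row[b] = ""
                else:
                    v = mat.values.loc[a, b]
                    if np.isnan(v):
                        row[b] = "NA"
                    else:
                        cell = f"{v:.2f}"
                        if j < i and v >= threshold:
                            cell += "*"
                        row[b] = cell
            rows.append(row)
        blocks.append(pd.DataFrame(rows))
    return pd.concat(blocks, ignore_index=True)
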