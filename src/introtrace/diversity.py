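"""Per-population genetic-diversity statistics and diversity-vs-history
analyses.

Implements the standard microsatellite diversity panel — observed and
unbiased expected heterozygosity, F_IS, rarefied allelic richness, private
alleles, a Monte-Carlo Hardy-Weinberg exact test, the standardized index of
association (linkage-equilibrium screen), and the g2 identity-disequilibrium
inbreeding test — plus retention ratios, an introduction-step linear model,
and a locus-blocked permutation comparison of diversity across populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data import MISSING, AlleleFreqTable, GenotypeDataset, allele_frequencies
from .history import ImportationHistory

__all__ = [
    "heterozygosity_summary",
    "rarefied_allelic_richness",
    "auto_rarefaction_size",
    "private_allele_count",
    "hwe_exact_test",
    "multilocus_ld_test",
    "g2_inbreeding_test",
    "diversity_report",
    "render_diversity_table",
    "retention_ratio",
    "steps_regression",
    "population_diversity_comparison",
    "AssociationIndexResult",
    "StepsRegressionResult",
    "DiversityComparisonResult",
]


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def _per_locus_het(col: np.ndarray) -> tuple[float, float, int] | None:
    """(H_O, unbiased H_E, n_typed) for one (population, locus) genotype
    column of shape (n, 2); None when nothing is typed."""
    typed = col[col[:, 0] != MISSING]
    n = typed.shape[0]
    if n == 0:
        return None
    h_obs = float(np.mean(typed[:, 0] != typed[:, 1]))
    _, counts = np.unique(typed.ravel(), return_counts=True)
    p = counts / (2 * n)
    h_exp = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2))) if n > 0 else 0.0
    return h_obs, h_exp, n


def heterozygosity_summary(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-(population, locus) H_O, unbiased H_E and F_IS.

    H_E uses the small-sample correction ``2n/(2n-1)``; per-locus
    F_IS = 1 - H_O/H_E, undefined (NaN) at monomorphic loci.  Population
    means are unweighted over loci (see :func:`population_means`).
    """
    rows = []
    pops = np.asarray(ds.populations)
    for pop in ds.population_labels():
        sub = ds.calls[pops == pop]
        for j, locus in enumerate(ds.locus_names):
            res = _per_locus_het(sub[:, j, :])
            if res is None:
                continue
            h_obs, h_exp, n = res
            fis = 1.0 - h_obs / h_exp if h_exp > 0 else np.nan
            rows.append(
                {"population": pop, "locus": locus, "n_typed": n,
                 "H_O": h_obs, "H_E": h_exp, "F_IS": fis}
            )
    return pd.DataFrame(rows)


def population_means(per_locus: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Unweighted means over loci per population (NaN cells excluded)."""
    return per_locus.groupby("population", sort=False)[columns].mean()


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def _rarefied_count(counts: np.ndarray, g: int) -> float:
    """Expected distinct alleles in a random subsample of g gene copies.

    ``sum_a [1 - C(N - N_a, g) / C(N, g)]`` evaluated through log-gamma for
    numerical range.
    """
    N = int(counts.sum())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds available copies N={N}")

    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    for n_a in counts:
        rest = N - int(n_a)
        miss = 0.0 if rest < g else np.exp(log_comb(rest, g) - log_comb(N, g))
        total += 1.0 - miss
    return total


def auto_rarefaction_size(ds: GenotypeDataset) -> int:
    """Default rarefaction size: twice the smallest per-(population, locus)
    typed-genotype count (gene-copy units)."""
    pops = np.asarray(ds.populations)
    smallest = None
    for pop in ds.population_labels():
        sub = ds.calls[pops == pop]
        typed = (sub[:, :, 0] != MISSING).sum(axis=0)
        m = int(typed[typed > 0].min()) if (typed > 0).any() else None
        if m is not None:
            smallest = m if smallest is None else min(smallest, m)
    if smallest is None:
        raise ValueError("no typed genotypes anywhere")
    return 2 * smallest


def rarefied_allelic_richness(
    ds: GenotypeDataset, g: int | None = None
) -> tuple[pd.DataFrame, int]:
    """Per-(population, locus) rarefied allelic richness A_R and the g used.

    ``g`` defaults to :func:`auto_rarefaction_size`.  A (population, locus)
    cell with fewer than ``g`` typed gene copies raises, naming the
    limiting cell.
    """
    if g is None:
        g = auto_rarefaction_size(ds)
    if g < 2:
        raise ValueError("g must be >= 2")
    freqs = allele_frequencies(ds)
    rows = []
    for (pop, locus), entry in freqs.entries.items():
        counts = np.round(entry.freqs * 2 * entry.n_typed).astype(int)
        if 2 * entry.n_typed < g:
            raise ValueError(
                f"g={g} exceeds the {2 * entry.n_typed} typed gene copies at "
                f"({pop!r}, {locus!r})"
            )
        rows.append(
            {"population": pop, "locus": locus, "A_R": _rarefied_count(counts, g)}
        )
    return pd.DataFrame(rows), g


# ---------------------------------------------------------------------------
# Private alleles
# ---------------------------------------------------------------------------

def private_allele_count(ds: GenotypeDataset) -> pd.Series:
    """Number of alleles observed in exactly one population, per population,
    summed over loci."""
    pops = ds.population_labels()
    if len(pops) < 2:
        raise ValueError("private alleles are undefined for a single population")
    freqs = allele_frequencies(ds)
    counts = {p: 0 for p in pops}
    for locus in ds.locus_names:
        holders: dict[int, list[str]] = {}
        for pop in pops:
            if (pop, locus) not in freqs:
                continue
            for a in freqs[(pop, locus)].alleles:
                holders.setdefault(int(a), []).append(pop)
        for a, hs in holders.items():
            if len(hs) == 1:
                counts[hs[0]] += 1
    return pd.Series(counts, name="A_p")


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo exact test
# ---------------------------------------------------------------------------

def _hwe_locus_pvalue(
    typed: np.ndarray, n_shuffles: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo exact HWE p-value conditional on allele counts.

    The conditional probability of a genotype configuration given allele
    counts is proportional to ``2^h / prod n_ij!``; the test repeatedly
    re-pairs the observed gene copies at random and counts configurations
    at most as probable as the observed one ((b+1)/(m+1) correction).
    """
    n = typed.shape[0]
    copies = typed.ravel()
    alleles, inv = np.unique(copies, return_inverse=True)
    K = len(alleles)
    if K < 2:
        return 1.0

    def log_weight(pairs: np.ndarray) -> float:
        a, b = np.minimum(pairs[:, 0], pairs[:, 1]), np.maximum(pairs[:, 0], pairs[:, 1])
        ids = a * K + b
        cnt = np.bincount(ids, minlength=K * K)
        h = int(np.sum(a != b))
        return h * np.log(2.0) - float(np.sum(gammaln(cnt + 1)))

    obs = log_weight(inv.reshape(-1, 2))
    # batch-shuffle the 2n copies: argsort of random keys gives independent
    # permutations per row
    B = n_shuffles
    keys = rng.random((B, 2 * n))
    order = np.argsort(keys, axis=1)
    shuffled = inv[order]
    a = np.minimum(shuffled[:, 0::2], shuffled[:, 1::2])
    b = np.maximum(shuffled[:, 0::2], shuffled[:, 1::2])
    ids = a * K + b + np.arange(B)[:, None] * (K * K)
    cnt = np.bincount(ids.ravel(), minlength=B * K * K).reshape(B, K * K)
    h = (a != b).sum(axis=1)
    lw = h * np.log(2.0) - gammaln(cnt + 1).sum(axis=1)
    hits = int(np.sum(lw <= obs + 1e-12))
    return (hits + 1) / (B + 1)


def hwe_exact_test(
    ds: GenotypeDataset, n_shuffles: int = 10000, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Monte-Carlo exact test of Hardy-Weinberg proportions.

    Returns per-(population, locus) p-values (monomorphic loci get p = 1
    with ``monomorphic=True``) and a per-population combined p-value
    (Fisher's method over polymorphic loci).
    """
    if n_shuffles < 999:
        raise ValueError("n_shuffles must be >= 999")
    rng = np.random.default_rng(seed)
    rows = []
    pops = np.asarray(ds.populations)
    for pop in ds.population_labels():
        sub = ds.calls[pops == pop]
        for j, locus in enumerate(ds.locus_names):
            col = sub[:, j, :]
            typed = col[col[:, 0] != MISSING]
            if typed.shape[0] == 0:
                continue
            mono = len(np.unique(typed)) < 2
            p = 1.0 if mono else _hwe_locus_pvalue(typed, n_shuffles, rng)
            rows.append(
                {"population": pop, "locus": locus, "p_value": p, "monomorphic": mono}
            )
    per_locus = pd.DataFrame(rows)
    combined = {}
    for pop, grp in per_locus.groupby("population", sort=False):
        ps = grp.loc[~grp["monomorphic"], "p_value"].to_numpy()
        if len(ps) == 0:
            combined[pop] = 1.0
        else:
            x = -2.0 * np.sum(np.log(ps))
            combined[pop] = float(stats.chi2.sf(x, 2 * len(ps)))
    return per_locus, pd.Series(combined, name="P_HWE")


# ---------------------------------------------------------------------------
# Multilocus linkage disequilibrium (standardized index of association)
# ---------------------------------------------------------------------------

@dataclass
class AssociationIndexResult:
    rbar_d: float
    p_perm: float
    n_perm: int


def _locus_distance_matrices(ds: GenotypeDataset) -> list[np.ndarray]:
    """Per-locus pairwise allele-mismatch distances (0/1/2), NaN where
    either individual is untyped."""
    n = ds.n_individuals
    mats = []
    for j in range(ds.n_loci):
        col = ds.calls[:, j, :]
        a, b = col[:, 0], col[:, 1]
        typed = a != MISSING
        # multiset intersection of sorted pairs (a1,a2), (b1,b2): the best
        # of the straight and crossed matchings
        eq = (
            (a[:, None] == a[None, :]).astype(int)
            + (b[:, None] == b[None, :]).astype(int)
        )
        cross = (a[:, None] == b[None, :]).astype(int) + (b[:, None] == a[None, :]).astype(int)
        shared = np.maximum(eq, cross)
        d = (2 - shared).astype(float)
        d[~typed, :] = np.nan
        d[:, ~typed] = np.nan
        np.fill_diagonal(d, np.nan)
        mats.append(d)
    return mats


def _rbar_d(mats: list[np.ndarray], iu: tuple[np.ndarray, np.ndarray]) -> float:
    vecs = [m[iu] for m in mats]
    L = len(vecs)
    num = den = 0.0
    for l in range(L):
        for m in range(l + 1, L):
            ok = ~np.isnan(vecs[l]) & ~np.isnan(vecs[m])
            if ok.sum() < 2:
                continue
            x, y = vecs[l][ok], vecs[m][ok]
            vx, vy = x.var(), y.var()
            if vx <= 0 or vy <= 0:
                continue
            num += float(np.mean((x - x.mean()) * (y - y.mean())))
            den += float(np.sqrt(vx * vy))
    return num / den if den > 0 else 0.0


def multilocus_ld_test(
    ds: GenotypeDataset, n_perm: int = 999, seed: int = 0
) -> AssociationIndexResult:
    """Standardized index of association r̄_d with a permutation test.

    The null shuffles genotypes among individuals independently per locus,
    which preserves single-locus structure but destroys between-locus
    association; p is the fraction of permuted r̄_d at least the observed
    ((b+1)/(m+1) corrected).
    """
    if ds.n_loci < 2:
        raise ValueError("need >= 2 loci")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    mats = _locus_distance_matrices(ds)
    poly = [m for m in mats if np.nanvar(m) > 0]
    if len(poly) < 2:
        raise ValueError("need >= 2 polymorphic loci")
    n = ds.n_individuals
    iu = np.triu_indices(n, k=1)
    obs = _rbar_d(poly, iu)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_mats = []
        for m in poly:
            pi = rng.permutation(n)
            perm_mats.append(m[np.ix_(pi, pi)])
        if _rbar_d(perm_mats, iu) >= obs - 1e-12:
            hits += 1
    return AssociationIndexResult(
        rbar_d=obs, p_perm=(hits + 1) / (n_perm + 1), n_perm=n_perm
    )


# ---------------------------------------------------------------------------
# g2 identity disequilibrium
# ---------------------------------------------------------------------------

def _g2_statistic(het: np.ndarray, typed: np.ndarray) -> float:
    """Identity-disequilibrium g2 from a heterozygosity indicator matrix.

    ``het`` is (n, L) with 1 = heterozygous (0 where untyped); ``typed``
    marks scored genotypes.  For every locus pair the within-individual
    joint-heterozygosity rate is compared with its between-individual
    independence expectation, pooled over pairs with missing-data weights;
    g2 is the pooled ratio minus 1 and is 0 under no inbreeding variance.
    """
    h = het * typed
    n, L = h.shape
    ch = h.sum(axis=0).astype(float)       # per-locus het totals
    ct = typed.sum(axis=0).astype(float)   # per-locus typed totals
    # within-individual products over locus pairs
    rs_h = h.sum(axis=1)
    within_num = float(np.sum(rs_h**2) - np.sum(h * h))          # sum_{k != l} h_ik h_il
    rs_t = typed.sum(axis=1)
    within_den = float(np.sum(rs_t**2) - np.sum(typed * typed))
    # between-individual products: sum_{i != j} h_ik h_jl over k != l
    tot_pairs_h = float(np.sum(ch[:, None] * ch[None, :]) - np.sum(ch**2))
    between_num = tot_pairs_h - within_num
    tot_pairs_t = float(np.sum(ct[:, None] * ct[None, :]) - np.sum(ct**2))
    between_den = tot_pairs_t - within_den
    if within_den <= 0 or between_den <= 0 or between_num <= 0:
        return 0.0
    return (within_num / within_den) / (between_num / between_den) - 1.0


def g2_inbreeding_test(
    ds: GenotypeDataset, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """g2 identity-disequilibrium inbreeding test per population.

    Under inbreeding variance, heterozygosity is correlated across loci and
    g2 > 0.  The null permutes the single-locus heterozygosity indicators
    among typed individuals within each locus; P_g2 is the fraction of
    permuted g2 at least the observed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pops = np.asarray(ds.populations)
    for pop in ds.population_labels():
        sub = ds.calls[pops == pop]
        typed = (sub[:, :, 0] != MISSING).astype(float)
        het = ((sub[:, :, 0] != sub[:, :, 1]) & (sub[:, :, 0] != MISSING)).astype(float)
        if typed.shape[0] < 2 or typed.shape[1] < 2:
            rows.append({"population": pop, "g2": np.nan, "P_g2": np.nan})
            continue
        obs = _g2_statistic(het, typed)
        hits = 0
        for _ in range(n_perm):
            hp = het.copy()
            tp = typed.copy()
            for l in range(het.shape[1]):
                idx = np.flatnonzero(typed[:, l] > 0)
                hp[idx, l] = het[rng.permutation(idx), l]
                tp[:, l] = typed[:, l]
            if _g2_statistic(hp, tp) >= obs - 1e-12:
                hits += 1
        rows.append(
            {"population": pop, "g2": obs, "P_g2": (hits + 1) / (n_perm + 1)}
        )
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Diversity report (Table-2-shaped panel)
# ---------------------------------------------------------------------------

def diversity_report(
    ds: GenotypeDataset,
    g: int | None = None,
    n_perm: int = 1000,
    n_shuffles: int = 10000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """One row per population: A_R, A_p, H_E, H_O, F_IS, P_HWE, g2, P_g2.

    Returns the full-precision frame (indexed by population) and a run
    metadata dict (rarefaction g, seeds, permutation counts).
    """
    het = heterozygosity_summary(ds)
    means = population_means(het, ["H_O", "H_E", "F_IS"])
    ar, g_used = rarefied_allelic_richness(ds, g)
    ar_mean = ar.groupby("population", sort=False)["A_R"].mean()
    ap = private_allele_count(ds)
    _, p_hwe = hwe_exact_test(ds, n_shuffles=n_shuffles, seed=seed)
    g2 = g2_inbreeding_test(ds, n_perm=n_perm, seed=seed + 1)
    table = pd.DataFrame(
        {
            "A_R": ar_mean,
            "A_p": ap,
            "H_E": means["H_E"],
            "H_O": means["H_O"],
            "F_IS": means["F_IS"],
            "P_HWE": p_hwe,
            "g2": g2["g2"],
            "P_g2": g2["P_g2"],
        }
    ).loc[ds.population_labels()]
    meta = {
        "g": g_used,
        "n_perm": n_perm,
        "n_shuffles": n_shuffles,
        "seed": seed,
        "fis_definition": "1 - H_O/H_E with unbiased H_E, per locus, "
                          "unweighted mean over loci",
    }
    return table, meta


def render_diversity_table(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Round to the 2-decimal reporting precision and mark significant
    p-values (and their statistics) with ``**`` fences."""
    out = table.round(2).astype(object)
    for stat_col, p_col in (("F_IS", "P_HWE"), ("g2", "P_g2")):
        sig = table[p_col] <= alpha
        for col in (stat_col, p_col):
            out.loc[sig, col] = [f"**{v:.2f}**" for v in table.loc[sig, col].round(2)]
    return out


# ---------------------------------------------------------------------------
# Diversity vs. introduction history
# ---------------------------------------------------------------------------

def retention_ratio(
    table: pd.DataFrame, pop: str, reference: str
) -> tuple[float, int]:
    """Percent of the reference population's allelic richness retained in
    ``pop``: ``100 * A_R(pop) / A_R(reference)``.

    Returns the full-precision percentage and its integer-rounded report
    value.
    """
    for label in (pop, reference):
        if label not in table.index:
            raise KeyError(f"population {label!r} not in diversity table")
    ref = float(table.loc[reference, "A_R"])
    if ref <= 0:
        raise ValueError("reference A_R must be positive")
    value = 100.0 * float(table.loc[pop, "A_R"]) / ref
    return value, int(round(value))


@dataclass
class StepsRegressionResult:
    slope: float
    intercept: float
    F_statistic: float
    df_num: int
    df_den: int
    p_value: float
    n_points: int


def steps_regression(
    table: pd.DataFrame,
    history: ImportationHistory,
    response: str = "A_R",
    extra_steps: dict[str, int] | None = None,
) -> StepsRegressionResult:
    """OLS of population-mean diversity on introduction-step count.

    Step counts come from the history's shortest directed path from the
    native range; ``extra_steps`` supplies counts for populations outside
    the ledger (e.g. a native-range collection site at step 0).
    Populations without a step count are excluded.
    """
    steps_map = dict(history.step_counts())
    if extra_steps:
        steps_map.update(extra_steps)
    pairs = [
        (steps_map[p], float(table.loc[p, response]))
        for p in table.index
        if p in steps_map and np.isfinite(table.loc[p, response])
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 populations with step counts")
    x = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([b for _, b in pairs], dtype=float)
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("step counts are constant; regression undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    ssr = float(np.sum((fitted - y.mean()) ** 2))
    sse = float(np.sum((y - fitted) ** 2))
    df_den = n - 2
    if ssr <= 1e-300:
        f_stat, p = 0.0, 1.0
    elif sse <= 1e-300:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ssr / 1.0) / (sse / df_den)
        p = float(stats.f.sf(f_stat, 1, df_den))
    return StepsRegressionResult(slope, intercept, f_stat, 1, df_den, p, n)


@dataclass
class DiversityComparisonResult:
    statistic: float
    p_global: float
    pairwise: pd.DataFrame   # pop_a, pop_b, difference, p_raw, p_adjusted
    response: str
    n_perm: int


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def population_diversity_comparison(
    ds: GenotypeDataset,
    response: str = "A_R",
    n_perm: int = 999,
    seed: int = 0,
    g: int | None = None,
) -> DiversityComparisonResult:
    """Locus-blocked permutation test of diversity differences among
    populations.

    Loci are blocks: the test statistic is the variance across populations
    of the per-population mean of the per-locus response, and the null
    permutes population labels within each locus row.  Pairwise contrasts
    use the same scheme restricted to each pair, with Benjamini-Hochberg
    adjustment.
    """
    if response == "A_R":
        per_locus, _ = rarefied_allelic_richness(ds, g)
        value_col = "A_R"
    elif response == "H_E":
        per_locus = heterozygosity_summary(ds)
        value_col = "H_E"
    else:
        raise ValueError("response must be 'A_R' or 'H_E'")
    pops = ds.population_labels()
    if len(pops) < 2 or ds.n_loci < 2:
        raise ValueError("need >= 2 populations and >= 2 loci")
    X = (
        per_locus.pivot_table(index="locus", columns="population", values=value_col)
        .reindex(columns=pops)
        .to_numpy()
    )
    rng = np.random.default_rng(seed)

    def stat(mat: np.ndarray) -> float:
        col_means = np.nanmean(mat, axis=0)
        return float(np.var(col_means))

    def perm_rows(mat: np.ndarray) -> np.ndarray:
        out = mat.copy()
        for r in range(mat.shape[0]):
            out[r] = mat[r, rng.permutation(mat.shape[1])]
        return out

    obs = stat(X)
    if not np.isfinite(obs) or obs == 0:
        p_global = 1.0
    else:
        hits = sum(stat(perm_rows(X)) >= obs - 1e-15 for _ in range(n_perm))
        p_global = (hits + 1) / (n_perm + 1)

    pair_rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub = X[:, [i, j]]
            d_obs = abs(np.nanmean(sub[:, 0]) - np.nanmean(sub[:, 1]))
            hits = sum(
                abs(np.diff(np.nanmean(perm_rows(sub), axis=0))[0]) >= d_obs - 1e-15
                for _ in range(n_perm)
            )
            pair_rows.append(
                {"pop_a": pops[i], "pop_b": pops[j],
                 "difference": float(np.nanmean(sub[:, 0]) - np.nanmean(sub[:, 1])),
                 "p_raw": (hits + 1) / (n_perm + 1)}
            )
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_adjusted"] = _bh_adjust(pairwise["p_raw"].to_numpy())
    return DiversityComparisonResult(obs, p_global, pairwise, response, n_perm)
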