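"""Data model and I/O for codominant multilocus microsatellite genotypes.

A :class:`GenotypeDataset` holds diploid allele calls (integer fragment
lengths) for a set of individuals grouped into populations, together with
locus metadata.  Genotypes are unordered allele pairs; a missing call is the
sentinel :data:`MISSING` internally, serialised as ``-9`` (STRUCTURE
convention) or an empty cell (CSV dialects).

Marker-QC operations live here as well: per-population allele frequencies,
the Brookfield (1996) null-allele frequency estimator, genotype accumulation
curves, and missingness filtering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "LocusInfo",
    "GenotypeDataset",
    "AlleleFreqTable",
    "NullAlleleEstimate",
    "read_genotype_table",
    "write_genotype_table",
    "write_structure_format",
    "allele_frequencies",
    "null_allele_frequency",
    "genotype_accumulation_curve",
    "filter_dataset",
]

#: Internal sentinel for a missing allele call (also the STRUCTURE file code).
MISSING: int = -9


class GenotypeDataError(ValueError):
    """Malformed genotype data (bad allele codes, inconsistent rows)."""


class GenotypeParseError(GenotypeDataError):
    """A file could not be parsed under the requested dialect."""


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one microsatellite locus.

    Parameters
    ----------
    name
        Locus name, unique within a dataset.
    motif_length
        Repeat-motif length in bp (3 for a trinucleotide), if known.
    species_panel
        Label of the species-specific marker panel the locus belongs to
        (used by hybrid cross-amplification calls).
    """

    name: str
    motif_length: int | None = None
    species_panel: str | None = None

    def __post_init__(self) -> None:
        if self.motif_length is not None and self.motif_length < 1:
            raise GenotypeDataError(
                f"locus {self.name!r}: motif_length must be >= 1"
            )


class GenotypeDataset:
    """Diploid multilocus genotypes with population labels.

    Parameters
    ----------
    individuals
        Individual identifiers (unique).
    populations
        Population label per individual, parallel to ``individuals``.
    loci
        Locus metadata (or bare names) defining column order.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele codes
        are positive integers, missing calls are :data:`MISSING` in both
        slots.  Pairs are unordered and stored sorted.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        populations: Sequence[str],
        loci: Sequence[LocusInfo | str],
        calls: np.ndarray,
    ) -> None:
        self.individuals = [str(i) for i in individuals]
        self.populations = [str(p) for p in populations]
        self.loci = [
            l if isinstance(l, LocusInfo) else LocusInfo(str(l)) for l in loci
        ]
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise GenotypeDataError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        if len(self.populations) != len(self.individuals):
            raise GenotypeDataError("one population label per individual required")
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeDataError("individual IDs must be unique")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise GenotypeDataError("locus names must be unique")
        # Half-missing genotypes are not representable: a call is either a
        # full unordered pair of positive codes or entirely MISSING.
        one_missing = (calls == MISSING).sum(axis=2) == 1
        if one_missing.any():
            i, l = np.argwhere(one_missing)[0]
            raise GenotypeDataError(
                f"half-missing call for individual {self.individuals[i]!r} "
                f"at locus {names[l]!r}"
            )
        bad = (calls <= 0) & (calls != MISSING)
        if bad.any():
            i, l, _ = np.argwhere(bad)[0]
            raise GenotypeDataError(
                f"non-positive allele code for individual "
                f"{self.individuals[i]!r} at locus {names[l]!r}"
            )
        self.calls = np.sort(calls, axis=2)

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_of(self, individual: str) -> str:
        return self.populations[self.individuals.index(individual)]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)`` mask of missing genotypes."""
        return self.calls[:, :, 0] == MISSING

    # -- subsetting ----------------------------------------------------------

    def subset(
        self,
        *,
        populations: Iterable[str] | None = None,
        individuals: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeDataset":
        """Return a new dataset restricted to the given labels (order kept)."""
        ind_idx = np.arange(self.n_individuals)
        if populations is not None:
            keep = set(populations)
            missing_pops = keep - set(self.populations)
            if missing_pops:
                raise KeyError(f"unknown populations: {sorted(missing_pops)}")
            ind_idx = ind_idx[[p in keep for p in self.populations]]
        if individuals is not None:
            order = {name: i for i, name in enumerate(self.individuals)}
            try:
                chosen = [order[name] for name in individuals]
            except KeyError as exc:
                raise KeyError(f"unknown individual {exc.args[0]!r}") from None
            ind_idx = np.array([i for i in chosen if i in set(ind_idx)], dtype=int)
        loc_idx = np.arange(self.n_loci)
        if loci is not None:
            order_l = {name: i for i, name in enumerate(self.locus_names)}
            try:
                loc_idx = np.array([order_l[name] for name in loci], dtype=int)
            except KeyError as exc:
                raise KeyError(f"unknown locus {exc.args[0]!r}") from None
        return GenotypeDataset(
            [self.individuals[i] for i in ind_idx],
            [self.populations[i] for i in ind_idx],
            [self.loci[i] for i in loc_idx],
            self.calls[np.ix_(ind_idx, loc_idx)],
        )

    def relabel(self, mapping: Mapping[str, str]) -> "GenotypeDataset":
        """Return a copy with population labels renamed through ``mapping``."""
        return GenotypeDataset(
            self.individuals,
            [mapping.get(p, p) for p in self.populations],
            self.loci,
            self.calls,
        )

    def concat(self, other: "GenotypeDataset") -> "GenotypeDataset":
        """Stack two datasets sharing the same loci."""
        if self.locus_names != other.locus_names:
            raise GenotypeDataError("datasets have different loci")
        return GenotypeDataset(
            self.individuals + other.individuals,
            self.populations + other.populations,
            self.loci,
            np.concatenate([self.calls, other.calls], axis=0),
        )

    # -- conversion ----------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format frame: individual, population, locus, allele1/2."""
        n, L = self.n_individuals, self.n_loci
        return pd.DataFrame(
            {
                "individual": np.repeat(self.individuals, L),
                "population": np.repeat(self.populations, L),
                "locus": np.tile(self.locus_names, n),
                "allele1": self.calls[:, :, 0].ravel(),
                "allele2": self.calls[:, :, 1].ravel(),
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"<GenotypeDataset {self.n_individuals} individuals x "
            f"{self.n_loci} loci, {len(self.population_labels())} populations>"
        )


# ---------------------------------------------------------------------------
# I/O dialects
# ---------------------------------------------------------------------------

DIALECTS = ("native_csv", "structure_text", "genalex_csv")


def read_genotype_table(path: str | Path, dialect: str = "native_csv") -> GenotypeDataset:
    """Read a genotype table in one of the supported dialects.

    ``native_csv`` is a tidy table (individual, population, locus,
    allele1, allele2; empty cells = missing), ``structure_text`` is the
    two-rows-per-individual integer matrix with ``-9`` for missing, and
    ``genalex_csv`` is the GenAlEx codominant layout (count header rows,
    two columns per locus).
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    text = path.read_text(encoding="utf-8")
    if dialect == "native_csv":
        return _read_native_csv(text)
    if dialect == "structure_text":
        return _read_structure_text(text)
    return _read_genalex_csv(text)


def _read_native_csv(text: str) -> GenotypeDataset:
    df = pd.read_csv(io.StringIO(text), dtype={"individual": str, "population": str, "locus": str})
    required = {"individual", "population", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(
            f"native_csv header must contain {sorted(required)}; got {list(df.columns)}"
        )
    loci: list[str] = list(dict.fromkeys(df["locus"]))
    individuals: list[str] = list(dict.fromkeys(df["individual"]))
    pop_of: dict[str, str] = {}
    for ind, pop in zip(df["individual"], df["population"]):
        if ind in pop_of and pop_of[ind] != pop:
            raise GenotypeDataError(f"individual {ind!r} has conflicting population labels")
        pop_of[ind] = pop
    ind_i = {v: i for i, v in enumerate(individuals)}
    loc_i = {v: i for i, v in enumerate(loci)}
    calls = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    a1 = df["allele1"].to_numpy()
    a2 = df["allele2"].to_numpy()
    for row, (ind, loc) in enumerate(zip(df["individual"], df["locus"])):
        x, y = a1[row], a2[row]
        if pd.isna(x) != pd.isna(y):
            raise GenotypeDataError(
                f"half-missing call for individual {ind!r} at locus {loc!r}"
            )
        if not pd.isna(x):
            calls[ind_i[ind], loc_i[loc]] = (int(x), int(y))
    return GenotypeDataset(individuals, [pop_of[i] for i in individuals], loci, calls)


def _read_structure_text(text: str) -> GenotypeDataset:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise GenotypeParseError("empty STRUCTURE file")
    loci = lines[0].split()
    rows = [ln.split() for ln in lines[1:]]
    if len(rows) % 2:
        raise GenotypeParseError(
            f"STRUCTURE file has {len(rows)} genotype rows; expected an even "
            "number (two per diploid individual)"
        )
    for k, r in enumerate(rows):
        if len(r) != len(loci) + 2:
            raise GenotypeParseError(
                f"line {k + 2}: expected {len(loci) + 2} fields, got {len(r)}"
            )
    individuals, populations = [], []
    calls = np.full((len(rows) // 2, len(loci), 2), MISSING, dtype=np.int64)
    for i in range(0, len(rows), 2):
        r1, r2 = rows[i], rows[i + 1]
        if r1[0] != r2[0] or r1[1] != r2[1]:
            raise GenotypeDataError(
                f"rows {i + 2}-{i + 3}: paired rows disagree on individual/population"
            )
        individuals.append(r1[0])
        populations.append(r1[1])
        try:
            calls[i // 2, :, 0] = [int(v) for v in r1[2:]]
            calls[i // 2, :, 1] = [int(v) for v in r2[2:]]
        except ValueError as exc:
            raise GenotypeParseError(f"line {i + 2}: non-integer allele code ({exc})")
    half = (calls == MISSING).sum(axis=2) == 1
    if half.any():
        i, l = np.argwhere(half)[0]
        raise GenotypeDataError(
            f"half-missing call for individual {individuals[i]!r} at locus {loci[l]!r}"
        )
    return GenotypeDataset(individuals, populations, loci, calls)


def _read_genalex_csv(text: str) -> GenotypeDataset:
    raw = list(pd.read_csv(io.StringIO(text), header=None, dtype=str).itertuples(index=False, name=None))
    if len(raw) < 4:
        raise GenotypeParseError("GenAlEx file too short (needs 3 header rows + data)")
    try:
        n_loci = int(float(raw[0][0]))
        n_ind = int(float(raw[0][1]))
    except (TypeError, ValueError):
        raise GenotypeParseError("line 1: GenAlEx count row must start with n_loci, n_individuals")
    header = raw[2]
    loci = [str(header[2 + 2 * j]) for j in range(n_loci)]
    individuals, populations = [], []
    calls = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    data = raw[3 : 3 + n_ind]
    if len(data) < n_ind:
        raise GenotypeParseError(
            f"GenAlEx file declares {n_ind} individuals but has {len(data)} data rows"
        )
    for i, row in enumerate(data):
        individuals.append(str(row[0]))
        populations.append(str(row[1]))
        for j in range(n_loci):
            x, y = row[2 + 2 * j], row[3 + 2 * j]
            empty_x = x is None or (isinstance(x, float) and np.isnan(x)) or str(x).strip() in ("", "0", "nan")
            empty_y = y is None or (isinstance(y, float) and np.isnan(y)) or str(y).strip() in ("", "0", "nan")
            if empty_x != empty_y:
                raise GenotypeDataError(
                    f"half-missing call for individual {individuals[-1]!r} at locus {loci[j]!r}"
                )
            if not empty_x:
                calls[i, j] = (int(float(x)), int(float(y)))
    return GenotypeDataset(individuals, populations, loci, calls)


def write_genotype_table(ds: GenotypeDataset, path: str | Path, dialect: str = "native_csv") -> None:
    """Write ``ds`` in the named dialect (inverse of :func:`read_genotype_table`)."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "native_csv":
        df = ds.to_dataframe()
        df["allele1"] = df["allele1"].where(df["allele1"] != MISSING, other=pd.NA)
        df["allele2"] = df["allele2"].where(df["allele2"] != MISSING, other=pd.NA)
        df.to_csv(path, index=False)
    elif dialect == "structure_text":
        write_structure_format(ds, path)
    else:
        _write_genalex_csv(ds, path)


def write_structure_format(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the two-rows-per-individual STRUCTURE text format (``-9`` missing)."""
    lines = [" ".join(ds.locus_names)]
    for i, (ind, pop) in enumerate(zip(ds.individuals, ds.populations)):
        for slot in (0, 1):
            fields = [ind, pop] + [str(int(a)) for a in ds.calls[i, :, slot]]
            lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_genalex_csv(ds: GenotypeDataset, path: str | Path) -> None:
    pops = ds.population_labels()
    sizes = [sum(p == q for q in ds.populations) for p in pops]
    row1 = [str(ds.n_loci), str(ds.n_individuals), str(len(pops))] + [str(s) for s in sizes]
    row2 = ["introtrace export", ""] + pops
    row3 = ["Ind", "Pop"]
    for name in ds.locus_names:
        row3 += [name, ""]
    width = max(len(row1), len(row2), len(row3), 2 + 2 * ds.n_loci)
    out = []
    for r in (row1, row2, row3):
        out.append(r + [""] * (width - len(r)))
    for i, (ind, pop) in enumerate(zip(ds.individuals, ds.populations)):
        row = [ind, pop]
        for j in range(ds.n_loci):
            a, b = ds.calls[i, j]
            row += (["", ""] if a == MISSING else [str(int(a)), str(int(b))])
        out.append(row + [""] * (width - len(row)))
    pd.DataFrame(out).to_csv(path, index=False, header=False)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class FreqEntry:
    """Allele relative frequencies for one (population, locus) cell."""

    alleles: np.ndarray        # sorted distinct allele codes
    freqs: np.ndarray          # relative frequencies, sum to 1
    n_typed: int               # non-missing diploid genotypes

    def freq_of(self, allele: int) -> float:
        hit = np.searchsorted(self.alleles, allele)
        if hit < len(self.alleles) and self.alleles[hit] == allele:
            return float(self.freqs[hit])
        return 0.0

    def as_dict(self) -> dict[int, float]:
        return {int(a): float(f) for a, f in zip(self.alleles, self.freqs)}


@dataclass
class AlleleFreqTable:
    """Per (population, locus) allele frequency vectors.

    Cells with zero typed genotypes are *absent* (listed in
    ``absent``), never zero-filled.
    """

    entries: dict[tuple[str, str], FreqEntry]
    absent: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, key: tuple[str, str]) -> FreqEntry:
        return self.entries[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries


def allele_frequencies(ds: GenotypeDataset) -> AlleleFreqTable:
    """Count allele copies per (population, locus) into relative frequencies."""
    entries: dict[tuple[str, str], FreqEntry] = {}
    absent: list[tuple[str, str]] = []
    pops = np.asarray(ds.populations)
    for pop in ds.population_labels():
        sub = ds.calls[pops == pop]
        for j, locus in enumerate(ds.locus_names):
            col = sub[:, j, :]
            typed = col[col[:, 0] != MISSING]
            if typed.size == 0:
                absent.append((pop, locus))
                continue
            alleles, counts = np.unique(typed.ravel(), return_counts=True)
            entries[(pop, locus)] = FreqEntry(
                alleles=alleles.astype(np.int64),
                freqs=counts / counts.sum(),
                n_typed=typed.shape[0],
            )
    return AlleleFreqTable(entries=entries, absent=absent)


# ---------------------------------------------------------------------------
# Null alleles (Brookfield 1996, estimator 1)
# ---------------------------------------------------------------------------

@dataclass
class NullAlleleEstimate:
    """Brookfield estimator-1 null-allele frequencies r = (He-Ho)/(1+He).

    ``r`` may be negative when observed heterozygosity exceeds expectation;
    such cells are reported as computed and listed in ``negative``.
    """

    r: dict[tuple[str, str], float]
    negative: list[tuple[str, str]] = field(default_factory=list)
    absent: list[tuple[str, str]] = field(default_factory=list)


def brookfield_r(h_exp: float, h_obs: float) -> float:
    """Closed-form Brookfield (1996) estimator 1: ``(He - Ho) / (1 + He)``."""
    return (h_exp - h_obs) / (1.0 + h_exp)


def null_allele_frequency(ds: GenotypeDataset) -> NullAlleleEstimate:
    """Estimate per-(population, locus) null-allele frequency.

    Uses unbiased expected heterozygosity and the observed heterozygote
    fraction in the Brookfield closed form.
    """
    from .diversity import _per_locus_het  # local import: avoids cycle

    out: dict[tuple[str, str], float] = {}
    negative: list[tuple[str, str]] = []
    absent: list[tuple[str, str]] = []
    pops = np.asarray(ds.populations)
    for pop in ds.population_labels():
        sub = ds.calls[pops == pop]
        for j, locus in enumerate(ds.locus_names):
            stats = _per_locus_het(sub[:, j, :])
            if stats is None:
                absent.append((pop, locus))
                continue
            h_obs, h_exp, _n = stats
            r = brookfield_r(h_exp, h_obs)
            out[(pop, locus)] = r
            if r < 0:
                negative.append((pop, locus))
    return NullAlleleEstimate(r=out, negative=negative, absent=absent)


# ---------------------------------------------------------------------------
# Genotype accumulation curve
# ---------------------------------------------------------------------------

def genotype_accumulation_curve(
    ds: GenotypeDataset, n_resamples: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean distinct multilocus genotypes as loci are subsampled.

    For each ``m`` in ``1..L-1``, draws ``n_resamples`` random subsets of
    ``m`` loci (without replacement) and counts distinct multilocus
    genotypes over all individuals (missing calls compare equal to each
    other only).  Returns a frame with columns ``n_loci``, ``mean``,
    ``sd``, ``min``, ``max``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if ds.n_loci < 2:
        raise ValueError("need at least 2 loci for an accumulation curve")
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(1, ds.n_loci):
        counts = np.empty(n_resamples)
        for b in range(n_resamples):
            chosen = rng.choice(ds.n_loci, size=m, replace=False)
            sub = ds.calls[:, chosen, :].reshape(ds.n_individuals, -1)
            counts[b] = np.unique(sub, axis=0).shape[0]
        rows.append(
            {
                "n_loci": m,
                "mean": counts.mean(),
                "sd": counts.std(ddof=1) if n_resamples > 1 else 0.0,
                "min": counts.min(),
                "max": counts.max(),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Missingness filtering
# ---------------------------------------------------------------------------

def filter_dataset(
    ds: GenotypeDataset,
    max_missing_per_locus: float = 0.25,
    max_missing_per_individual: float = 0.25,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Drop loci then individuals whose missingness exceeds the thresholds.

    Returns the filtered dataset and a removal log (columns ``kind``,
    ``name``, ``missing_fraction``, ``threshold``).  Applying the same
    thresholds to the output is a no-op (idempotent).
    """
    for t in (max_missing_per_locus, max_missing_per_individual):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    log_rows = []
    miss = ds.missing_mask()
    locus_frac = miss.mean(axis=0)
    keep_loci = []
    for j, name in enumerate(ds.locus_names):
        if locus_frac[j] > max_missing_per_locus:
            log_rows.append(
                {"kind": "locus", "name": name,
                 "missing_fraction": float(locus_frac[j]),
                 "threshold": max_missing_per_locus}
            )
        else:
            keep_loci.append(name)
    if not keep_loci:
        raise GenotypeDataError("missingness filter removed every locus")
    ds2 = ds.subset(loci=keep_loci)
    miss2 = ds2.missing_mask()
    ind_frac = miss2.mean(axis=1)
    keep_ind = []
    for i, name in enumerate(ds2.individuals):
        if ind_frac[i] > max_missing_per_individual:
            log_rows.append(
                {"kind": "individual", "name": name,
                 "missing_fraction": float(ind_frac[i]),
                 "threshold": max_missing_per_individual}
            )
        else:
            keep_ind.append(name)
    if not keep_ind:
        raise GenotypeDataError("missingness filter removed every individual")
    out = ds2.subset(individuals=keep_ind)
    log = pd.DataFrame(log_rows, columns=["kind", "name", "missing_fraction", "threshold"])
    return out, log
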