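"""Loaders for the packaged published reference tables.

These tables are report-format mirrors of the global *Neochetina* survey:
the per-site sample bookkeeping, the per-population diversity panel, and
the pairwise differentiation matrix for *N. bruchi*.  They serve as inputs
to the worked bookkeeping ratios (allelic-richness retention, genotype
counts) and as layout references for the reporting code; they are not
outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "reported_sample_sizes",
    "reported_diversity",
    "reported_differentiation_bruchi",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("introtrace.resources").joinpath(name)
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def reported_sample_sizes() -> pd.DataFrame:
    """Genotyped sample sizes per collection site and species."""
    return _read("reported_sample_sizes.csv")


def reported_diversity(species: str | None = None) -> pd.DataFrame:
    """Published per-population diversity panel (A_R, A_p, H_E, H_O, F_IS,
    P_HWE, g2, P_g2), optionally filtered to one species
    ('bruchi' / 'eichhorniae'), indexed by population."""
    df = _read("reported_diversity.csv")
    if species is not None:
        df = df[df["species"] == species].drop(columns="species")
    return df.set_index("population")


def reported_differentiation_bruchi(statistic: str = "JostD") -> pd.DataFrame:
    """Published pairwise differentiation values for *N. bruchi* as a tidy
    frame (pop_a, pop_b, value) for 'FST' or 'JostD'."""
    df = _read("reported_differentiation_bruchi.csv")
    if statistic not in ("FST", "JostD"):
        raise ValueError("statistic must be 'FST' or 'JostD'")
    return df[df["statistic"] == statistic].reset_index(drop=True)
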