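"""Interspecific hybrid detection by cross-amplification of
species-specific marker panels.

Each species' microsatellite primers fail to amplify in the other species,
so an individual whose DNA amplifies at loci from both panels carries
genomic material of both.  At least two amplifying loci from *each* panel
are required before a hybrid is called; the fraction of the minor panel
amplifying grades the call into a first-generation (F1) candidate versus a
later-generation backcross candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .data import MISSING, GenotypeDataset

__all__ = [
    "AmplificationProfile",
    "HybridCall",
    "amplification_profiles",
    "classify_hybrid",
    "hybrid_report",
]


@dataclass(frozen=True)
class AmplificationProfile:
    """Per-panel amplification counts for one individual."""

    individual: str
    panel_a: str
    panel_b: str
    attempted_a: int
    amplified_a: int
    attempted_b: int
    amplified_b: int

    @property
    def fraction_a(self) -> float:
        return self.amplified_a / self.attempted_a if self.attempted_a else 0.0

    @property
    def fraction_b(self) -> float:
        return self.amplified_b / self.attempted_b if self.attempted_b else 0.0


@dataclass(frozen=True)
class HybridCall:
    """Hybrid classification for one individual with the thresholds used."""

    individual: str
    call: str  # NON_HYBRID | F1_CANDIDATE | BACKCROSS_CANDIDATE | UNINFORMATIVE
    amplified_a: int
    amplified_b: int
    minor_fraction: float
    f1_threshold: float
    backcross_band: tuple[float, float]


def amplification_profiles(
    ds: GenotypeDataset,
    panels: Mapping[str, Sequence[str]] | None = None,
) -> list[AmplificationProfile]:
    """Count amplifying loci (>= 1 scored allele) per panel per individual.

    ``panels`` maps two panel names to disjoint locus lists; when omitted
    the panels come from each locus' ``species_panel`` metadata.
    """
    if panels is None:
        panels_d: dict[str, list[str]] = {}
        for loc in ds.loci:
            if loc.species_panel is None:
                raise ValueError(
                    f"locus {loc.name!r} has no species_panel and no panel "
                    "mapping was given"
                )
            panels_d.setdefault(loc.species_panel, []).append(loc.name)
    else:
        panels_d = {k: list(v) for k, v in panels.items()}
    if len(panels_d) != 2:
        raise ValueError(f"exactly two panels required, got {sorted(panels_d)}")
    (name_a, loci_a), (name_b, loci_b) = panels_d.items()
    overlap = set(loci_a) & set(loci_b)
    if overlap:
        raise ValueError(f"loci assigned to both panels: {sorted(overlap)}")
    idx = {name: j for j, name in enumerate(ds.locus_names)}
    ja = [idx[l] for l in loci_a if l in idx]
    jb = [idx[l] for l in loci_b if l in idx]
    amplified = ds.calls[:, :, 0] != MISSING
    out = []
    for i, ind in enumerate(ds.individuals):
        out.append(
            AmplificationProfile(
                individual=ind,
                panel_a=name_a,
                panel_b=name_b,
                attempted_a=len(ja),
                amplified_a=int(amplified[i, ja].sum()),
                attempted_b=len(jb),
                amplified_b=int(amplified[i, jb].sum()),
            )
        )
    return out


def classify_hybrid(
    profile: AmplificationProfile,
    f1_threshold: float = 0.6,
    backcross_band: tuple[float, float] = (0.2, 0.6),
) -> HybridCall:
    """Grade one amplification profile.

    UNINFORMATIVE when fewer than two loci were attempted on either panel;
    NON_HYBRID unless at least two loci amplify on each panel; otherwise
    the minor-panel amplification fraction decides: F1 candidate at or
    above ``f1_threshold``, backcross candidate within ``backcross_band``
    (half-open, upper bound exclusive), NON_HYBRID below the band.
    """
    lo, hi = backcross_band
    if not (0.0 <= lo < hi <= f1_threshold <= 1.0):
        raise ValueError("require 0 <= band_lo < band_hi <= f1_threshold <= 1")
    minor = min(profile.fraction_a, profile.fraction_b)
    if profile.attempted_a < 2 or profile.attempted_b < 2:
        call = "UNINFORMATIVE"
    elif profile.amplified_a < 2 or profile.amplified_b < 2:
        call = "NON_HYBRID"
    elif minor >= f1_threshold:
        call = "F1_CANDIDATE"
    elif lo <= minor < hi:
        call = "BACKCROSS_CANDIDATE"
    else:
        call = "NON_HYBRID"
    return HybridCall(
        individual=profile.individual,
        call=call,
        amplified_a=profile.amplified_a,
        amplified_b=profile.amplified_b,
        minor_fraction=minor,
        f1_threshold=f1_threshold,
        backcross_band=backcross_band,
    )


def hybrid_report(
    ds: GenotypeDataset,
    panels: Mapping[str, Sequence[str]] | None = None,
    f1_threshold: float = 0.6,
    backcross_band: tuple[float, float] = (0.2, 0.6),
) -> pd.DataFrame:
    """Profiles and calls for every individual as a tidy frame."""
    rows = []
    for prof in amplification_profiles(ds, panels):
        call = classify_hybrid(prof, f1_threshold, backcross_band)
        rows.append(
            {
                "individual": prof.individual,
                "panel_a": prof.panel_a,
                "panel_b": prof.panel_b,
                "fraction_a": prof.fraction_a,
                "fraction_b": prof.fraction_b,
                "amplified_a": prof.amplified_a,
                "amplified_b": prof.amplified_b,
                "call": call.call,
            }
        )
    return pd.DataFrame(rows)
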