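"""Importation-history ledger: dated release events with propagule sizes.

The ledger is the documented record of biological-control releases — who
shipped weevils where, when, and how many — and drives both the synthetic
replay (serial founder events and admixture) and the introduction-step
counting used in the diversity-versus-history analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "NATIVE",
    "ImportationEvent",
    "ImportationHistory",
    "read_history",
    "write_history",
    "packaged_ledger",
]

#: Conventional label for the native-range source population.
NATIVE = "NATIVE"


class HistoryError(ValueError):
    """Invalid importation history (cycles, unreachable populations...)."""


@dataclass(frozen=True)
class ImportationEvent:
    """One documented release: ``propagule_size`` founders moved
    ``source`` -> ``destination`` in ``year``."""

    source: str
    destination: str
    year: int
    propagule_size: int
    notes: str = ""

    def __post_init__(self) -> None:
        if self.propagule_size < 1:
            raise HistoryError(
                f"{self.source}->{self.destination} ({self.year}): "
                "propagule_size must be >= 1"
            )
        if self.source == self.destination:
            raise HistoryError(f"self-introduction {self.source}->{self.destination}")


@dataclass
class ImportationHistory:
    """Ordered release events rooted at a native-range population.

    Every non-native population must be reachable from ``native_label``
    through the directed event graph; step counts are shortest directed
    path lengths from the native range.
    """

    events: list[ImportationEvent]
    native_label: str = NATIVE

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.year, e.destination))
        self.validate()

    def populations(self) -> list[str]:
        """All labels, native first, then destinations in event order."""
        seen = {self.native_label: None}
        for e in self.events:
            seen.setdefault(e.source)
            seen.setdefault(e.destination)
        return list(seen)

    def validate(self) -> None:
        steps = self._bfs_steps()
        unreachable = [p for p in self.populations() if p not in steps]
        if unreachable:
            raise HistoryError(
                f"populations not reachable from {self.native_label!r}: {unreachable}"
            )
        for e in self.events:
            # A source must exist (be founded) no later than it exports.
            if e.source != self.native_label:
                founded = min(
                    f.year for f in self.events if f.destination == e.source
                )
                if founded > e.year:
                    raise HistoryError(
                        f"{e.source!r} exports in {e.year} before its first "
                        f"founding event in {founded}"
                    )

    def _bfs_steps(self) -> dict[str, int]:
        adj: dict[str, set[str]] = {}
        for e in self.events:
            adj.setdefault(e.source, set()).add(e.destination)
        steps = {self.native_label: 0}
        frontier = [self.native_label]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):  # breadth-first: minimum path length
                    if v not in steps:
                        steps[v] = steps[u] + 1
                        nxt.append(v)
            frontier = nxt
        return steps

    def step_counts(self) -> dict[str, int]:
        """Introduction steps per population: shortest directed path length
        from the native range (native itself = 0)."""
        return self._bfs_steps()

    def events_into(self, destination: str) -> list[ImportationEvent]:
        return [e for e in self.events if e.destination == destination]

    def propagule_ratio(
        self, numerator: tuple[str, str], denominator: tuple[str, str]
    ) -> float:
        """Percent ratio of total propagule sizes along two routes.

        Each route is a ``(source, destination)`` pair; event sizes along
        the same route are summed.  Returns ``100 * num / den``.
        """
        def total(route: tuple[str, str]) -> int:
            src, dst = route
            sizes = [
                e.propagule_size
                for e in self.events
                if e.source == src and e.destination == dst
            ]
            if not sizes:
                raise KeyError(f"no events on route {src}->{dst}")
            return sum(sizes)

        return 100.0 * total(numerator) / total(denominator)


# ---------------------------------------------------------------------------
# Ledger I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["source", "destination", "year", "propagule_size", "notes"]


def read_history(path: str | Path, native_label: str = NATIVE) -> ImportationHistory:
    """Read a ledger from CSV (columns source, destination, year,
    propagule_size, notes) or JSON (list of event objects)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text(encoding="utf-8"))
    else:
        df = pd.read_csv(path, dtype={"source": str, "destination": str, "notes": str})
        missing = set(_COLUMNS[:4]) - set(df.columns)
        if missing:
            raise HistoryError(f"ledger missing columns: {sorted(missing)}")
        records = df.to_dict("records")
    events = [
        ImportationEvent(
            source=str(r["source"]),
            destination=str(r["destination"]),
            year=int(r["year"]),
            propagule_size=int(r["propagule_size"]),
            notes="" if pd.isna(r.get("notes", "")) else str(r.get("notes", "")),
        )
        for r in records
    ]
    return ImportationHistory(events=events, native_label=native_label)


def write_history(history: ImportationHistory, path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "source": e.source,
            "destination": e.destination,
            "year": e.year,
            "propagule_size": e.propagule_size,
            "notes": e.notes,
        }
        for e in history.events
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2) + "\n", encoding="utf-8")
    else:
        pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def packaged_ledger(species: str) -> ImportationHistory:
    """Load the packaged documented-release ledger for one weevel species.

    ``species`` is ``"bruchi"`` or ``"eichhorniae"``.  Sizes and years not
    stated in the published record are nominal and flagged in the notes
    column of the CSV.
    """
    fname = f"ledger_{species}.csv"
    ref = resources.files("introtrace.resources").joinpath(fname)
    with resources.as_file(ref) as p:
        return read_history(p, native_label="Argentina")
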