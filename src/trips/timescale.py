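"""Geological timescale: stages, durations, and age-range overlaps.

A :class:`Timescale` is an ordered, contiguous sequence of :class:`Stage`
intervals. Ages are in Ma (million years before present), so the *early*
bound of a stage is numerically larger than its *late* bound; durations are
in Myr. A default Mesozoic stage table is shipped with the package (see
``trips/data/mesozoic_stages.csv`` for the provenance of each boundary).
"""

from __future__ import annotations

from collections.abc import Iterator, Sequence
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

#: Tolerance (Ma) used when checking that adjacent stages share a boundary.
CONTIGUITY_TOL = 1e-6


class TimescaleError(ValueError):
    """Raised for invalid stage tables (gaps, overlaps, zero durations)."""


@dataclass(frozen=True)
class Stage:
    """A named geological interval ``[late_bound, early_bound]`` in Ma."""

    name: str
    early_bound: float
    late_bound: float

    def __post_init__(self) -> None:
        if not self.early_bound > self.late_bound:
            raise TimescaleError(
                f"stage {self.name!r}: early_bound ({self.early_bound}) must be "
                f"strictly older than late_bound ({self.late_bound})"
            )

    @property
    def duration(self) -> float:
        """Stage duration d_t in Myr."""
        return self.early_bound - self.late_bound

    def contains(self, age: float) -> bool:
        """Whether ``age`` (Ma) lies in the closed interval of this stage."""
        return self.late_bound <= age <= self.early_bound


def overlap(early: float, late: float, stage: Stage) -> float:
    """Length (Myr) of the intersection of an age range with a stage.

    ``early``/``late`` are the older/younger ends of the range in Ma. A
    zero-length intersection (disjoint ranges, or a shared single point)
    returns 0.0.
    """
    if early < late:
        raise ValueError(f"age range inverted: early={early} < late={late}")
    return max(0.0, min(early, stage.early_bound) - max(late, stage.late_bound))


class Timescale(Sequence):
    """Ordered (old -> young), contiguous, non-overlapping stages."""

    def __init__(self, stages: Sequence[Stage]):
        stages = list(stages)
        if not stages:
            raise TimescaleError("timescale must contain at least one stage")
        for older, younger in zip(stages, stages[1:]):
            if older.early_bound < younger.early_bound:
                raise TimescaleError(
                    f"stages out of order: {older.name!r} before {younger.name!r}"
                )
            gap = older.late_bound - younger.early_bound
            if abs(gap) > CONTIGUITY_TOL:
                kind = "gap" if gap > 0 else "overlap"
                raise TimescaleError(
                    f"{kind} of {abs(gap):g} Myr between {older.name!r} "
                    f"({older.early_bound}-{older.late_bound}) and "
                    f"{younger.name!r} ({younger.early_bound}-{younger.late_bound})"
                )
        self._stages = stages
        self._by_name = {s.name: i for i, s in enumerate(stages)}
        if len(self._by_name) != len(stages):
            raise TimescaleError("duplicate stage names in timescale")

    def __len__(self) -> int:
        return len(self._stages)

    def __iter__(self) -> Iterator[Stage]:
        return iter(self._stages)

    def __getitem__(self, i):
        return self._stages[i]

    def __repr__(self) -> str:
        return (
            f"Timescale({len(self)} stages, {self._stages[0].early_bound}-"
            f"{self._stages[-1].late_bound} Ma)"
        )

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._stages]

    @property
    def durations(self) -> dict[str, float]:
        return {s.name: s.duration for s in self._stages}

    @property
    def span(self) -> float:
        """Total extent in Myr, oldest early bound to youngest late bound."""
        return self._stages[0].early_bound - self._stages[-1].late_bound

    def stage(self, name: str) -> Stage:
        try:
            return self._stages[self._by_name[name]]
        except KeyError:
            raise KeyError(f"no stage named {name!r} in timescale") from None

    def overlaps(self, early: float, late: float) -> dict[str, float]:
        """Overlap in Myr of the age range with every stage (zeros included)."""
        return {s.name: overlap(early, late, s) for s in self._stages}


def load_timescale(path: str | Path) -> Timescale:
    """Read a stage table (CSV: ``name,early_bound,late_bound``) and validate it.

    Lines starting with ``#`` are treated as comments. Rows may appear in
    either chronological direction; they are sorted old -> young.
    """
    df = pd.read_csv(path, comment="#")
    required = {"name", "early_bound", "late_bound"}
    missing = required - set(df.columns)
    if missing:
        raise TimescaleError(f"timescale table missing columns: {sorted(missing)}")
    df = df.sort_values("early_bound", ascending=False)
    stages = [
        Stage(str(r.name), float(r.early_bound), float(r.late_bound))
        for r in df.itertuples(index=False)
    ]
    return Timescale(stages)


def load_default_timescale() -> Timescale:
    """The packaged Mesozoic stage table (Induan through Maastrichtian)."""
    ref = resources.files("trips.data").joinpath("mesozoic_stages.csv")
    with resources.as_file(ref) as path:
        return load_timescale(path)
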