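"""Occurrence-table ingestion, filtering, and stage-binned count matrices.

Reads PaleoDB-style occurrence downloads (one row per fossil observation),
applies rank and exclusion-list filters, assigns each record to a single
geological stage with probability proportional to the overlap of its
reported age range with each stage, and tallies per-taxon per-stage
observation counts. Because the stage assignment is stochastic for records
whose age range spans several stages, analyses are run on replicated count
matrices (100 by default) downstream.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .timescale import Timescale

logger = logging.getLogger(__name__)

#: Default column mapping for PaleoDB occurrence downloads.
DEFAULT_COLUMNS = {
    "taxon": "accepted_name",
    "rank": "accepted_rank",
    "genus": "genus",
    "early": "max_ma",
    "late": "min_ma",
    "collection": "collection_no",
}


class OccurrenceFormatError(ValueError):
    pass


class OutOfTimescaleError(ValueError):
    pass


def _norm(name: str) -> str:
    """Case/whitespace-normalised taxon name used for identity and matching."""
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


@dataclass(frozen=True)
class OccurrenceRecord:
    """One fossil observation: a taxon at a collection with an age range (Ma)."""

    taxon_name: str
    matched_rank: str
    genus_name: str
    early_age: float
    late_age: float
    collection_id: str = ""

    def __post_init__(self):
        if not str(self.taxon_name).strip():
            raise OccurrenceFormatError("taxon_name must be nonempty")
        if self.early_age < self.late_age:
            raise OccurrenceFormatError(
                f"{self.taxon_name!r}: early_age ({self.early_age}) < "
                f"late_age ({self.late_age})"
            )


@dataclass
class ExclusionLists:
    """Names to drop: invalid taxa, ichnotaxa, ootaxa, and ichno-genera."""

    invalid_taxa: set[str] = field(default_factory=set)
    ichnotaxa: set[str] = field(default_factory=set)
    ootaxa: set[str] = field(default_factory=set)
    ichno_genera: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.invalid_taxa = {_norm(n) for n in self.invalid_taxa}
        self.ichnotaxa = {_norm(n) for n in self.ichnotaxa}
        self.ootaxa = {_norm(n) for n in self.ootaxa}
        self.ichno_genera = {_norm(n) for n in self.ichno_genera}

    @classmethod
    def from_files(
        cls,
        invalid: str | Path | None = None,
        ichno: str | Path | None = None,
        oo: str | Path | None = None,
        ichno_genera: str | Path | None = None,
    ) -> "ExclusionLists":
        """Build from plain-text files, one name per line; '#' comments allowed."""

        def read(p):
            if p is None:
                return set()
            lines = Path(p).read_text().splitlines()
            return {l.strip() for l in lines if l.strip() and not l.startswith("#")}

        return cls(read(invalid), read(ichno), read(oo), read(ichno_genera))

    def excludes(self, record: OccurrenceRecord) -> bool:
        name = _norm(record.taxon_name)
        genus = _norm(record.genus_name) if record.genus_name else ""
        return (
            name in self.invalid_taxa
            or name in self.ichnotaxa
            or name in self.ootaxa
            or genus in self.ichno_genera
        )


def read_occurrences(
    path: str | Path, columns: dict[str, str] | None = None
) -> list[OccurrenceRecord]:
    """Parse an occurrence CSV into validated records.

    ``columns`` maps the logical fields (taxon, rank, genus, early, late,
    collection) to the file's column names; defaults follow PaleoDB field
    names. Unknown extra columns are ignored. Malformed rows raise a single
    :class:`OccurrenceFormatError` listing the offending line numbers
    (1-based, header excluded).
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, comment="#")
    required = [cols["taxon"], cols["rank"], cols["early"], cols["late"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise OccurrenceFormatError(
            f"{path}: missing required columns {missing}; present: {list(df.columns)}"
        )
    has_genus = cols["genus"] in df.columns
    has_coll = cols["collection"] in df.columns
    records, bad = [], []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            taxon = str(row[cols["taxon"]])
            genus = str(row[cols["genus"]]) if has_genus else taxon.split()[0]
            records.append(
                OccurrenceRecord(
                    taxon_name=taxon,
                    matched_rank=str(row[cols["rank"]]).strip().casefold(),
                    genus_name=genus,
                    early_age=float(row[cols["early"]]),
                    late_age=float(row[cols["late"]]),
                    collection_id=str(row[cols["collection"]]) if has_coll else "",
                )
            )
        except (OccurrenceFormatError, ValueError, IndexError) as e:
            bad.append((i, str(e)))
    if bad:
        lines = "; ".join(f"row {i}: {msg}" for i, msg in bad[:10])
        raise OccurrenceFormatError(
            f"{path}: {len(bad)} malformed row(s): {lines}"
        )
    return records


def filter_records(
    records: Iterable[OccurrenceRecord],
    rank: str = "species",
    exclusions: ExclusionLists | None = None,
) -> list[OccurrenceRecord]:
    """Keep records matched at ``rank`` and not named in any exclusion list."""
    exclusions = exclusions or ExclusionLists()
    rank = rank.strip().casefold()
    return [
        r
        for r in records
        if r.matched_rank == rank and not exclusions.excludes(r)
    ]


def assign_stage(
    record: OccurrenceRecord, ts: Timescale, rng: np.random.Generator
) -> str:
    """Draw one stage for a record, proportional to age-range overlap.

    A record whose range lies within a single stage is assigned
    deterministically. A record whose range has zero overlap with every
    stage but touches a boundary (e.g. a point age exactly on a shared
    stage boundary) is assigned to the oldest stage containing it.
    """
    weights = np.array(
        [max(0.0, min(record.early_age, s.early_bound) - max(record.late_age, s.late_bound))
         for s in ts]
    )
    total = weights.sum()
    if total > 0.0:
        positive = np.flatnonzero(weights)
        if positive.size == 1:
            return ts[positive[0]].name
        return ts[rng.choice(len(ts), p=weights / total)].name
    # zero-measure range: containment tie rule, oldest stage wins
    for s in ts:  # ordered old -> young
        if s.contains(record.early_age) and s.contains(record.late_age):
            return s.name
    raise OutOfTimescaleError(
        f"{record.taxon_name!r} ({record.early_age}-{record.late_age} Ma) "
        f"does not overlap the timescale"
    )


@dataclass
class CountMatrix:
    """Per-taxon, per-stage fossil observation counts O_i,t.

    ``counts`` is a DataFrame with taxa as rows and stage names as columns;
    every taxon row has at least one positive entry.
    """

    counts: pd.DataFrame
    rank: str = "species"

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)

    def stage_counts(self, stage: str) -> np.ndarray:
        """Positive observation counts for one stage (observed taxa only)."""
        col = self.counts[stage].to_numpy()
        return col[col > 0]

    def observed_richness(self) -> pd.Series:
        """N_t: number of taxa with at least one observation per stage."""
        return (self.counts > 0).sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def write(self, path: str | Path, meta: dict | None = None) -> None:
        """Write the matrix as CSV with a JSON sidecar of run metadata."""
        path = Path(path)
        self.counts.to_csv(path, index_label="taxon")
        sidecar = dict(meta or {})
        sidecar.setdefault("rank", self.rank)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def build_count_matrix(
    records: Sequence[OccurrenceRecord],
    ts: Timescale,
    rank: str = "species",
    rng: np.random.Generator | int | None = None,
) -> CountMatrix:
    """Tally one stage draw per record into a taxon-by-stage count matrix.

    Records whose age range falls entirely outside the timescale are
    dropped with a logged warning. Taxon identity is the whitespace/case
    normalised name (display uses the first spelling seen).
    """
    rng = np.random.default_rng(rng)
    display: dict[str, str] = {}
    tallies: dict[tuple[str, str], int] = {}
    dropped = 0
    for rec in records:
        try:
            stage = assign_stage(rec, ts, rng)
        except OutOfTimescaleError:
            dropped += 1
            continue
        key = _norm(rec.taxon_name)
        display.setdefault(key, re.sub(r"\s+", " ", rec.taxon_name.strip()))
        tallies[(key, stage)] = tallies.get((key, stage), 0) + 1
    if dropped:
        logger.warning("%d record(s) outside the timescale were dropped", dropped)
    taxa = sorted(display)
    mat = pd.DataFrame(0, index=[display[t] for t in taxa], columns=ts.names, dtype=int)
    for (taxon, stage), n in tallies.items():
        mat.loc[display[taxon], stage] += n
    return CountMatrix(mat, rank=rank)


def replicate_matrices(
    records: Sequence[OccurrenceRecord],
    ts: Timescale,
    rank: str = "species",
    n_reps: int = 100,
    seed: int | None = None,
) -> list[CountMatrix]:
    """Independent stage-assignment realisations of the count matrix.

    A master seed spawns one child stream per replicate, so replicate ``r``
    is reproducible regardless of ``n_reps``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    return [
        build_count_matrix(records, ts, rank=rank, rng=np.random.default_rng(c))
        for c in children
    ]
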