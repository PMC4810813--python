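"""Synthetic occurrence tables with planted truth.

Generates PaleoDB-style occurrence CSVs in which each stage holds a known
number of planted species sampled by a homogeneous Poisson process, so the
whole ingestion-to-estimation pipeline can be exercised against a known
true richness. Counts per planted species are Poisson(lambda * d); species
drawing zero observations simply never appear in the table, exactly as
unobserved taxa never enter a fossil database.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .timescale import Timescale

__all__ = ["synthesize_occurrences", "write_occurrences"]


def synthesize_occurrences(
    ts: Timescale,
    n_taxa: int = 50,
    lam: float | dict[str, float] = 0.5,
    widen: float = 0.0,
    rank: str = "species",
    seed: int | None = None,
) -> pd.DataFrame:
    """Occurrence table with ``n_taxa`` planted species per stage.

    ``lam`` is the per-lineage sampling rate in observations per Myr,
    either one value for all stages or a per-stage mapping (stages absent
    from the mapping are skipped). ``widen`` expands each record's age
    range by that many Myr on both sides (clipped to the timescale), so
    records span several stages and exercise the probabilistic assignment.
    Taxon names encode the planted stage, e.g. ``Synthosaurus norian_7``.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    oldest = ts[0].early_bound
    youngest = ts[-1].late_bound
    rows = []
    for stage in ts:
        rate = lam.get(stage.name) if isinstance(lam, dict) else lam
        if rate is None:
            continue
        counts = rng.poisson(rate * stage.duration, n_taxa)
        early = min(stage.early_bound + widen, oldest)
        late = max(stage.late_bound - widen, youngest)
        tag = stage.name.lower().replace(" ", "_")
        for i, c in enumerate(counts):
            name = f"Synthosaurus {tag}_{i}"
            for k in range(int(c)):
                rows.append(
                    {
                        "accepted_name": name,
                        "accepted_rank": rank,
                        "genus": "Synthosaurus",
                        "max_ma": early,
                        "min_ma": late,
                        "collection_no": f"{tag}-{i}-{k}",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "accepted_name",
            "accepted_rank",
            "genus",
            "max_ma",
            "min_ma",
            "collection_no",
        ],
    )


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
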