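"""Per-home scores: the moldiness index (ERMI) and Shannon diversity.

The Environmental Relative Moldiness Index for a home is

    ERMI = sum_{i=1..26} log10(s1_i) - sum_{j=1..10} log10(s2_j)

where s1 are the CE/mg concentrations of the 26 water-damage-associated
(group 1) species and s2 those of the 10 outdoor-origin (group 2)
species.  Concentrations must be floored at 1 CE/mg first so every log
term is non-negative and a fully non-detected group contributes 0.

Diversity is the Shannon index H = -sum p_i ln p_i over the 36 panel
proportions (natural log, so H is in nats and bounded by ln 36), with
equitability H / ln(36).  Floored values are treated as abundances —
the study quantified, so presence/absence would discard information —
but species sitting exactly at the floor are censoring artifacts and do
not count toward richness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import ConcentrationMatrix, HomeMetadata, MoldPanel

__all__ = [
    "ErmiResult",
    "DiversityResult",
    "ermi",
    "shannon_diversity",
    "score_cohort",
]


@dataclass(frozen=True)
class ErmiResult:
    home_id: str
    year: int
    sum_logs_g1: float
    sum_logs_g2: float

    @property
    def ermi(self) -> float:
        return self.sum_logs_g1 - self.sum_logs_g2


@dataclass(frozen=True)
class DiversityResult:
    home_id: str
    year: int
    shannon_h: float
    equitability: float
    richness: int


def _check_floored(row: pd.Series, floor: float) -> None:
    if (row.values < floor).any():
        bad = row[row < floor].index.tolist()
        raise ValueError(
            f"row has values below the floor ({bad[:3]}...); apply floor_matrix first"
        )


def ermi(
    row: pd.Series,
    panel: MoldPanel,
    home_id: str = "",
    year: int = 2018,
    floor: float = 1.0,
) -> ErmiResult:
    """Score one floored CE/mg row: group log-sums and their difference."""
    missing = [s for s in panel.species_names if s not in row.index]
    if missing:
        raise KeyError(f"row is missing panel species: {missing[:3]}...")
    _check_floored(row[list(panel.species_names)], floor)
    g1 = float(np.log10(row[list(panel.group1_species)].astype(float)).sum())
    g2 = float(np.log10(row[list(panel.group2_species)].astype(float)).sum())
    return ErmiResult(home_id=home_id, year=year, sum_logs_g1=g1, sum_logs_g2=g2)


def shannon_diversity(
    row: pd.Series,
    home_id: str = "",
    year: int = 2018,
    floor: float = 1.0,
) -> DiversityResult:
    """Shannon H (nats), equitability H/ln(S), and above-floor richness.

    Proportions are taken over all panel species present in the row.
    An all-floor row is legal: it yields the uniform distribution
    (H = ln S, equitability 1, richness 0).
    """
    vals = row.astype(float)
    _check_floored(vals, floor)
    p = vals.values / vals.values.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    s = len(vals)
    return DiversityResult(
        home_id=home_id,
        year=year,
        shannon_h=h,
        equitability=h / np.log(s),
        richness=int((vals.values > floor).sum()),
    )


def score_cohort(
    matrix: ConcentrationMatrix,
    metadata: Sequence[HomeMetadata],
    panel: MoldPanel,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Score every (home, year) row and join region metadata.

    Returns one record per matrix row with columns
    ``home_id, year, region, sum_logs_g1, sum_logs_g2, ermi,
    shannon_h, equitability, richness``.  Raises if any matrix row
    lacks metadata.
    """
    meta_by_key = {(m.home_id, m.year): m for m in metadata}
    records = []
    for (home_id, year), row in matrix.values.iterrows():
        key = (home_id, int(year))
        if key not in meta_by_key:
            raise KeyError(f"no metadata for home {home_id!r}, year {year}")
        e = ermi(row, panel, home_id=home_id, year=int(year), floor=floor)
        d = shannon_diversity(
            row[list(panel.species_names)], home_id=home_id, year=int(year), floor=floor
        )
        records.append(
            {
                "home_id": home_id,
                "year": int(year),
                "region": meta_by_key[key].region,
                "sum_logs_g1": e.sum_logs_g1,
                "sum_logs_g2": e.sum_logs_g2,
                "ermi": e.ermi,
                "shannon_h": d.shannon_h,
                "equitability": d.equitability,
                "richness": d.richness,
            }
        )
    return pd.DataFrame.from_records(records)
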