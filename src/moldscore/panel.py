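"""Mold panel registry, home metadata, and the concentration data model.

The Environmental Relative Moldiness Index (ERMI) panel is a closed
vocabulary of 36 indicator molds quantified by mold-specific qPCR:
26 "group 1" species associated with water damage indoors and 10
"group 2" species that primarily enter the home from outdoors.  The
registry stores, per assay, the standard-curve parameters used to
convert cycle-threshold values into cell equivalents (CE).

Species names are stored exactly as the panel prints them (including
the two *Cladosporium cladosporioides* types and *Penicillium
chrysogenum* 2); matching is case-sensitive after whitespace trimming.
Fuzzy matching is deliberately not offered — a closed panel invites
silent mis-assignment otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayDefinition",
    "MoldPanel",
    "HomeMetadata",
    "ConcentrationMatrix",
    "build_default_panel",
    "validate_matrix",
    "read_concentration_csv",
    "write_concentration_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "GROUP1_SPECIES",
    "GROUP2_SPECIES",
    "MATERIALS",
    "VENTILATION_TYPES",
]

# Default standard curve: one doubling per cycle (slope = -1/log10(2))
# with a single cell equivalent crossing threshold at the final cycle.
DEFAULT_SLOPE = -3.321928094887362
DEFAULT_INTERCEPT = 40.0
DEFAULT_MAX_CYCLE = 40.0

# The 26 water-damage-associated indicator species.
GROUP1_SPECIES: tuple[str, ...] = (
    "Aspergillus flavus",
    "Aspergillus fumigatus",
    "Aspergillus niger",
    "Aspergillus ochraceus",
    "Aspergillus penicillioides",
    "Aspergillus restrictus",
    "Aspergillus sclerotiorum",
    "Aspergillus sydowii",
    "Aspergillus unguis",
    "Aspergillus versicolor",
    "Aureobasidium pullulans",
    "Chaetomium globosum",
    "Cladosporium sphaerospermum",
    "Eurotium amstelodami",
    "Paecilomyces variotii",
    "Penicillium brevicompactum",
    "Penicillium corylophilum",
    "Penicillium crustosum",
    "Penicillium purpurogenum",
    "Penicillium spinulosum",
    "Penicillium variabile",
    "Scopulariopsis brevicaulis",
    "Scopulariopsis chartarum",
    "Stachybotrys chartarum",
    "Trichoderma viride",
    "Wallemia sebi",
)

# The 10 species that primarily enter the home from the outdoor environment.
GROUP2_SPECIES: tuple[str, ...] = (
    "Acremonium strictum",
    "Alternaria alternata",
    "Aspergillus ustus",
    "Cladosporium cladosporioides 1",
    "Cladosporium cladosporioides 2",
    "Cladosporium herbarum",
    "Epicoccum nigrum",
    "Mucor group",
    "Penicillium chrysogenum 2",
    "Rhizopus stolonifer",
)

MATERIALS = ("Cement", "Wood", "vinyl")
VENTILATION_TYPES = ("Natural", "full AC")
VALID_YEARS = (2018, 2019)
VALID_REGIONS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class AssayDefinition:
    """One mold-specific qPCR assay and its standard curve.

    Parameters
    ----------
    species_name
        Panel species name, stored verbatim.
    group
        1 (water-damage associated) or 2 (outdoor origin).
    slope
        Standard-curve slope in Ct per log10(CE).  Negative: more
        template amplifies earlier.
    intercept
        Ct at 1 CE.
    max_cycle
        Final thermal cycle; a reaction with no signal by this cycle
        is a non-detect.
    """

    species_name: str
    group: int
    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    max_cycle: float = DEFAULT_MAX_CYCLE

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_name", self.species_name.strip())
        if self.group not in (1, 2):
            raise ValueError(f"group must be 1 or 2, got {self.group!r}")
        if not self.slope < 0:
            raise ValueError(f"slope must be negative, got {self.slope}")
        if not self.max_cycle > 0:
            raise ValueError(f"max_cycle must be positive, got {self.max_cycle}")


@dataclass(frozen=True)
class MoldPanel:
    """Ordered registry of the 36 panel assays (26 group 1 + 10 group 2)."""

    assays: tuple[AssayDefinition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assays", tuple(self.assays))
        names = [a.species_name for a in self.assays]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate species names in panel: {dupes}")
        n1 = sum(a.group == 1 for a in self.assays)
        n2 = sum(a.group == 2 for a in self.assays)
        if (n1, n2) != (26, 10):
            raise ValueError(
                f"panel must have 26 group-1 and 10 group-2 assays, got {n1}/{n2}"
            )

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(a.species_name for a in self.assays)

    @property
    def group1_species(self) -> tuple[str, ...]:
        return tuple(a.species_name for a in self.assays if a.group == 1)

    @property
    def group2_species(self) -> tuple[str, ...]:
        return tuple(a.species_name for a in self.assays if a.group == 2)

    def assay(self, species_name: str) -> AssayDefinition:
        key = species_name.strip()
        for a in self.assays:
            if a.species_name == key:
                return a
        raise KeyError(f"species not in panel: {species_name!r}")

    def __len__(self) -> int:
        return len(self.assays)

    def __contains__(self, species_name: str) -> bool:
        return species_name.strip() in self.species_names

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the registry (species, group, curve parameters)."""
        payload = [
            {
                "species_name": a.species_name,
                "group": a.group,
                "slope": a.slope,
                "intercept": a.intercept,
                "max_cycle": a.max_cycle,
            }
            for a in self.assays
        ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MoldPanel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(tuple(AssayDefinition(**row) for row in json.loads(text)))


def build_default_panel() -> MoldPanel:
    """Return the standard 36-assay ERMI registry.

    Standard-curve parameters default to a 100%-efficiency curve
    (slope -3.3219, one CE crossing at cycle 40); load real per-assay
    curves via :meth:`MoldPanel.from_json` when available.
    """
    assays = [AssayDefinition(name, 1) for name in GROUP1_SPECIES]
    assays += [AssayDefinition(name, 2) for name in GROUP2_SPECIES]
    return MoldPanel(tuple(assays))


@dataclass(frozen=True)
class HomeMetadata:
    """Per-home study covariates: region, year, damage, construction."""

    home_id: str
    region: int
    year: int
    water_damage: bool
    material: str
    ventilation: str
    dog: bool

    def __post_init__(self) -> None:
        if self.region not in VALID_REGIONS:
            raise ValueError(f"region must be 1..5, got {self.region}")
        if self.year not in VALID_YEARS:
            raise ValueError(f"year must be one of {VALID_YEARS}, got {self.year}")
        if self.material not in MATERIALS:
            raise ValueError(f"material must be one of {MATERIALS}, got {self.material!r}")
        if self.ventilation not in VENTILATION_TYPES:
            raise ValueError(
                f"ventilation must be one of {VENTILATION_TYPES}, got {self.ventilation!r}"
            )


class ConcentrationMatrix:
    """Homes x species concentrations in cell equivalents per mg dust.

    Rows are keyed by ``(home_id, year)`` — the study design resamples
    the same homes across years, and a home present in only one year is
    allowed.  Columns cover the full panel; a cell is either a detected
    concentration or a non-detect (value 0 until a detection floor is
    applied).
    """

    def __init__(self, values: pd.DataFrame, detected: pd.DataFrame | None = None):
        values = values.copy()
        if not isinstance(values.index, pd.MultiIndex):
            raise ValueError("values must be indexed by (home_id, year)")
        values.index = values.index.set_names(["home_id", "year"])
        values = values.astype(float)
        if detected is None:
            detected = values > 0
        else:
            detected = detected.copy().astype(bool)
            if not detected.index.equals(values.index) or list(
                detected.columns
            ) != list(values.columns):
                raise ValueError("detected flags must align with values")
        self.values = values
        self.detected = detected

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def rows(self) -> list[tuple[str, int]]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.detected.equals(other.detected)

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(self.values.copy(), self.detected.copy())

    def for_year(self, year: int) -> "ConcentrationMatrix":
        mask = self.values.index.get_level_values("year") == year
        return ConcentrationMatrix(self.values.loc[mask], self.detected.loc[mask])

    def row(self, home_id: str, year: int) -> pd.Series:
        return self.values.loc[(home_id, year)]

    @classmethod
    def from_rows(
        cls,
        rows: dict[tuple[str, int], dict[str, float]],
        species: Sequence[str],
        non_detect: Iterable[tuple[tuple[str, int], str]] = (),
    ) -> "ConcentrationMatrix":
        index = pd.MultiIndex.from_tuples(list(rows), names=["home_id", "year"])
        values = pd.DataFrame(
            [[rows[k].get(s, 0.0) for s in species] for k in rows],
            index=index,
            columns=list(species),
            dtype=float,
        )
        detected = values > 0
        for key, sp in non_detect:
            detected.loc[key, sp] = False
        return cls(values, detected)


def validate_matrix(matrix: ConcentrationMatrix, panel: MoldPanel) -> list[str]:
    """Check a concentration matrix against the panel contract.

    Returns a list of human-readable violations (empty iff valid);
    validation reports rather than throws so a caller can aggregate
    every problem in one pass.  Rules: every row carries all 36 panel
    columns, values are non-negative and finite, and non-detect cells
    hold value 0 before flooring.
    """
    violations: list[str] = []
    panel_species = set(panel.species_names)
    have = set(matrix.species)
    for missing in sorted(panel_species - have):
        violations.append(f"missing panel column: {missing!r}")
    for extra in sorted(have - panel_species):
        violations.append(f"column not in panel: {extra!r}")
    vals = matrix.values
    for (home_id, year), row in vals.iterrows():
        for sp, v in row.items():
            if not np.isfinite(v):
                violations.append(
                    f"non-finite concentration: row ({home_id!r}, {year}), column {sp!r}"
                )
            elif v < 0:
                violations.append(
                    f"negative concentration: row ({home_id!r}, {year}), "
                    f"column {sp!r}, value {v}"
                )
    if matrix.values.index.has_duplicates:
        dupes = matrix.values.index[matrix.values.index.duplicated()].tolist()
        violations.append(f"duplicate (home_id, year) rows: {sorted(set(dupes))}")
    return violations


# ---------------------------------------------------------------------------
# CSV interchange
#
# Wide concentration schema: header home_id,year,<36 species names>; UTF-8;
# non-detects written as "ND".  Metadata schema:
# home_id,region,year,water_damage,material,ventilation,dog.
# ---------------------------------------------------------------------------


def write_concentration_csv(matrix: ConcentrationMatrix, path: str | Path) -> None:
    out = matrix.values.copy().astype(object)
    out[~matrix.detected] = "ND"
    out.reset_index().to_csv(path, index=False)


def read_concentration_csv(path: str | Path) -> ConcentrationMatrix:
    df = pd.read_csv(path, dtype={"home_id": str})
    if "home_id" not in df.columns or "year" not in df.columns:
        raise ValueError("concentration CSV must have home_id and year columns")
    df = df.set_index(["home_id", "year"])
    raw = df.astype(object)
    is_nd = raw.map(lambda v: (isinstance(v, str) and v.strip().upper() == "ND") or pd.isna(v))
    values = raw.mask(is_nd, 0.0).astype(float)
    return ConcentrationMatrix(values, detected=~is_nd)


def write_metadata_csv(metadata: Sequence[HomeMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "home_id": [m.home_id for m in metadata],
            "region": [m.region for m in metadata],
            "year": [m.year for m in metadata],
            "water_damage": [m.water_damage for m in metadata],
            "material": [m.material for m in metadata],
            "ventilation": [m.ventilation for m in metadata],
            "dog": [m.dog for m in metadata],
        }
    )
    df.to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> list[HomeMetadata]:
    df = pd.read_csv(path, dtype={"home_id": str})

    def _bool(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in ("true", "1", "yes")
        return bool(v)

    return [
        HomeMetadata(
            home_id=str(r.home_id),
            region=int(r.region),
            year=int(r.year),
            water_damage=_bool(r.water_damage),
            material=str(r.material),
            ventilation=str(r.ventilation),
            dog=_bool(r.dog),
        )
        for r in df.itertuples()
    ]
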