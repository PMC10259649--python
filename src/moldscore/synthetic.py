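"""Synthetic study cohorts with known ground truth.

The study's raw per-home concentrations are not deposited, so testing
the pipeline end to end requires a generator that reproduces the
*structure* the analysis assumes: per-species log10-Normal CE/mg
concentrations, a five-region two-year design resampling the same
homes, a multiplicative elevation of the 26 water-damage-associated
(group 1) species in damaged homes, a year-2 elevation of the 10
outdoor-origin (group 2) species (the post-hurricane phylloplane
bloom), and a remediation effect that removes the damage elevation in
the second year.  Effects are multiplicative — additive on log10 — so
the expected shifts of the group log-sums have closed forms used by
the tests (a fold-change f on every group-2 species moves the group-2
log-sum by 10*log10(f), censoring at the detection floor aside).

All randomness flows from one integer seed through per-cell streams
keyed by (home, year, species), so enlarging the panel or the cohort
never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import ConcentrationMatrix, HomeMetadata, MoldPanel

__all__ = [
    "SyntheticConfig",
    "OutdoorSeriesConfig",
    "generate_cohort",
    "generate_outdoor_series",
    "default_mu",
]

# Table-1-style study layout: per region, (n_homes, n_damaged,
# materials, ventilation, n_dogs).  Damaged homes and dogs are
# assigned to the leading/trailing homes of each region respectively.
_REGION_LAYOUT: dict[int, dict] = {
    1: {"n": 6, "damaged": 0, "materials": ["Cement"] * 6, "full_ac": [], "dogs": 0},
    2: {"n": 5, "damaged": 2, "materials": ["Cement"] * 4 + ["Wood"], "full_ac": [], "dogs": 1},
    3: {"n": 2, "damaged": 1, "materials": ["Wood"] * 2, "full_ac": [], "dogs": 0},
    4: {"n": 5, "damaged": 0, "materials": ["Cement"] * 5, "full_ac": [4], "dogs": 2},
    5: {"n": 2, "damaged": 1, "materials": ["Cement", "vinyl"], "full_ac": [], "dogs": 2},
}


def default_mu(panel: MoldPanel) -> np.ndarray:
    """Baseline log10(CE/mg) means spanning 1..4 within each group.

    Indoor mold concentrations span orders of magnitude; spreading the
    per-species medians over roughly 1-4 on the log10 scale keeps every
    species comfortably above the 1 CE/mg detection floor while
    covering the dynamic range a dust panel typically shows.
    """
    mus = np.empty(len(panel.assays))
    for group in (1, 2):
        idx = [i for i, a in enumerate(panel.assays) if a.group == group]
        mus[idx] = np.linspace(1.0, 4.0, len(idx))
    return mus


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort generator parameters.

    region_sizes: homes per region (default 6,5,2,5,2 — 20 homes).
    mu, sigma: per-species (or scalar) mean / sd of log10(CE/mg);
        ``mu=None`` uses :func:`default_mu`.
    damage_multiplier_g1: fold-change applied to group-1 species in
        water-damaged homes (default 10).
    bloom_multiplier_g2: fold-change applied to group-2 species in the
        second year (default 3), emulating a post-hurricane release of
        phylloplane spores.
    remediation_recovery: fraction of the damage effect removed in the
        second year for damaged homes (default 1.0 — full remediation).
    detection_floor: CE/mg below which a draw is a non-detect.
    """

    region_sizes: tuple[int, ...] = (6, 5, 2, 5, 2)
    years: tuple[int, int] = (2018, 2019)
    mu: tuple[float, ...] | None = None
    sigma: float | tuple[float, ...] = 0.5
    damage_multiplier_g1: float = 10.0
    bloom_multiplier_g2: float = 3.0
    remediation_recovery: float = 1.0
    detection_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.region_sizes) != 5 or any(n <= 0 for n in self.region_sizes):
            raise ValueError("region_sizes must be 5 positive integers")
        if self.damage_multiplier_g1 < 1 or self.bloom_multiplier_g2 < 1:
            raise ValueError("effect multipliers must be >= 1")
        if not 0 <= self.remediation_recovery <= 1:
            raise ValueError("remediation_recovery must lie in [0, 1]")
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be positive")
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if (sig <= 0).any():
            raise ValueError("sigma must be positive")


def _build_metadata(config: SyntheticConfig) -> list[HomeMetadata]:
    metadata: list[HomeMetadata] = []
    for region, n in zip(range(1, 6), config.region_sizes):
        layout = _REGION_LAYOUT[region]
        for i in range(n):
            materials = layout["materials"]
            material = materials[i] if i < len(materials) else materials[-1]
            ventilation = "full AC" if i in layout["full_ac"] else "Natural"
            damaged = i < layout["damaged"]
            dog = i >= n - layout["dogs"]
            for year in config.years:
                metadata.append(
                    HomeMetadata(
                        home_id=f"r{region}h{i + 1}",
                        region=region,
                        year=year,
                        water_damage=damaged,
                        material=material,
                        ventilation=ventilation,
                        dog=dog,
                    )
                )
    return metadata


def _log10_effect(
    group: int, damaged: bool, is_year2: bool, config: SyntheticConfig
) -> float:
    """Total log10 fold-change applied to one cell."""
    effect = 0.0
    if group == 1 and damaged:
        scale = (1.0 - config.remediation_recovery) if is_year2 else 1.0
        effect += scale * np.log10(config.damage_multiplier_g1)
    if group == 2 and is_year2:
        effect += np.log10(config.bloom_multiplier_g2)
    return effect


def generate_cohort(
    config: SyntheticConfig, panel: MoldPanel
) -> tuple[ConcentrationMatrix, list[HomeMetadata], pd.DataFrame]:
    """Draw a full two-year cohort.

    Per (home, year, species): log10 CE/mg ~ Normal(mu_s + effect,
    sigma_s), where the effect is the log10 of the applied fold-change;
    draws below the detection floor become non-detects (value 0).

    Returns the concentration matrix (unfloored), the per-(home, year)
    metadata, and a ground-truth table listing every cell-level
    fold-change actually applied (species, home_id, year, multiplier).
    """
    metadata = _build_metadata(config)
    homes = sorted(
        {(m.home_id, m.region, m.water_damage) for m in metadata},
        key=lambda t: (t[1], t[0]),
    )
    species = list(panel.species_names)
    groups = {a.species_name: a.group for a in panel.assays}
    mu = np.asarray(config.mu, dtype=float) if config.mu is not None else default_mu(panel)
    if mu.shape != (len(species),):
        raise ValueError(f"mu must have {len(species)} entries")
    sigma = np.broadcast_to(
        np.asarray(config.sigma, dtype=float), (len(species),)
    ).copy()

    rows: dict[tuple[str, int], dict[str, float]] = {}
    non_detect: list[tuple[tuple[str, int], str]] = []
    truth_rows: list[dict] = []
    year2 = max(config.years)
    for h, (home_id, _region, damaged) in enumerate(homes):
        for year in config.years:
            key = (home_id, year)
            row: dict[str, float] = {}
            for s, sp in enumerate(species):
                eff = _log10_effect(groups[sp], damaged, year == year2, config)
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(config.seed), h, int(year), s])
                )
                log10c = rng.normal(mu[s] + eff, sigma[s])
                conc = 10.0**log10c
                if conc < config.detection_floor:
                    row[sp] = 0.0
                    non_detect.append((key, sp))
                else:
                    row[sp] = conc
                if eff != 0.0:
                    truth_rows.append(
                        {
                            "species": sp,
                            "home_id": home_id,
                            "year": year,
                            "multiplier": 10.0**eff,
                        }
                    )
            rows[key] = row

    matrix = ConcentrationMatrix.from_rows(rows, species, non_detect)
    truth = pd.DataFrame(
        truth_rows, columns=["species", "home_id", "year", "multiplier"]
    )
    return matrix, metadata, truth


@dataclass(frozen=True)
class OutdoorSeriesConfig:
    """Outdoor spore-count series generator (log10 counts per year).

    Defaults echo a three-year station record around a landfall event:
    yearly mean log10 counts 4.6812 / 4.8593 / 4.7335 with standard
    deviations 0.1417 / 0.1781 / 0.0895, and 50 counts per year
    (roughly weekly station readings).
    """

    years: tuple[int, ...] = (2017, 2018, 2019)
    mean_log_counts: tuple[float, ...] = (4.6812, 4.8593, 4.7335)
    sd_log_counts: tuple[float, ...] = (0.1417, 0.1781, 0.0895)
    n_per_year: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            len(self.years) == len(self.mean_log_counts) == len(self.sd_log_counts)
        ):
            raise ValueError("years, means, and sds must have equal lengths")
        if any(sd <= 0 for sd in self.sd_log_counts):
            raise ValueError("sd_log_counts must be positive")
        if self.n_per_year < 2:
            raise ValueError("n_per_year must be >= 2")


def generate_outdoor_series(config: OutdoorSeriesConfig) -> dict[str, np.ndarray]:
    """Normal draws of log10 spore counts, keyed by year label."""
    out: dict[str, np.ndarray] = {}
    for i, (year, m, sd) in enumerate(
        zip(config.years, config.mean_log_counts, config.sd_log_counts)
    ):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 1_000_000 + i])
        )
        out[str(year)] = rng.normal(m, sd, size=config.n_per_year)
    return out
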