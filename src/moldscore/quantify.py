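"""Cycle-threshold to CE/mg conversion with spike-in extraction QC.

Quantification follows the standard linear qPCR model per assay,
Ct = intercept + slope * log10(CE), inverted to CE = 10**((ct - intercept)/slope).
Each dust extract carries a known *Geotrichum candidum* conidial spike
added before DNA extraction; its recovery Ct gates extraction and
purification quality.  Replicates are averaged on the linear CE scale
(the quantity that enters the moldiness index), then normalized by the
analyzed dust mass (5 mg by default).

Flooring: values below 1 CE/mg are raised to 1 so the log10 terms of
the moldiness index are non-negative and a fully non-detected group
contributes zero to its log-sum.  Flooring is applied after the per-mg
division, never before.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import AssayDefinition, ConcentrationMatrix, MoldPanel

__all__ = [
    "CtRecord",
    "SpikeInRecord",
    "QuantConfig",
    "QCVerdict",
    "ct_to_cell_equivalents",
    "quantify_sample",
    "quantify_cohort",
    "floor_matrix",
    "read_ct_csv",
    "read_spike_csv",
    "write_qc_report",
]

NON_DETECT = None  # sentinel: a reaction with no signal by max_cycle


@dataclass(frozen=True)
class CtRecord:
    """One qPCR reaction: sample, assay, replicate, threshold cycle.

    ``ct`` is ``None`` for a non-detect (no amplification by the final
    cycle)."""

    sample_id: str
    species_name: str
    ct: float | None
    replicate: int = 1


@dataclass(frozen=True)
class SpikeInRecord:
    """Internal-reference spike recovery for one sample.

    ``ct_reference`` is the expected Ct for the 1e6-conidia spike under
    the extraction protocol; ``ct_observed`` is what the sample gave."""

    sample_id: str
    ct_observed: float
    ct_reference: float

    def __post_init__(self) -> None:
        if self.ct_observed <= 0 or self.ct_reference <= 0:
            raise ValueError("spike Ct values must be positive")

    @property
    def delta_cycles(self) -> float:
        return self.ct_observed - self.ct_reference


@dataclass(frozen=True)
class QuantConfig:
    """Quantification parameters.

    dust_mass_mg: analyzed dust mass (default 5 mg of sieved dust).
    spike_tolerance_cycles: |observed - reference| spike Ct beyond which
        extraction QC fails (default 3 cycles, roughly an 8-fold
        recovery loss under a doubling curve).
    floor_ce_per_mg: detection floor applied by :func:`floor_matrix`.
    """

    dust_mass_mg: float = 5.0
    spike_tolerance_cycles: float = 3.0
    floor_ce_per_mg: float = 1.0

    def __post_init__(self) -> None:
        for name in ("dust_mass_mg", "spike_tolerance_cycles", "floor_ce_per_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class QCVerdict:
    sample_id: str
    passed: bool
    delta_cycles: float

    @property
    def label(self) -> str:
        return "PASS" if self.passed else "FAIL"


def ct_to_cell_equivalents(ct: float, assay: AssayDefinition) -> float:
    """Invert the standard curve: CE = 10**((ct - intercept) / slope).

    Strictly decreasing in ct (slope < 0).  Non-detects have no numeric
    conversion — callers route them to the floor path instead.
    """
    if ct is None:
        raise ValueError(
            f"non-detect has no Ct->CE conversion ({assay.species_name}); "
            "use the floor path"
        )
    if not 0 < ct <= assay.max_cycle:
        raise ValueError(
            f"ct={ct} outside (0, {assay.max_cycle}] for {assay.species_name}"
        )
    return 10.0 ** ((ct - assay.intercept) / assay.slope)


def quantify_sample(
    records: Sequence[CtRecord],
    spike: SpikeInRecord,
    panel: MoldPanel,
    config: QuantConfig = QuantConfig(),
) -> tuple[pd.Series, pd.Series, QCVerdict]:
    """Turn one sample's Ct records into a CE/mg row plus a QC verdict.

    Per species: mean CE over detected replicates, divided by the dust
    mass.  A species whose replicates are all non-detect (or absent)
    gets value 0 with a non-detect flag.  A failed spike (|delta| over
    tolerance) flags the whole row unreliable but still returns values.

    Returns ``(values, detected, verdict)`` — two Series indexed by the
    panel species, and the spike verdict.
    """
    seen: set[tuple[str, int]] = set()
    per_species: dict[str, list[float]] = {}
    for rec in records:
        name = rec.species_name.strip()
        if name not in panel:
            raise KeyError(f"unknown species in Ct records: {rec.species_name!r}")
        key = (name, rec.replicate)
        if key in seen:
            raise ValueError(
                f"duplicate (species, replicate) record: {name!r} rep {rec.replicate}"
            )
        seen.add(key)
        if rec.ct is not None:
            ce = ct_to_cell_equivalents(rec.ct, panel.assay(name))
            per_species.setdefault(name, []).append(ce)

    species = list(panel.species_names)
    values = pd.Series(0.0, index=species)
    detected = pd.Series(False, index=species)
    for name, ces in per_species.items():
        values[name] = float(np.mean(ces)) / config.dust_mass_mg
        detected[name] = True

    delta = spike.delta_cycles
    verdict = QCVerdict(
        sample_id=spike.sample_id,
        passed=abs(delta) <= config.spike_tolerance_cycles,
        delta_cycles=delta,
    )
    return values, detected, verdict


def quantify_cohort(
    records: Sequence[CtRecord],
    spikes: Sequence[SpikeInRecord],
    sample_keys: dict[str, tuple[str, int]],
    panel: MoldPanel,
    config: QuantConfig = QuantConfig(),
) -> tuple[ConcentrationMatrix, list[QCVerdict]]:
    """Quantify every sample and assemble the concentration matrix.

    ``sample_keys`` maps sample_id -> (home_id, year).  Every sample
    must have exactly one spike record.
    """
    spike_by_sample = {s.sample_id: s for s in spikes}
    by_sample: dict[str, list[CtRecord]] = {sid: [] for sid in sample_keys}
    for rec in records:
        if rec.sample_id not in by_sample:
            raise KeyError(f"Ct record for unknown sample: {rec.sample_id!r}")
        by_sample[rec.sample_id].append(rec)

    rows: dict[tuple[str, int], pd.Series] = {}
    flags: dict[tuple[str, int], pd.Series] = {}
    verdicts: list[QCVerdict] = []
    for sid, key in sample_keys.items():
        if sid not in spike_by_sample:
            raise KeyError(f"no spike-in record for sample {sid!r}")
        vals, det, verdict = quantify_sample(
            by_sample[sid], spike_by_sample[sid], panel, config
        )
        rows[key] = vals
        flags[key] = det
        verdicts.append(verdict)

    index = pd.MultiIndex.from_tuples(list(rows), names=["home_id", "year"])
    values = pd.DataFrame([rows[k] for k in rows], index=index)
    detected = pd.DataFrame([flags[k] for k in rows], index=index)
    return ConcentrationMatrix(values, detected), verdicts


def floor_matrix(
    matrix: ConcentrationMatrix, config: QuantConfig = QuantConfig()
) -> ConcentrationMatrix:
    """Raise every value below the detection floor to the floor.

    Idempotent; detected/non-detect flags are preserved (flooring is a
    censoring convention, not a detection)."""
    if (matrix.values.values < 0).any():
        raise ValueError("matrix has negative values; validate before flooring")
    values = matrix.values.clip(lower=config.floor_ce_per_mg)
    return ConcentrationMatrix(values, matrix.detected.copy())


# ---------------------------------------------------------------------------
# CSV interchange: long Ct schema and spike schema
# ---------------------------------------------------------------------------


def read_ct_csv(path: str | Path) -> list[CtRecord]:
    """Read ``sample_id,species_name,replicate,ct`` (ct empty = non-detect)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "species_name": str})
    out = []
    for r in df.itertuples():
        ct = None if pd.isna(r.ct) else float(r.ct)
        out.append(
            CtRecord(
                sample_id=str(r.sample_id),
                species_name=str(r.species_name),
                ct=ct,
                replicate=int(r.replicate),
            )
        )
    return out


def read_spike_csv(path: str | Path) -> list[SpikeInRecord]:
    """Read ``sample_id,ct_observed,ct_reference``."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    return [
        SpikeInRecord(str(r.sample_id), float(r.ct_observed), float(r.ct_reference))
        for r in df.itertuples()
    ]


def write_qc_report(verdicts: Iterable[QCVerdict], path: str | Path) -> None:
    verdicts = list(verdicts)
    df = pd.DataFrame(
        {
            "sample_id": [v.sample_id for v in verdicts],
            "verdict": [v.label for v in verdicts],
            "delta_cycles": [v.delta_cycles for v in verdicts],
        }
    )
    df.to_csv(path, index=False)
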