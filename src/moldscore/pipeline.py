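"""End-to-end run orchestration: quantify -> floor -> score -> compare.

One :class:`RunConfig` drives a full analysis producing the standard
report set — per-home scores, the per-species year-comparison table,
the Tukey letter report on diversity by region, extraction-QC verdicts
when starting from raw Ct records, and a diversity boxplot — plus a
manifest with a config echo and SHA-256 checksums so identical
configurations yield verifiably identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .inference import anova_tukey, species_comparison_battery
from .panel import (
    ConcentrationMatrix,
    MoldPanel,
    build_default_panel,
    read_concentration_csv,
    read_metadata_csv,
    validate_matrix,
)
from .quantify import (
    QuantConfig,
    floor_matrix,
    quantify_cohort,
    read_ct_csv,
    read_spike_csv,
    write_qc_report,
)
from .scoring import score_cohort

__all__ = ["RunConfig", "run_full_analysis", "summarize_table2"]

log = logging.getLogger("moldscore")


class ValidationError(ValueError):
    """Aggregated, human-readable schema violations."""


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``concentration_csv`` or ``ct_csv`` must be given;
    Ct input additionally needs ``spike_csv`` and ``sample_map_csv``
    (columns ``sample_id,home_id,year``).
    """

    metadata_csv: str
    out_dir: str
    concentration_csv: str | None = None
    ct_csv: str | None = None
    spike_csv: str | None = None
    sample_map_csv: str | None = None
    panel_json: str | None = None
    quant: QuantConfig = field(default_factory=QuantConfig)
    alpha: float = 0.05
    holm_family: str = "all"
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.concentration_csv is None) == (self.ct_csv is None):
            raise ValueError(
                "provide exactly one of concentration_csv or ct_csv"
            )
        if self.ct_csv is not None and (
            self.spike_csv is None or self.sample_map_csv is None
        ):
            raise ValueError("ct input requires spike_csv and sample_map_csv")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "quant" in raw and isinstance(raw["quant"], dict):
            raw["quant"] = QuantConfig(**raw["quant"])
        return cls(**raw)

    def echo(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_matrix(
    config: RunConfig, panel: MoldPanel, out: Path
) -> tuple[ConcentrationMatrix, list[Path]]:
    outputs: list[Path] = []
    if config.concentration_csv is not None:
        matrix = read_concentration_csv(config.concentration_csv)
        log.info("loaded %d concentration rows", len(matrix))
        return matrix, outputs
    records = read_ct_csv(config.ct_csv)
    spikes = read_spike_csv(config.spike_csv)
    sample_map = pd.read_csv(config.sample_map_csv, dtype={"home_id": str, "sample_id": str})
    keys = {
        str(r.sample_id): (str(r.home_id), int(r.year)) for r in sample_map.itertuples()
    }
    matrix, verdicts = quantify_cohort(records, spikes, keys, panel, config.quant)
    qc_path = out / "qc_report.csv"
    write_qc_report(verdicts, qc_path)
    outputs.append(qc_path)
    n_fail = sum(not v.passed for v in verdicts)
    log.info("quantified %d samples, %d spike-QC failures", len(verdicts), n_fail)
    return matrix, outputs


def summarize_table2(
    matrix_2018: ConcentrationMatrix,
    matrix_2019: ConcentrationMatrix,
    panel: MoldPanel,
) -> pd.DataFrame:
    """Per-species yearly mean CE/mg plus group log-sum and index rows.

    Averaging order is per-home score first, then cohort mean, which
    makes the mean index row equal the difference of the mean group
    log-sum rows exactly (linearity of the index in the log-sums).
    """
    from .scoring import ermi

    rows = []
    for assay in panel.assays:
        sp = assay.species_name
        rows.append(
            {
                "row": sp,
                "group": assay.group,
                "avg_2018": float(matrix_2018.values[sp].mean()),
                "avg_2019": float(matrix_2019.values[sp].mean()),
            }
        )

    def _means(matrix: ConcentrationMatrix) -> tuple[float, float, float]:
        res = [
            ermi(r, panel, home_id=h, year=int(y))
            for (h, y), r in matrix.values.iterrows()
        ]
        g1 = sum(x.sum_logs_g1 for x in res) / len(res)
        g2 = sum(x.sum_logs_g2 for x in res) / len(res)
        e = sum(x.ermi for x in res) / len(res)
        return g1, g2, e

    a = _means(matrix_2018)
    b = _means(matrix_2019)
    for i, name in enumerate(["Sum logs group 1", "Sum logs group 2", "ERMI"]):
        rows.append(
            {"row": name, "group": None, "avg_2018": a[i], "avg_2019": b[i]}
        )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole battery; returns the manifest (also written to disk).

    Outputs in ``config.out_dir``: ``scores.csv``,
    ``comparison_report.csv``, ``tukey_report.csv``, ``summary_table.csv``,
    ``sdi_boxplot.png``, ``qc_report.csv`` (Ct input only), and
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = (
        MoldPanel.from_json(config.panel_json)
        if config.panel_json
        else build_default_panel()
    )
    metadata = read_metadata_csv(config.metadata_csv)
    matrix, outputs = _load_matrix(config, panel, out)

    violations = validate_matrix(matrix, panel)
    if violations:
        raise ValidationError(
            "input matrix failed validation:\n  " + "\n  ".join(violations)
        )

    floored = floor_matrix(matrix, config.quant)
    scores = score_cohort(floored, metadata, panel, floor=config.quant.floor_ce_per_mg)
    scores_path = out / "scores.csv"
    scores.to_csv(scores_path, index=False)
    outputs.append(scores_path)

    years = sorted(scores["year"].unique())
    if len(years) == 2:
        m_a, m_b = (floored.for_year(y) for y in years)
        report = species_comparison_battery(
            m_a,
            m_b,
            panel,
            alpha=config.alpha,
            holm_family=config.holm_family,
            paired=config.paired,
        )
        n_nm = int(report.species["method"].eq("NM").sum())
        log.info(
            "year battery: %d species tested (Holm family %d, %d NM excluded)",
            len(report.species),
            report.holm_family_size,
            n_nm,
        )
        table = report.species.copy()
        table["group"] = table["group"].astype(float)
        extra = pd.DataFrame(
            [
                {
                    "species": name,
                    "group": np.nan,
                    "avg_2018": np.nan,
                    "avg_2019": np.nan,
                    "p_raw": res.p_raw,
                    "p_adjusted": np.nan,
                    "significant": res.p_raw <= config.alpha,
                    "method": res.method,
                }
                for name, res in report.group_tests.items()
            ]
        )
        table = pd.concat([table, extra], ignore_index=True)
        comp_path = out / "comparison_report.csv"
        table.to_csv(comp_path, index=False)
        outputs.append(comp_path)

        summary = summarize_table2(m_a, m_b, panel)
        summary_path = out / "summary_table.csv"
        summary.to_csv(summary_path, index=False)
        outputs.append(summary_path)

    # Tukey letters on diversity across region x year groups
    groups = {
        f"region{r}_{y}": sub["shannon_h"].to_numpy()
        for (r, y), sub in scores.groupby(["region", "year"])
        if len(sub) >= 2
    }
    if len(groups) >= 2:
        tk = anova_tukey(groups, alpha=config.alpha)
        if tk.small_groups:
            log.warning(
                "Tukey groups with n < 3 (weakly informed comparisons): %s",
                ", ".join(tk.small_groups),
            )
        tukey_df = pd.DataFrame(
            {
                "group": tk.labels,
                "mean": [tk.means[g] for g in tk.labels],
                "sd": [tk.sds[g] for g in tk.labels],
                "n": [tk.ns[g] for g in tk.labels],
                "letter": [tk.letters[g] for g in tk.labels],
            }
        )
        tukey_path = out / "tukey_report.csv"
        tukey_df.to_csv(tukey_path, index=False)
        outputs.append(tukey_path)

    fig_path = out / "sdi_boxplot.png"
    _plot_sdi(scores, fig_path)
    outputs.append(fig_path)

    manifest = {
        "config": config.echo(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _plot_sdi(scores: pd.DataFrame, path: Path) -> None:
    """Plain boxplot of Shannon H by region, one panel block per year."""
    years = sorted(scores["year"].unique())
    regions = sorted(scores["region"].unique())
    fig, axes = plt.subplots(1, len(years), figsize=(4 * len(years), 4), sharey=True)
    if len(years) == 1:
        axes = [axes]
    for ax, year in zip(axes, years):
        sub = scores[scores["year"] == year]
        data = [sub.loc[sub["region"] == r, "shannon_h"].to_numpy() for r in regions]
        ax.boxplot(data, tick_labels=[str(r) for r in regions])
        ax.set_title(str(year))
        ax.set_xlabel("region")
    axes[0].set_ylabel("Shannon H (nats)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
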