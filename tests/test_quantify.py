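import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moldscore import (
    ConcentrationMatrix,
    CtRecord,
    QuantConfig,
    SpikeInRecord,
    ct_to_cell_equivalents,
    floor_matrix,
    quantify_sample,
)
from moldscore.panel import AssayDefinition

ASSAY = AssayDefinition("Aspergillus flavus", 1)  # slope -3.3219, intercept 40
SPIKE_OK = SpikeInRecord("s1", ct_observed=22.0, ct_reference=22.0)


class TestCtConversion:
    def test_ct_at_intercept_is_one_ce(self):
        assert ct_to_cell_equivalents(40.0, ASSAY) == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles(self):
        assert ct_to_cell_equivalents(39.0, ASSAY) == pytest.approx(2.0, abs=1e-3)

    def test_closed_form_value(self):
        # 10 ** ((26.713 - 40) / -3.3219) = 1e4 to 0.5%
        assert ct_to_cell_equivalents(26.713, ASSAY) == pytest.approx(1e4, rel=5e-3)

    def test_out_of_range_ct_rejected(self):
        with pytest.raises(ValueError):
            ct_to_cell_equivalents(41.0, ASSAY)
        with pytest.raises(ValueError):
            ct_to_cell_equivalents(0.0, ASSAY)

    def test_non_detect_routed_to_floor_path(self):
        with pytest.raises(ValueError, match="floor path"):
            ct_to_cell_equivalents(None, ASSAY)

    @given(
        ct_lo=st.floats(1.0, 39.0),
        delta=st.floats(0.01, 1.0),
        slope=st.floats(-5.0, -1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_ct(self, ct_lo, delta, slope):
        """Lower Ct (more template) never yields lower CE."""
        assay = AssayDefinition("X", 1, slope=slope, intercept=40.0)
        assert ct_to_cell_equivalents(ct_lo, assay) >= ct_to_cell_equivalents(
            ct_lo + delta, assay
        )


class TestQuantifySample:
    def test_all_non_detect_gives_zero_row_qc_pass(self, panel):
        records = [CtRecord("s1", s, ct=None) for s in panel.species_names]
        values, detected, verdict = quantify_sample(records, SPIKE_OK, panel)
        assert (values == 0).all()
        assert not detected.any()
        assert verdict.passed

    def test_per_mg_division(self, panel):
        # CE 500 over 5 mg dust -> 100 CE/mg
        ct = 40.0 + ASSAY.slope * np.log10(500.0)
        records = [CtRecord("s1", "Aspergillus flavus", ct=ct)]
        values, detected, _ = quantify_sample(records, SPIKE_OK, panel)
        assert values["Aspergillus flavus"] == pytest.approx(100.0)
        assert detected["Aspergillus flavus"]

    def test_replicates_averaged_on_ce_scale(self, panel):
        cts = [40.0 + ASSAY.slope * np.log10(ce) for ce in (100.0, 300.0)]
        records = [
            CtRecord("s1", "Aspergillus flavus", ct=c, replicate=i)
            for i, c in enumerate(cts)
        ]
        values, _, _ = quantify_sample(records, SPIKE_OK, panel)
        # mean CE = 200, over 5 mg -> 40; averaging Ct instead would give
        # the geometric mean (sqrt(3)*100 ~ 173 CE -> 34.6)
        assert values["Aspergillus flavus"] == pytest.approx(40.0)

    def test_spike_failure_flags_but_returns(self, panel):
        spike = SpikeInRecord("s1", ct_observed=27.0, ct_reference=22.0)
        records = [CtRecord("s1", "Wallemia sebi", ct=30.0)]
        values, _, verdict = quantify_sample(records, spike, panel)
        assert not verdict.passed
        assert verdict.delta_cycles == pytest.approx(5.0)
        assert values["Wallemia sebi"] > 0  # still returned

    def test_unknown_species_named_in_error(self, panel):
        with pytest.raises(KeyError, match="Fusarium"):
            quantify_sample([CtRecord("s1", "Fusarium sp", ct=30.0)], SPIKE_OK, panel)

    def test_duplicate_replicate_rejected(self, panel):
        records = [
            CtRecord("s1", "Wallemia sebi", ct=30.0, replicate=1),
            CtRecord("s1", "Wallemia sebi", ct=31.0, replicate=1),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            quantify_sample(records, SPIKE_OK, panel)

    def test_scaling_replicate_ce_scales_row(self, panel, rng):
        """Multiplying every replicate CE by c multiplies the row by c."""
        ces = rng.uniform(10, 1e5, size=5)
        c = 7.0

        def row_for(ce_values):
            records = [
                CtRecord("s1", "Wallemia sebi", 40.0 + ASSAY.slope * np.log10(ce), i)
                for i, ce in enumerate(ce_values)
            ]
            return quantify_sample(records, SPIKE_OK, panel)[0]

        base = row_for(ces)["Wallemia sebi"]
        scaled = row_for(c * ces)["Wallemia sebi"]
        assert scaled == pytest.approx(c * base, rel=1e-9)


class TestFloorMatrix:
    def _matrix(self, panel, fill):
        rows = {("h1", 2018): {s: fill for s in panel.species_names}}
        return ConcentrationMatrix.from_rows(rows, list(panel.species_names))

    def test_zero_floored_to_one(self, panel):
        m = floor_matrix(self._matrix(panel, 0.0))
        assert (m.values.values == 1.0).all()

    def test_large_values_unchanged(self, panel):
        m = floor_matrix(self._matrix(panel, 2318.0))
        assert (m.values.values == 2318.0).all()

    def test_idempotent_on_random_matrix(self, panel, rng):
        rows = {
            (f"h{i}", 2018): {
                s: v
                for s, v in zip(
                    panel.species_names, rng.uniform(0, 100, size=36) ** 2
                )
            }
            for i in range(5)
        }
        m = ConcentrationMatrix.from_rows(rows, list(panel.species_names))
        once = floor_matrix(m)
        twice = floor_matrix(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_flags_preserved(self, panel):
        m = self._matrix(panel, 0.0)
        floored = floor_matrix(m)
        assert not floored.detected.any().any()

    def test_negative_rejected(self, panel):
        m = self._matrix(panel, 1.0)
        m.values.iloc[0, 0] = -1.0
        with pytest.raises(ValueError):
            floor_matrix(m)
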