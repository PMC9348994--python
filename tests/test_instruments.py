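"""Instrument selection, harmonization, GRS arithmetic and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from vitdmr import instruments, simulate
from vitdmr.simulate import SimParams

from conftest import make_summary_table


class TestSelectInstruments:
    def _tables(self):
        # five variants; v3 fails directional consistency, v4 fails MAF,
        # v5 fails replication significance -> expect {v1, v2} kept... and
        # v0 kept: hand-enumerated truth table
        discovery = make_summary_table([
            ("v0", "A", "G", 0.30, 1.0, 0.1, 1e-8),
            ("v1", "C", "T", 0.45, -0.8, 0.1, 1e-6),
            ("v2", "G", "A", 0.80, 0.5, 0.1, 1e-5),   # MAF 0.20, fine
            ("v3", "A", "C", 0.30, 0.6, 0.1, 1e-6),   # replication flips sign
            ("v4", "T", "C", 0.03, 0.9, 0.1, 1e-9),   # MAF 3% -> dropped
        ])
        replication = make_summary_table([
            ("v0", "A", "G", 0.31, 0.9, 0.2, 1e-4),
            ("v1", "C", "T", 0.44, -0.7, 0.2, 0.01),
            ("v2", "G", "A", 0.79, 0.4, 0.2, 0.04),
            ("v3", "A", "C", 0.30, -0.5, 0.2, 0.001),
            ("v4", "T", "C", 0.03, 0.8, 0.2, 1e-5),
            ("v9", "A", "G", 0.50, 1.0, 0.2, 1e-5),   # not in discovery
        ])
        return discovery, replication

    def test_filter_truth_table(self):
        discovery, replication = self._tables()
        panel = instruments.select_instruments(discovery, replication)
        assert sorted(panel["variant_id"]) == ["v0", "v1", "v2"]
        # weights come from the replication side
        assert panel.set_index("variant_id").loc["v0", "beta"] == 0.9

    def test_replication_p_threshold(self):
        discovery, replication = self._tables()
        panel = instruments.select_instruments(discovery, replication,
                                               p_replication=0.02)
        assert sorted(panel["variant_id"]) == ["v0", "v1"]

    def test_empty_intersection(self):
        discovery, replication = self._tables()
        with pytest.raises(ValueError, match="shared"):
            instruments.select_instruments(
                discovery, replication.assign(variant_id=lambda d: d.variant_id + "_x")
            )


class TestHarmonize:
    def _pair(self):
        exposure = make_summary_table([
            ("s1", "A", "G", 0.30, 0.5, 0.05, 1e-8),   # same alleles
            ("s2", "C", "T", 0.20, 0.4, 0.05, 1e-8),   # swapped on outcome side
            ("s3", "A", "T", 0.50, 0.3, 0.05, 1e-8),   # palindromic, ambiguous
            ("s4", "A", "T", 0.10, 0.3, 0.05, 1e-8),   # palindromic, resolvable
            ("s5", "G", "C", 0.55, 0.2, 0.05, 1e-8),   # palindromic, ambiguous
            ("s6", "A", "G", 0.30, 0.6, 0.05, 1e-8),   # allele mismatch
        ])
        outcome = make_summary_table([
            ("s1", "A", "G", 0.31, 0.10, 0.02, 0.1),
            ("s2", "T", "C", 0.81, 0.10, 0.02, 0.1),
            ("s3", "A", "T", 0.50, 0.10, 0.02, 0.1),
            ("s4", "T", "A", 0.89, 0.10, 0.02, 0.1),
            ("s5", "G", "C", 0.54, 0.10, 0.02, 0.1),
            ("s6", "A", "C", 0.30, 0.10, 0.02, 0.1),
        ])
        return exposure, outcome

    def test_action_classification(self):
        exposure, outcome = self._pair()
        h = instruments.harmonize(exposure, outcome).set_index("variant_id")
        assert h.loc["s1", "harmonization_action"] == "kept"
        assert h.loc["s2", "harmonization_action"] == "flipped"
        assert h.loc["s2", "beta_outcome"] == pytest.approx(-0.10)
        assert h.loc["s2", "eaf_outcome"] == pytest.approx(0.19)
        assert h.loc["s3", "harmonization_action"] == "dropped_palindromic"
        assert h.loc["s4", "harmonization_action"] == "flipped"
        assert h.loc["s4", "eaf_outcome"] == pytest.approx(0.11)
        assert h.loc["s5", "harmonization_action"] == "dropped_palindromic"
        assert h.loc["s6", "harmonization_action"] == "dropped_mismatch"
        multiset = sorted(h["harmonization_action"])
        assert multiset == ["dropped_mismatch", "dropped_palindromic",
                            "dropped_palindromic", "flipped", "flipped", "kept"]

    def test_strand_complement_kept(self):
        exposure = make_summary_table([("s1", "A", "G", 0.3, 0.5, 0.05, 1e-8)])
        outcome = make_summary_table([("s1", "T", "C", 0.3, 0.2, 0.02, 0.1)])
        h = instruments.harmonize(exposure, outcome)
        assert h.loc[0, "harmonization_action"] == "kept"
        assert h.loc[0, "beta_outcome"] == pytest.approx(0.2)

    def test_idempotent(self):
        exposure, outcome = self._pair()
        h1 = instruments.harmonize(exposure, outcome)
        kept1 = instruments.kept(h1)
        # re-express the aligned outcome side as a summary table and re-run
        outcome_aligned = kept1.rename(
            columns={"beta_outcome": "beta", "se_outcome": "se",
                     "eaf_outcome": "eaf"}
        )[["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se"]]
        outcome_aligned["pval"] = 0.5
        h2 = instruments.harmonize(exposure, outcome_aligned)
        kept2 = instruments.kept(h2)
        assert (kept2["harmonization_action"] == "kept").all()
        np.testing.assert_allclose(kept2["beta_outcome"], kept1["beta_outcome"])

    def test_missing_allele_columns(self):
        exposure, outcome = self._pair()
        with pytest.raises(ValueError, match="allele column"):
            instruments.harmonize(exposure, outcome.drop(columns="other_allele"))


class TestGRS:
    def _panel(self):
        return pd.DataFrame(
            {"variant_id": ["a", "b", "c"], "effect_allele": "A",
             "other_allele": "G", "eaf": [0.2, 0.4, 0.5],
             "beta": [1.5, -0.5, 2.0], "se": 0.1, "pval": 1e-6, "block": "x"}
        )

    def test_hand_dot_products(self):
        dosages = np.array([[0, 1, 2], [2, 2, 0], [1, 0, 1]], dtype=float)
        grs = instruments.compute_grs(dosages, self._panel())
        np.testing.assert_allclose(grs, [3.5, 2.0, 3.5])

    def test_zero_weights_and_identity(self):
        panel = self._panel()
        dosages = np.array([[0, 1, 2], [2, 2, 0]], dtype=float)
        zero = panel.assign(beta=0.0)
        np.testing.assert_allclose(instruments.compute_grs(dosages, zero), 0.0)
        single = panel.iloc[:1].assign(beta=1.0)
        np.testing.assert_allclose(
            instruments.compute_grs(dosages[:, :1], single), dosages[:, 0]
        )

    def test_missing_imputed_as_2eaf(self):
        dosages = np.array([[np.nan, 1.0, 2.0]])
        grs = instruments.compute_grs(dosages, self._panel())
        assert grs[0] == pytest.approx(2 * 0.2 * 1.5 + 1 * -0.5 + 2 * 2.0)

    def test_column_mismatch(self):
        with pytest.raises(ValueError, match="columns"):
            instruments.compute_grs(np.zeros((5, 2)), self._panel())


class TestDiagnostics:
    def test_closed_form_ols(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=10)
        v = 2.0 + 0.7 * g + rng.normal(size=10)
        diag, resid = instruments.instrument_diagnostics(g, v)
        slope, intercept = np.polyfit(g, v, 1)
        np.testing.assert_allclose(resid, v - slope * g - intercept + v.mean(),
                                   atol=1e-10)
        r2_oracle = np.corrcoef(g, v)[0, 1] ** 2
        assert diag.r2 == pytest.approx(r2_oracle, abs=1e-12)
        assert diag.f_stat == pytest.approx(diag.r2 * 8 / (1 - diag.r2), abs=1e-12)

    def test_residual_orthogonality_and_scale(self, small_cohort):
        _, cohort = small_cohort
        diag, resid = instruments.instrument_diagnostics(
            cohort["grs"].to_numpy(), cohort["vitd"].to_numpy()
        )
        assert abs(np.corrcoef(resid, cohort["grs"])[0, 1]) < 1e-10
        assert resid.mean() == pytest.approx(cohort["vitd"].mean())

    def test_uncorrelated_grs(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=2000)
        v = rng.normal(50, 20, size=2000)
        diag, resid = instruments.instrument_diagnostics(g, v)
        assert diag.r2 < 0.01
        np.testing.assert_allclose(resid, v, atol=2.5)

    def test_zero_variance_grs(self):
        with pytest.raises(ValueError, match="zero variance"):
            instruments.instrument_diagnostics(np.ones(10), np.arange(10.0))


class TestLeaveBlockOut:
    def test_absent_block_is_noop(self, small_cohort):
        panel, _ = small_cohort
        out = instruments.leave_block_out(panel, block="no-such-block")
        pd.testing.assert_frame_equal(out, panel.reset_index(drop=True))

    def test_exclude_all_raises(self, small_cohort):
        panel, _ = small_cohort
        single_block = panel.assign(block="only")
        with pytest.raises(ValueError, match="zero variants"):
            instruments.leave_block_out(single_block, block="only")

    def test_dominant_block_reduces_r2(self, small_cohort):
        panel, cohort = small_cohort
        reduced = instruments.leave_block_out(panel, block="binding protein")
        assert len(reduced) < len(panel)
        full_grs = instruments.compute_grs(cohort, panel)
        red_grs = instruments.compute_grs(cohort, reduced)
        v = cohort["vitd"].to_numpy()
        r2_full = instruments.instrument_diagnostics(full_grs, v)[0].r2
        r2_red = instruments.instrument_diagnostics(red_grs, v)[0].r2
        assert r2_red < r2_full

    def test_leave_one_variant_out(self, small_cohort):
        panel, _ = small_cohort
        vid = panel.loc[3, "variant_id"]
        out = instruments.leave_block_out(panel, variant_id=vid)
        assert vid not in set(out["variant_id"]) and len(out) == len(panel) - 1
        with pytest.raises(ValueError, match="not present"):
            instruments.leave_block_out(panel, variant_id="rs0")
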