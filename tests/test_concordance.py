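import collections

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lnconcord import (
    ConcordanceCategory,
    DomainError,
    EnhancementPattern,
    IntegrityError,
    SimConfig,
    attach_station_outcome,
    cohort_summary,
    compute_lnr,
    compute_spr,
    correlation_category,
    generate_cohort,
    pattern_association,
    station_concordance,
)


class TestCategory:
    @pytest.mark.parametrize(
        "s, p, expected",
        [
            (3, 2, ConcordanceCategory.positive),
            (0, 0, ConcordanceCategory.negative),
            (2, 0, ConcordanceCategory.false_positive),
            (0, 4, ConcordanceCategory.false_negative),
        ],
    )
    def test_examples(self, s, p, expected):
        assert correlation_category(s, p) is expected

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            correlation_category(-1, 0)

    @given(st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, s, p):
        assert correlation_category(s, p) in ConcordanceCategory


class TestRatios:
    def test_spr_examples(self):
        assert compute_spr(10, 10) == pytest.approx(1.0)
        assert round(compute_spr(241, 412), 3) == 0.585
        assert compute_spr(5, 0) is None  # undefined, never infinity

    @given(st.integers(0, 1000), st.integers(1, 1000))
    @settings(max_examples=200, deadline=None)
    def test_spr_identity(self, s, p):
        assert compute_spr(s, p) * p == pytest.approx(s)

    def test_lnr_examples(self):
        assert round(compute_lnr(170, 1809), 4) == 0.0940
        assert compute_lnr(0, 12) == 0.0
        assert compute_lnr(12, 12) == 1.0

    def test_lnr_domain(self):
        with pytest.raises(DomainError):
            compute_lnr(1, 0)
        with pytest.raises(DomainError):
            compute_lnr(13, 12)


class TestStationConcordance:
    def test_single_station_composition(self, registry):
        ct = pd.DataFrame({
            "patient_id": ["P1"] * 2,
            "station_code": ["241"] * 2,
            "suspicious": [True, True],
        })
        histo = pd.DataFrame({
            "patient_id": ["P1"] * 4,
            "station_code": ["241"] * 4,
            "metastatic": [True, False, False, False],
        })
        rec = station_concordance(ct, histo, registry)
        assert len(rec) == 1
        row = rec.iloc[0]
        assert row["category"] == "positive"
        assert row["spr"] == pytest.approx(2.0)
        assert row["band"] == "locoregional"

    def test_station_only_in_histology_is_negative(self, registry):
        ct = pd.DataFrame({"patient_id": [], "station_code": [], "suspicious": []})
        histo = pd.DataFrame({
            "patient_id": ["P1"], "station_code": ["251"], "metastatic": [False],
        })
        rec = station_concordance(ct, histo, registry)
        assert rec.iloc[0]["category"] == "negative"
        assert rec.iloc[0]["n_ct"] == 0

    def test_unresolvable_code_named_in_error(self, registry):
        ct = pd.DataFrame({
            "patient_id": ["P1"], "station_code": ["999"], "suspicious": [True],
        })
        histo = pd.DataFrame({"patient_id": [], "station_code": [], "metastatic": []})
        with pytest.raises(DomainError, match="999"):
            station_concordance(ct, histo, registry)

    def test_counts_equal_brute_force_recount(self, registry):
        """Counts on a simulated cohort equal an independent dict-based
        group-by recount."""
        _, ct, histo = generate_cohort(SimConfig(n_patients=25), registry, seed=3)
        rec = station_concordance(ct, histo, registry, by_patient=True)

        expected = collections.defaultdict(lambda: [0, 0, 0, 0])
        for row in ct.itertuples():
            key = (row.patient_id, row.station_code)
            expected[key][0] += 1
            expected[key][1] += bool(row.suspicious)
        for row in histo.itertuples():
            key = (row.patient_id, row.station_code)
            expected[key][2] += 1
            expected[key][3] += bool(row.metastatic)

        got = {
            (r.patient_id, r.station_code):
                [r.n_ct, r.n_suspicious, r.n_harvested, r.n_positive]
            for r in rec.itertuples()
        }
        assert got == dict(expected)


class TestCohortSummary:
    def test_hand_computed_two_patient_fixture(self, registry, hand_cohort):
        patients, ct, histo = hand_cohort
        s = cohort_summary(patients, ct, histo, registry)
        assert s.n_patients == 2
        assert s.n_ct_nodes == 6 and s.n_suspicious == 4
        assert s.n_harvested == 10 and s.n_positive == 3
        assert s.overall_lnr == pytest.approx(0.3)
        assert s.overall_spr == pytest.approx(4 / 3)
        assert s.patient_positive_fraction == pytest.approx(1.0)
        # bands: 241/251 locoregional, 242/252 intermediate, 253 central
        assert s.band_spr["locoregional"] == pytest.approx(2 / 3)
        assert s.band_spr["intermediate"] is None   # 2 suspicious, 0 positive
        assert s.band_spr["central"] is None
        assert s.site_spr["sigmoid"] == pytest.approx(3 / 2)
        assert s.site_spr["superior_rectum"] == pytest.approx(1.0)
        assert s.site_spr["cecum"] is None
        assert s.category_counts == {
            "positive": 1, "negative": 2, "false_positive": 2,
            "false_negative": 1,
        }
        # node-level 2x2 against station-context labels
        t = s.node_table
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 1)
        assert s.node_metrics.sensitivity == pytest.approx(2 / 3)
        assert s.node_metrics.specificity == pytest.approx(1 / 3)
        # both patients test- and disease-positive
        assert (s.patient_table.a, s.patient_table.d) == (2, 0)
        assert s.patient_metrics.sensitivity == 1.0
        assert s.patient_metrics.specificity is None

    def test_band_spr_all_one_when_counts_match(self, registry):
        """Constructed equality: per band, suspicious count == positive count."""
        ct = pd.DataFrame({
            "node_id": ["a", "b", "c"],
            "patient_id": ["P1"] * 3,
            "station_code": ["241", "242", "253"],
            "suspicious": [True, True, True],
        })
        histo = pd.DataFrame({
            "node_id": ["h1", "h2", "h3"],
            "patient_id": ["P1"] * 3,
            "station_code": ["241", "242", "253"],
            "metastatic": [True, True, True],
        })
        patients = pd.DataFrame({
            "patient_id": ["P1"], "sex": ["M"], "age": [60.0],
            "tumor_site": ["sigmoid"],
        })
        s = cohort_summary(patients, ct, histo, registry)
        assert all(v == pytest.approx(1.0) for v in s.band_spr.values())

    def test_orphan_patient_is_integrity_error(self, registry, hand_cohort):
        patients, ct, histo = hand_cohort
        with pytest.raises(IntegrityError, match="P99"):
            cohort_summary(
                patients, ct,
                pd.concat([histo, pd.DataFrame({
                    "node_id": ["hX"], "patient_id": ["P99"],
                    "station_code": ["241"], "metastatic": [True],
                })], ignore_index=True),
                registry,
            )


class TestAttachStationOutcome:
    def test_labels_follow_patient_station(self, hand_cohort):
        _, ct, histo = hand_cohort
        lab = attach_station_outcome(ct, histo)
        by_node = lab.set_index("node_id")["metastatic"]
        # P1 station 241 and P2 station 251 are the metastatic stations
        assert by_node[["n1", "n2", "n5"]].all()
        assert not by_node[["n3", "n4", "n6"]].any()


class TestPatternAssociation:
    def test_single_pattern_is_degenerate(self):
        with pytest.raises(DomainError, match="degenerate"):
            pattern_association([("dotted", True), ("dotted", False)])

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            pattern_association([])

    def test_null_association_gives_unit_ors(self):
        """Outcome independent of pattern -> every one-vs-rest OR is 1."""
        rows = []
        for pat in ("homogenous", "dotted", "linear"):
            rows += [(pat, True)] * 10 + [(pat, False)] * 30
        ors = pattern_association(rows)
        for res in ors.values():
            assert res.odds_ratio == pytest.approx(1.0)

    def test_orientation_is_odds_of_metastasis(self):
        # dotted nodes: 8 met / 2 clean; others: 2 met / 8 clean -> OR 16
        rows = [("dotted", True)] * 8 + [("dotted", False)] * 2
        rows += [("homogenous", True)] * 2 + [("homogenous", False)] * 8
        res = pattern_association(rows)[EnhancementPattern.dotted]
        assert res.odds_ratio == pytest.approx(16.0)
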