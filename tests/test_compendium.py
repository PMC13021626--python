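"""Compendium I/O, regulation calling, site frequencies and predominance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosphocoreg import (
    Call,
    CompendiumError,
    SiteID,
    Thresholds,
    classify_observation,
    predominant_sites,
    predominant_sites_for_protein,
    read_compendium,
    site_frequencies,
    write_compendium,
)
from phosphocoreg.synthetic import SyntheticParams, generate

from conftest import HEADER, compendium_text


class TestSiteID:
    def test_label_round_trip(self):
        s = SiteID("TNIK", 640, "S", "Q9UKE5")
        assert s.label == "TNIK_S640"
        assert SiteID.parse("TNIK_S640") == s  # accession not compared

    @pytest.mark.parametrize("bad", ["TNIK_X640", "TNIK-S640", "_S640", "TNIK_S0x"])
    def test_rejects_malformed_labels(self, bad):
        with pytest.raises(ValueError):
            SiteID.parse(bad)

    def test_rejects_bad_fields(self):
        with pytest.raises(ValueError):
            SiteID("TNIK", 0, "S")
        with pytest.raises(ValueError):
            SiteID("TNIK", 640, "A")


class TestClassifyObservation:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.3, 0.01, Call.UP),  # boundary inclusive
            (0.76, 0.04, Call.DOWN),  # boundary inclusive
            (2.0, 0.2, Call.NS),  # significance required
            (1.0, 0.001, Call.NS),  # unchanged abundance
            (1.29, 0.01, Call.NS),
            (2.0, 0.05, Call.NS),  # p-value strictly < alpha
        ],
    )
    def test_call_boundaries(self, fc, p, expected):
        assert classify_observation(fc, p) is expected

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            classify_observation(0.0, 0.01)
        with pytest.raises(ValueError):
            classify_observation(-2.0, 0.01)

    def test_missing_pvalue_default_ns_opt_in_trusted(self):
        assert classify_observation(2.0, None) is Call.NS
        assert classify_observation(2.0, None, trust_prefiltered=True) is Call.UP
        assert classify_observation(0.5, float("nan"), trust_prefiltered=True) is Call.DOWN

    @settings(max_examples=200, deadline=None)
    @given(
        fc=st.floats(0.01, 20.0),
        p=st.floats(0.001, 1.0, exclude_max=False),
        dfc=st.floats(0.0, 5.0),
        dp=st.floats(0.0, 0.9),
    )
    def test_monotone_in_fold_change_and_pvalue(self, fc, p, dfc, dp):
        """Raising FC never flips UP->DOWN; lowering p never flips UP->NS."""
        base = classify_observation(fc, p)
        raised = classify_observation(fc + dfc, p)
        if base is Call.UP:
            assert raised is Call.UP
        lowered_p = classify_observation(fc, max(p - dp, 1e-9))
        if base in (Call.UP, Call.DOWN):
            assert lowered_p is base


class TestReadWrite:
    def test_direct_load(self, tmp_path):
        rows = [
            "ds1\tP1\tcA\tdifferential\tTNIK\tQ\tS\t640\t2.0\t0.01",
            "ds1\tP1\tcA\tdifferential\tABC\tQ2\tT\t5\t0.5\t0.001",
            "pf1\tP1\tcA\tprofiling\tTNIK\tQ\tS\t640\t\t",
        ]
        path = tmp_path / "c.tsv"
        path.write_text(compendium_text(rows))
        c = read_compendium(path)
        assert len(c.observations) == 3
        assert set(c.observations["call"]) == {"UP", "DOWN", "DETECTED"}

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("dataset_id\tpmid\nx\ty\n")
        with pytest.raises(CompendiumError, match="condition_code"):
            read_compendium(path)

    def test_duplicate_site_dataset_rejected_and_collapsible(self, tmp_path):
        rows = [
            "ds1\tP1\tcA\tdifferential\tTNIK\tQ\tS\t640\t2.0\t0.01",
            "ds1\tP1\tcA\tdifferential\tTNIK\tQ\tS\t640\t0.4\t0.01",
        ]
        path = tmp_path / "c.tsv"
        path.write_text(compendium_text(rows))
        with pytest.raises(CompendiumError, match="TNIK_S640@ds1"):
            read_compendium(path)
        c = read_compendium(path, on_duplicate="collapse")
        assert len(c.observations) == 1
        # |log 0.4| > |log 2.0|: the DOWN peptide is the more extreme one
        assert c.observations["fold_change"].iloc[0] == 0.4

    def test_invalid_kind_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(compendium_text(["ds1\tP1\tcA\tqualitative\tTNIK\tQ\tS\t640\t2.0\t0.01"]))
        with pytest.raises(CompendiumError, match="kind"):
            read_compendium(path)

    def test_mapping_table_remaps_symbols(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(compendium_text(["ds1\tP1\tcA\tdifferential\tOLDNAME\tQ\tS\t640\t2.0\t0.01"]))
        mapping = pd.DataFrame({"old_symbol": ["OLDNAME"], "new_symbol": ["TNIK"]})
        c = read_compendium(path, mapping=mapping)
        assert list(c.observations["gene_symbol"]) == ["TNIK"]

    def test_round_trip_preserves_contents(self, tmp_path):
        """Write-then-reread equality on a 2 profiling + 2 differential fixture."""
        c, _ = generate(SyntheticParams(seed=3, n_datasets=2, n_studies=2, n_pos_coupled=2,
                                        n_neg_coupled=2, n_background=5, n_profiling_datasets=2))
        out = tmp_path / "round.tsv"
        write_compendium(c, out)
        c2 = read_compendium(out)
        assert c2.datasets.sort_index().equals(c.datasets.sort_index())
        key = ["dataset_id", "gene_symbol", "residue", "position"]
        a = c.observations.sort_values(key).reset_index(drop=True)
        b = c2.observations.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b[a.columns], check_dtype=False)
        assert list(a["call"]) == list(b["call"])


class TestFrequenciesAndPredominance:
    def test_counts_are_distinct_datasets(self, small_compendium):
        freqs = site_frequencies(small_compendium, "TNIK")
        row = freqs.loc["TNIK_S640"]
        assert row["profiling_count"] == 2
        assert row["up_count"] == 1 and row["down_count"] == 1
        assert row["differential_count"] == 2

    def test_ns_does_not_count_as_differential(self, small_compendium):
        freqs = site_frequencies(small_compendium, "OTHER")
        assert freqs.loc["OTHER_T20", "differential_count"] == 0
        assert freqs.loc["OTHER_S10", "differential_count"] == 2

    def test_unknown_protein_warns_and_returns_empty(self, small_compendium):
        with pytest.warns(UserWarning, match="NOPE"):
            freqs = site_frequencies(small_compendium, "NOPE")
        assert freqs.empty

    def test_planted_counts_recovered(self):
        """Generator ground truth: anchor differential count equals the truth map."""
        c, truth = generate(SyntheticParams(seed=11, n_background=20, n_pos_coupled=0, n_neg_coupled=0))
        freqs = site_frequencies(c, "TNIK")
        assert freqs.loc["TNIK_S640", "differential_count"] == len(truth.anchor_direction)
        ups = sum(1 for d in truth.anchor_direction.values() if d == "UP")
        assert freqs.loc["TNIK_S640", "up_count"] == ups

    def test_predominance_strict_majority(self):
        freqs = pd.DataFrame(
            {
                "gene_symbol": ["T", "T"],
                "residue": ["S", "S"],
                "position": [10, 20],
                "profiling_count": [0, 0],
                "up_count": [6, 5],
                "down_count": [0, 0],
                "differential_count": [6, 5],
            },
            index=["T_S10", "T_S20"],
        )
        hits = predominant_sites(freqs, denominator=10)
        assert [s.label for s in hits] == ["T_S10"]  # 6/10 in, 5/10 out (strict >)

    def test_predominance_tie_break_by_position(self):
        freqs = pd.DataFrame(
            {
                "gene_symbol": ["T"] * 2,
                "residue": ["S"] * 2,
                "position": [99, 7],
                "profiling_count": [0, 0],
                "up_count": [8, 8],
                "down_count": [0, 0],
                "differential_count": [8, 8],
            },
            index=["T_S99", "T_S7"],
        )
        assert [s.position for s in predominant_sites(freqs, 10)] == [7, 99]

    def test_empty_table_gives_empty_list(self):
        assert predominant_sites(pd.DataFrame(columns=["gene_symbol", "residue", "position", "differential_count"]), 5) == []

    def test_row_permutation_invariance(self, tmp_path):
        rows = [
            "ds1\tP1\tcA\tdifferential\tT\tQ\tS\t10\t2.0\t0.01",
            "ds2\tP1\tcB\tdifferential\tT\tQ\tS\t10\t1.5\t0.01",
            "ds2\tP1\tcB\tdifferential\tT\tQ\tS\t20\t2.0\t0.01",
            "ds3\tP2\tcA\tdifferential\tT\tQ\tS\t10\t1.6\t0.02",
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text(compendium_text(rows))
        p2.write_text(compendium_text(rows[::-1]))
        out1 = predominant_sites_for_protein(read_compendium(p1), "T")
        out2 = predominant_sites_for_protein(read_compendium(p2), "T")
        assert out1 == out2 == [SiteID("T", 10, "S")]

    def test_per_dataset_call_count_consistency(self):
        """Sum of UP+DOWN+NS over sites equals differential observations per dataset."""
        c, _ = generate(SyntheticParams(seed=5, n_background=15))
        obs = c.observations
        for ds in c.differential_ids:
            sub = obs[obs["dataset_id"] == ds]
            n_calls = sub["call"].isin(["UP", "DOWN", "NS"]).sum()
            assert n_calls == len(sub)


class TestThresholds:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(up_fc=0.9)
        with pytest.raises(ValueError):
            Thresholds(alpha=0.0)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "th.yaml"
        path.write_text("up_fc: 1.5\nhc_min_pmids: 2\n")
        th = Thresholds.from_yaml(path)
        assert th.up_fc == 1.5 and th.hc_min_pmids == 2 and th.down_fc == 0.76

    def test_yaml_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "th.yaml"
        path.write_text("up_fold: 1.5\n")
        with pytest.raises(CompendiumError, match="up_fold"):
            Thresholds.from_yaml(path)
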