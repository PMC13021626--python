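"""Pair tallies, one-sided Fisher exact tests and the high-confidence screen."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosphocoreg import SiteID, Thresholds
from phosphocoreg.coreg import (
    CoregResult,
    PairTally,
    coregulation_screen,
    fet_pvalue,
    high_confidence,
    passing_sites,
    screen_to_frame,
    tally_pair,
)
from phosphocoreg.synthetic import SyntheticParams, generate


def hypergeom_oracle(a: int, b: int, c: int, d: int, direction: str) -> float:
    """Exact one-sided p by enumeration over all 2x2 tables with the observed margins.

    Conditional on both margins, the top-left count X is hypergeometric;
    the positive (concordance) alternative sums P(X >= a), the negative
    alternative P(X <= a).  Integer arithmetic until the final division.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = range(a, hi + 1) if direction == "positive" else range(lo, a + 1)
    num = sum(comb(r1, k) * comb(r2, c1 - k) for k in ks)
    return num / comb(n, c1)


def make_tally(a, b, c, d, **kw):
    return PairTally(anchor=SiteID("T", 1, "S"), other=SiteID("O", 2, "S"),
                     nUU=a, nUD=b, nDU=c, nDD=d, **kw)


class TestTallyPair:
    def test_table_one_categories(self, small_compendium, anchor):
        """Concordant UP-UP and DOWN-DOWN datasets land in nUU and nDD."""
        t = tally_pair(small_compendium, anchor, SiteID("OTHER", 10, "S"))
        assert (t.nUU, t.nUD, t.nDU, t.nDD) == (1, 0, 0, 1)
        assert t.pmids_concordant == {"P02", "P03"}
        assert t.codes_concordant == {"cA", "cB"}
        assert t.anchor_diff_total == 2

    def test_ns_everywhere_gives_empty_tally(self, small_compendium, anchor):
        t = tally_pair(small_compendium, anchor, SiteID("OTHER", 20, "T"))
        assert t.n_codifferential == 0

    def test_anchor_never_differential_warns(self, small_compendium):
        with pytest.warns(UserWarning, match="differential in no dataset"):
            t = tally_pair(small_compendium, SiteID("OTHER", 20, "T"), SiteID("OTHER", 10, "S"))
        assert t.anchor_diff_total == 0

    def test_perfect_coupling_tally(self, anchor):
        c, truth = generate(SyntheticParams(seed=2, n_datasets=10, n_studies=2, n_pos_coupled=2,
                                            n_neg_coupled=0, n_background=0,
                                            coupling_prob=1.0, detection_prob=1.0))
        for site in truth.pos_coupled:
            t = tally_pair(c, anchor, site)
            assert t.nUD == t.nDU == 0


class TestFetPvalue:
    def test_five_five_diagonal(self):
        """[[5,0],[0,5]] positive: 1 of C(10,5)=252 equally extreme tables."""
        assert fet_pvalue(make_tally(5, 0, 0, 5), "positive") == pytest.approx(1 / 252, abs=1e-12)

    def test_all_zero_table_uninformative(self):
        assert fet_pvalue(make_tally(0, 0, 0, 0), "positive") == 1.0
        assert fet_pvalue(make_tally(0, 0, 0, 0), "negative") == 1.0

    def test_oracle_agreement_small_sweep(self):
        """Implementation equals margin-conditional enumeration (margins <= 6)."""
        for a in range(7):
            for b in range(7 - a):
                for c in range(7):
                    for d in range(7 - c):
                        t = make_tally(a, b, c, d)
                        for direction in ("positive", "negative"):
                            expected = hypergeom_oracle(a, b, c, d, direction)
                            assert fet_pvalue(t, direction) == pytest.approx(expected, abs=1e-12)

    def test_column_swap_maps_positive_to_negative(self):
        """Swapping the other-site direction converts the alternatives."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 9, 4)
            p_pos = fet_pvalue(make_tally(a, b, c, d), "positive")
            p_neg_swapped = fet_pvalue(make_tally(b, a, d, c), "negative")
            assert p_pos == pytest.approx(p_neg_swapped, abs=1e-12)

    def test_concordant_evidence_monotone(self):
        """Adding a concordant dataset never increases the positive p."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 7, 4)
            base = fet_pvalue(make_tally(a, b, c, d), "positive")
            assert fet_pvalue(make_tally(a + 1, b, c, d), "positive") <= base + 1e-12
            assert fet_pvalue(make_tally(a, b, c, d + 1), "positive") <= base + 1e-12

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            fet_pvalue(make_tally(1, 1, 1, 1), "sideways")


class TestHighConfidence:
    def mk(self, p, ratio, pmids, codes):
        t = make_tally(5, 1, 1, 5, anchor_diff_total=20)
        return CoregResult(tally=t, direction="positive", support=10, ratio=ratio,
                           fet_p=p, n_pmids=pmids, n_codes=codes, passes=False, flags={})

    def test_all_four_criteria_at_boundaries(self):
        ok, flags = high_confidence(self.mk(0.01, 0.12, 3, 3))
        assert ok and all(flags.values())

    def test_single_criterion_failure_flagged(self):
        ok, flags = high_confidence(self.mk(0.01, 0.09, 5, 5))
        assert not ok
        assert flags == {"fet": True, "ratio": False, "pmids": True, "codes": True}

    def test_strict_p_inclusive_ratio(self):
        ok, _ = high_confidence(self.mk(0.04999, 0.10, 3, 3))
        assert ok
        ok, flags = high_confidence(self.mk(0.05, 0.10, 3, 3))
        assert not ok and not flags["fet"]


class TestScreen:
    def test_planted_positive_set_recovered(self, anchor):
        c, truth = generate(SyntheticParams(seed=42))
        res = coregulation_screen(c, anchor)
        found = {s.label for s in passing_sites(res, "positive")}
        planted = {s.label for s in truth.pos_coupled}
        recall = len(found & planted) / len(planted)
        precision = len(found & planted) / len(found)
        assert recall >= 0.8
        assert precision >= 0.75  # FET null leakage over 270 background sites

    def test_site_passes_one_direction_at_most(self):
        c, _ = generate(SyntheticParams(seed=8))
        res = coregulation_screen(c, SiteID("TNIK", 640, "S"))
        passes = {}
        for r in res:
            if r.passes:
                assert passes.setdefault(r.other.label, r.direction) == r.direction

    def test_deterministic_and_order_invariant(self, anchor):
        c, _ = generate(SyntheticParams(seed=9, n_background=30))
        df1 = screen_to_frame(coregulation_screen(c, anchor))
        # permute observation rows and dataset order
        c.observations = c.observations.sample(frac=1.0, random_state=0).reset_index(drop=True)
        c.datasets = c.datasets.iloc[::-1]
        df2 = screen_to_frame(coregulation_screen(c, anchor))
        assert df1.to_csv() == df2.to_csv()

    def test_anchor_only_compendium_empty(self):
        c, _ = generate(SyntheticParams(seed=1, n_pos_coupled=0, n_neg_coupled=0, n_background=0))
        assert coregulation_screen(c, SiteID("TNIK", 640, "S")) == []

    def test_screen_tallies_match_tally_pair(self, anchor):
        """The vectorised screen reproduces the reference per-pair tally."""
        c, truth = generate(SyntheticParams(seed=13, n_background=10, n_pos_coupled=3, n_neg_coupled=3))
        res = coregulation_screen(c, anchor)
        by_site = {r.other.label: r.tally for r in res}
        for site in sorted(truth.pos_coupled | truth.background, key=lambda s: s.label)[:8]:
            t_ref = tally_pair(c, anchor, site)
            if site.label not in by_site:
                assert t_ref.n_codifferential == 0
                continue
            t = by_site[site.label]
            assert (t.nUU, t.nUD, t.nDU, t.nDD) == (t_ref.nUU, t_ref.nUD, t_ref.nDU, t_ref.nDD)
            assert t.pmids_concordant == t_ref.pmids_concordant
            assert t.codes_discordant == t_ref.codes_discordant

    def test_ratio_denominator_switch(self, anchor):
        c, _ = generate(SyntheticParams(seed=4, n_background=5, n_pos_coupled=2, n_neg_coupled=0))
        res_anchor = coregulation_screen(c, anchor, ratio_denominator="anchor")
        res_comp = coregulation_screen(c, anchor, ratio_denominator="compendium")
        n_anchor_diff = res_anchor[0].tally.anchor_diff_total
        for ra, rc in zip(res_anchor, res_comp):
            assert ra.ratio * n_anchor_diff == pytest.approx(rc.ratio * 40)

    def test_fdr_column_optional_extension(self, anchor):
        c, _ = generate(SyntheticParams(seed=4, n_background=5))
        res = coregulation_screen(c, anchor)
        assert "fet_q" not in screen_to_frame(res).columns
        df = screen_to_frame(res, fdr=True)
        assert (df["fet_q"] >= df["fet_p"] - 1e-12).all()
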