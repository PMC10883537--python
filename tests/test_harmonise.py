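"""Instrument selection, clumping, proxy search, and allele alignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as hst

import smoketrace as st
from smoketrace.errors import InsufficientInstrumentsError, LookupMissError
from smoketrace.harmonise import LdReference

from conftest import make_record, make_stats


class TestSelectInstruments:
    def test_nothing_significant_gives_valid_empty_set(self):
        stats = make_stats([make_record(f"rs{i}", 0.01, 0.1, pvalue=0.5, pos=i) for i in range(5)])
        inst = st.select_instruments(stats)
        assert len(inst) == 0
        assert all(status == "dropped" for _, status, _ in inst.selection_log)

    def test_ordering_and_log_conservation(self):
        stats = make_stats(
            [
                make_record("rsA", 0.3, 0.03, pvalue=1e-9, pos=1),
                make_record("rsB", 0.3, 0.03, pvalue=1e-30, pos=2),
                make_record("rsC", 0.3, 0.03, pvalue=0.2, pos=3),
            ]
        )
        inst = st.select_instruments(stats)
        assert inst.variants == ["rsB", "rsA"]  # ascending p
        assert len(inst.selection_log) == 3

    def test_default_panels_reach_the_published_instrument_counts(self, study_exposure_gwas):
        """At the study's sample sizes every panel variant is genome-wide significant:
        55 smoking-heaviness instruments and 7 NMR instruments."""
        assert len(study_exposure_gwas["cpd_inst"]) == 55
        assert len(study_exposure_gwas["nmr_inst"]) == 7


def _panel(entries):
    """entries: (rsid, chrom, pos); all pairwise r2 default 0."""
    ref = LdReference()
    for rsid, chrom, pos in entries:
        ref.add(rsid, rsid, 1.0)
        ref.positions[rsid] = (chrom, pos)
    return ref


class TestClump:
    def test_unlinked_panel_unchanged(self):
        inst = st.InstrumentSet("x", ["rs1", "rs2", "rs3"], {"rs1": 1e-10, "rs2": 1e-9, "rs3": 1e-8})
        ref = _panel([("rs1", "1", 100), ("rs2", "1", 200), ("rs3", "2", 100)])
        assert st.clump(inst, ref).variants == ["rs1", "rs2", "rs3"]

    def test_dominant_variant_absorbs_linked_partner(self):
        inst = st.InstrumentSet("x", ["rs1", "rs2"], {"rs1": 1e-10, "rs2": 1e-9})
        ref = _panel([("rs1", "1", 100), ("rs2", "1", 200)])
        ref.add("rs1", "rs2", 1.0)
        out = st.clump(inst, ref)
        assert out.variants == ["rs1"]

    def test_missing_variant_raises_named_lookup_error(self):
        inst = st.InstrumentSet("x", ["rsX"], {"rsX": 1e-10})
        with pytest.raises(LookupMissError, match="rsX"):
            st.clump(inst, _panel([("rs1", "1", 100)]))

    @given(hst.integers(0, 10_000))
    def test_output_satisfies_exhaustive_pairwise_oracle(self, seed):
        """Randomised panels: the greedy result must (a) contain no kept pair that
        violates the window+r2 constraint and (b) drop a variant only when a
        better-ranked kept variant conflicts with it — checked by enumeration."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 10))
        rsids = [f"rs{i}" for i in range(m)]
        pos = rng.integers(0, 3_000_000, m)
        pvals = 10.0 ** rng.uniform(-30, -8, m)
        ref = _panel([(r, "1", int(p)) for r, p in zip(rsids, pos)])
        r2 = {}
        for a, b in itertools.combinations(range(m), 2):
            val = float(rng.choice([0.0, 0.3, 0.9]))
            ref.add(rsids[a], rsids[b], val)
            r2[(a, b)] = r2[(b, a)] = val
        window, r2max = 1000.0, 0.2
        inst = st.InstrumentSet("x", rsids, dict(zip(rsids, pvals)))
        kept = st.clump(inst, ref, window_kb=window, r2_max=r2max).variants
        kept_idx = [rsids.index(r) for r in kept]

        def conflicts(i, j):
            return abs(pos[i] - pos[j]) / 1000 <= window and r2.get((i, j), 0.0) >= r2max

        for i, j in itertools.combinations(kept_idx, 2):
            assert not conflicts(i, j)
        order = sorted(range(m), key=lambda i: (pvals[i], rsids[i]))
        for i in set(range(m)) - set(kept_idx):
            better = [j for j in kept_idx if order.index(j) < order.index(i)]
            assert any(conflicts(i, j) for j in better)

    def test_result_independent_of_input_record_order(self):
        rng = np.random.default_rng(3)
        rsids = [f"rs{i}" for i in range(8)]
        pvals = dict(zip(rsids, 10.0 ** rng.uniform(-20, -8, 8)))
        ref = _panel([(r, "1", i * 100) for i, r in enumerate(rsids)])
        for a, b in itertools.combinations(rsids, 2):
            ref.add(a, b, float(rng.choice([0.0, 0.5])))
        base = st.clump(st.InstrumentSet("x", rsids, pvals), ref).variants
        shuffled = list(rsids)
        rng.shuffle(shuffled)
        assert st.clump(st.InstrumentSet("x", shuffled, pvals), ref).variants == base


class TestFindProxy:
    def _target(self, rsids):
        return make_stats([make_record(r, 0.1, 0.02, pos=i) for i, r in enumerate(rsids, 1)])

    def test_no_candidate_above_threshold_returns_none(self):
        ref = _panel([("rsQ", "1", 100), ("rs1", "1", 200)])
        ref.add("rsQ", "rs1", 0.5)
        assert st.find_proxy("rsQ", self._target(["rs1"]), ref, r2_min=0.8) is None

    def test_single_qualifying_candidate_found(self):
        ref = _panel([("rsQ", "1", 100), ("rs1", "1", 200)])
        ref.add("rsQ", "rs1", 0.9)
        assert st.find_proxy("rsQ", self._target(["rs1"]), ref) == "rs1"

    def test_tie_breaking_matches_enumeration_oracle(self):
        """Max r2 first, then smallest bp distance, then lexicographic rsid."""
        entries = [("rsQ", "1", 1000), ("rsA", "1", 3000), ("rsB", "1", 1500),
                   ("rsC", "1", 500), ("rsD", "1", 2000)]
        ref = _panel(entries)
        r2s = {"rsA": 0.95, "rsB": 0.9, "rsC": 0.9, "rsD": 0.85}
        for r, v in r2s.items():
            ref.add("rsQ", r, v)
        target = self._target(list(r2s))
        # brute-force oracle over all candidates
        pos = dict((r, p) for r, _, p in entries)
        best = min(r2s, key=lambda r: (-r2s[r], abs(pos[r] - pos["rsQ"]), r))
        assert st.find_proxy("rsQ", target, ref) == best
        # equal r2, equal distance -> lexicographic
        ref2 = _panel([("rsQ", "1", 1000), ("rsB", "1", 1500), ("rsA", "1", 500)])
        ref2.add("rsQ", "rsA", 0.9)
        ref2.add("rsQ", "rsB", 0.9)
        assert st.find_proxy("rsQ", self._target(["rsA", "rsB"]), ref2) == "rsA"

    def test_query_absent_from_reference_raises(self):
        with pytest.raises(LookupMissError):
            st.find_proxy("rsMissing", self._target(["rs1"]), _panel([("rs1", "1", 1)]))


def _pair(rsid, ea, oa, beta, eaf, *, trait, pos=100, se=0.02):
    return make_record(rsid, beta, se, ea=ea, oa=oa, eaf=eaf, pos=pos), trait


def _stats_for(records, trait):
    return make_stats(records, trait=trait)


class TestHarmonise:
    def _run(self, exp_rec, out_rec, band=(0.30, 0.70)):
        pads_exp = [make_record(f"rsPAD{i}", 0.5, 0.05, pos=990 + i, pvalue=1e-20)
                    for i in range(2)]
        pads_out = [make_record(f"rsPAD{i}", 0.2, 0.05, pos=990 + i) for i in range(2)]
        exp = make_stats([exp_rec, *pads_exp], trait="exp")
        out = make_stats([out_rec, *pads_out], trait="out")
        inst = st.InstrumentSet(
            "exp",
            [exp_rec.rsid, "rsPAD0", "rsPAD1"],
            {exp_rec.rsid: 1e-10, "rsPAD0": 1e-20, "rsPAD1": 1e-20},
        )
        return st.harmonise([exp], out, inst, palindromic_eaf_window=band)

    def test_aligned_variant_passes_unchanged(self):
        H = self._run(make_record("rs1", 0.4, 0.04, pvalue=1e-12),
                      make_record("rs1", 0.3, 0.05))
        i = H.rsids.index("rs1")
        assert H.outcome_beta[i] == pytest.approx(0.3)
        assert H.exposure_beta[i, 0] == pytest.approx(0.4)

    def test_swapped_outcome_alleles_flip_the_sign(self):
        H = self._run(make_record("rs1", 0.4, 0.04, ea="A", oa="G", pvalue=1e-12),
                      make_record("rs1", 0.3, 0.05, ea="G", oa="A", eaf=0.7))
        assert H.outcome_beta[H.rsids.index("rs1")] == pytest.approx(-0.3)

    def test_strand_flip_resolved_by_complementing(self):
        H = self._run(make_record("rs1", 0.4, 0.04, ea="A", oa="G", pvalue=1e-12),
                      make_record("rs1", 0.3, 0.05, ea="T", oa="C"))
        assert H.outcome_beta[H.rsids.index("rs1")] == pytest.approx(0.3)

    def test_palindromic_rule_table(self):
        """Enumerated oracle over eaf configurations for an A/T variant:
        keep only when both frequencies sit outside the band on the same side."""
        cases = [
            (0.10, 0.12, True, 0.3),    # both low -> kept as-is
            (0.90, 0.88, True, 0.3),    # both high -> kept
            (0.10, 0.88, False, None),  # opposite sides -> dropped
            (0.10, 0.50, False, None),  # outcome inside band -> dropped
            (0.45, 0.45, False, None),  # both inside band -> dropped
            (0.10, None, False, None),  # missing eaf -> dropped
        ]
        for exp_eaf, out_eaf, kept, expect_beta in cases:
            H = self._run(
                make_record("rs1", 0.4, 0.04, ea="A", oa="T", eaf=exp_eaf, pvalue=1e-12),
                make_record("rs1", 0.3, 0.05, ea="A", oa="T", eaf=out_eaf),
            )
            assert ("rs1" in H.rsids) == kept, (exp_eaf, out_eaf)
            if kept:
                assert H.outcome_beta[H.rsids.index("rs1")] == pytest.approx(expect_beta)

    def test_incompatible_alleles_dropped_with_reason(self):
        H = self._run(make_record("rs1", 0.4, 0.04, ea="A", oa="G", pvalue=1e-12),
                      make_record("rs1", 0.3, 0.05, ea="A", oa="C"))
        assert "rs1" not in H.rsids
        assert any("rs1" == r and "unresolvable" in why for r, why in H.exclusion_log)

    def test_conservation_and_involution(self):
        rng = np.random.default_rng(5)
        pairs = [("A", "G"), ("C", "T"), ("A", "T"), ("G", "C"), ("A", "C")]
        exp_recs, out_recs = [], []
        for i, (ea, oa) in enumerate(pairs):
            eaf = float(rng.uniform(0.05, 0.25))
            exp_recs.append(make_record(f"rs{i}", 0.3, 0.03, ea=ea, oa=oa, eaf=eaf,
                                        pos=i + 1, pvalue=1e-12))
            out_recs.append(make_record(f"rs{i}", float(rng.normal(0, 0.1)), 0.05,
                                        ea=ea, oa=oa, eaf=eaf, pos=i + 1))
        exp = make_stats(exp_recs, trait="exp")
        out = make_stats(out_recs, trait="out")
        inst = st.InstrumentSet("exp", [r.rsid for r in exp_recs],
                                {r.rsid: 1e-12 for r in exp_recs})
        H = st.harmonise([exp], out, inst)
        assert len(H.rsids) + len(H.exclusion_log) == len(inst)
        # involution: re-harmonising the aligned output changes nothing
        aligned_out = make_stats(
            [make_record(r, float(H.outcome_beta[i]), float(H.outcome_se[i]),
                         ea=exp[r].effect_allele, oa=exp[r].other_allele,
                         eaf=exp[r].eaf, pos=i + 1)
             for i, r in enumerate(H.rsids)],
            trait="out",
        )
        inst2 = st.InstrumentSet("exp", H.rsids, {r: 1e-12 for r in H.rsids})
        H2 = st.harmonise([exp], aligned_out, inst2)
        np.testing.assert_allclose(H2.outcome_beta, H.outcome_beta)
        np.testing.assert_allclose(H2.exposure_beta, H.exposure_beta)

    @given(hst.integers(0, 1_000))
    def test_outcome_magnitudes_invariant_under_frame_changes(self, seed):
        """Randomly re-reporting outcome records on the opposite allele frame
        must leave the multiset of |outcome beta| unchanged."""
        rng = np.random.default_rng(seed)
        n = 6
        exp_recs, out_recs = [], []
        for i in range(n):
            beta_out = float(rng.normal(0, 0.2))
            exp_recs.append(make_record(f"rs{i}", 0.3, 0.03, ea="A", oa="G", eaf=0.2,
                                        pos=i + 1, pvalue=1e-12))
            if rng.random() < 0.5:
                out_recs.append(make_record(f"rs{i}", -beta_out, 0.05, ea="G", oa="A",
                                            eaf=0.8, pos=i + 1))
            else:
                out_recs.append(make_record(f"rs{i}", beta_out, 0.05, ea="A", oa="G",
                                            eaf=0.2, pos=i + 1))
        inst = st.InstrumentSet("exp", [f"rs{i}" for i in range(n)],
                                {f"rs{i}": 1e-12 for i in range(n)})
        H = st.harmonise([make_stats(exp_recs, trait="exp")],
                         make_stats(out_recs, trait="out"), inst)
        base = sorted(round(abs(b), 12) for b in H.outcome_beta)
        ref = sorted(round(abs(r.beta), 12) for r in out_recs)
        assert base == ref

    def test_too_few_survivors_raise(self):
        exp = make_stats([make_record("rs1", 0.4, 0.04, pvalue=1e-12)], trait="exp")
        out = make_stats([make_record("rs2", 0.3, 0.05, pos=2)], trait="out")
        inst = st.InstrumentSet("exp", ["rs1"], {"rs1": 1e-12})
        with pytest.raises(InsufficientInstrumentsError):
            st.harmonise([exp], out, inst)
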