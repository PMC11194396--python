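"""Instrument selection: variance explained, strength, LD clumping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drugtarget_mr.instruments import (
    Instrument,
    LDMatrix,
    SelectionConfig,
    compute_f,
    compute_pve,
    greedy_clump,
    select_instruments,
)
from drugtarget_mr.sumstats import GeneRegion, SumstatsTable

from conftest import make_assoc

GENE = GeneRegion("ENSG1", "G1", "1", tss=1_000_000)


class TestPVE:
    def test_zero_effect(self):
        assert compute_pve(make_assoc(beta=0.0)) == 0.0

    def test_hand_evaluation(self):
        # 0.01 / (0.01 + 100 * 0.0001) = 0.5
        assert compute_pve(make_assoc(beta=0.1, se=0.01, n=100)) == pytest.approx(0.5)

    def test_frequency_factor_cancels(self):
        """The allele-frequency-weighted form equals the simplified one."""
        for eaf in (0.2, 0.4):
            a = make_assoc(beta=0.1, se=0.01, n=100, eaf=eaf)
            g = 2 * eaf * (1 - eaf)
            unsimplified = (g * a.beta**2) / (g * a.beta**2 + g * a.n * a.se**2)
            assert compute_pve(a) == pytest.approx(unsimplified, rel=1e-12)
        assert compute_pve(make_assoc(eaf=0.2)) == compute_pve(make_assoc(eaf=0.4))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_pve(make_assoc(n=-1))


class TestF:
    @pytest.mark.parametrize(
        "pve, n, expected",
        [(0.0, 100, 0.0), (0.5, 102, 100.0), (0.01, 1002, 10.10101010101)],
    )
    def test_examples(self, pve, n, expected):
        assert compute_f(pve, n) == pytest.approx(expected, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_f(1.0, 100)
        with pytest.raises(ValueError):
            compute_f(0.5, 2)

    @given(
        pve=st.floats(1e-6, 0.99),
        dpve=st.floats(1e-6, 0.005),
        n=st.floats(10, 1e6),
        dn=st.floats(1, 1e5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_pve_and_n(self, pve, dpve, n, dn):
        if pve + dpve < 1:
            assert compute_f(pve + dpve, n) > compute_f(pve, n)
        assert compute_f(pve, n + dn) > compute_f(pve, n)

    def test_instrument_invariant(self):
        inst = Instrument.from_association(make_assoc(), GENE)
        assert inst.f_stat == pytest.approx(
            inst.pve * (inst.assoc.n - 2) / (1 - inst.pve), rel=1e-9
        )
        assert not inst.is_trans  # pos 1 Mb from tss boundary is inclusive


def _insts(specs):
    """specs: list of (vid, pos, pval)."""
    return [
        Instrument.from_association(
            make_assoc(variant_id=v, pos=p, pval=pv), GENE
        )
        for v, p, pv in specs
    ]


def _ld(vids, r2):
    return LDMatrix(vids, np.asarray(r2, float))


class TestGreedyClump:
    def test_correlated_pair_keeps_most_significant(self):
        insts = _insts([("a", 100, 1e-8), ("b", 200, 1e-10)])
        ld = _ld(["a", "b"], [[1, 0.5], [0.5, 1]])
        kept = greedy_clump(insts, ld)
        assert [i.variant_id for i in kept] == ["b"]

    def test_uncorrelated_pair_both_retained(self):
        insts = _insts([("a", 100, 1e-8), ("b", 200, 1e-10)])
        ld = _ld(["a", "b"], [[1, 0.0005], [0.0005, 1]])
        assert len(greedy_clump(insts, ld)) == 2

    def test_single_candidate_unchanged(self):
        insts = _insts([("a", 100, 1e-8)])
        ld = _ld(["a"], [[1.0]])
        assert greedy_clump(insts, ld) == insts

    def test_outside_window_not_clumped(self):
        insts = _insts([("a", 100, 1e-8), ("b", 100 + 11_000_000, 1e-10)])
        ld = _ld(["a", "b"], [[1, 0.9], [0.9, 1]])
        assert len(greedy_clump(insts, ld, window_kb=10_000)) == 2

    def test_missing_candidate_fatal(self):
        insts = _insts([("a", 100, 1e-8)])
        ld = _ld(["b"], [[1.0]])
        with pytest.raises(KeyError):
            greedy_clump(insts, ld)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """Greedy retention equals the p-value-priority enumeration on
        random regions of up to 12 variants."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 13))
        pos = np.sort(rng.integers(0, 20_000_000, size=m))
        pvals = 10.0 ** (-rng.uniform(2, 30, size=m))
        corr = rng.uniform(0, 1, size=(m, m))
        r2 = (corr + corr.T) / 2
        np.fill_diagonal(r2, 1.0)
        vids = [f"v{i}" for i in range(m)]
        insts = _insts(list(zip(vids, pos.tolist(), pvals.tolist())))
        ld = _ld(vids, r2)

        # oracle: walk candidates in (pval, pos, id) order, retain unless in
        # conflict with an already retained variant -- full O(n^2) scan
        order = sorted(insts, key=lambda i: (i.assoc.pval, i.assoc.pos, i.variant_id))
        retained = []
        for cand in order:
            clash = any(
                abs(cand.assoc.pos - kept.assoc.pos) <= 10_000 * 1000
                and ld.get(cand.variant_id, kept.variant_id) >= 0.001
                for kept in retained
            )
            if not clash:
                retained.append(cand)

        got = greedy_clump(insts, ld, r2_max=0.001, window_kb=10_000)
        assert [i.variant_id for i in got] == [i.variant_id for i in retained]


class TestSelectInstruments:
    def _table(self, records):
        return SumstatsTable.from_records(records)

    def test_stage_filters(self):
        records = [
            make_assoc(variant_id="sig", pos=100, pval=1e-10),
            make_assoc(variant_id="notsig", pos=200, pval=1e-7),
            make_assoc(variant_id="rare", pos=300, eaf=0.995),
        ]
        ld = _ld(["sig", "notsig", "rare"], np.eye(3) * 0.999 + 0.001)
        iv = select_instruments(self._table(records), GENE, ld)
        assert iv.variant_ids == ["sig"]
        assert iv.selection_log["removed_significance"] == 1
        assert iv.selection_log["removed_maf"] == 1  # min(0.995, 0.005) < 0.01

    def test_weak_instrument_removed(self):
        # z ~ 5.6 passes 5e-8; F ~ z²(n−2)/n, so only a minuscule n gives F < 10
        weak = make_assoc(variant_id="w", beta=0.56, se=0.1, n=2.5, pval=2e-8)
        ld = _ld(["w"], [[1.0]])
        iv = select_instruments(self._table([weak]), GENE, ld)
        assert len(iv) == 0 and iv.selection_log["removed_weak"] == 1

    def test_empty_table_empty_log(self):
        iv = select_instruments(self._table([]), GENE, _ld([], np.empty((0, 0))))
        assert len(iv) == 0
        assert all(v == 0 for v in iv.selection_log.values())

    def test_significance_and_maf_filters_commute(self):
        records = [
            make_assoc(variant_id=f"v{i}", pos=100 + i, pval=p, eaf=e)
            for i, (p, e) in enumerate(
                itertools.product([1e-10, 1e-6], [0.3, 0.005, 0.996])
            )
        ]
        cfg = SelectionConfig()
        one = [r for r in records if r.pval < cfg.p_max]
        one = {r.variant_id for r in one if r.maf > cfg.maf_min}
        two = [r for r in records if r.maf > cfg.maf_min]
        two = {r.variant_id for r in two if r.pval < cfg.p_max}
        assert one == two

    def test_trans_flagging(self):
        far = make_assoc(variant_id="t", pos=GENE.tss + 2_000_000, pval=1e-12)
        ld = _ld(["t"], [[1.0]])
        iv = select_instruments(self._table([far]), GENE, ld)
        assert len(iv) == 1 and iv.any_trans


class TestLDMatrix:
    def test_round_trip(self, tmp_path):
        ld = _ld(["a", "b"], [[1, 0.25], [0.25, 1]])
        p = tmp_path / "ld.tsv"
        ld.write_tsv(p)
        again = LDMatrix.read_tsv(p)
        assert again.variant_ids == ld.variant_ids
        np.testing.assert_allclose(again.r2, ld.r2)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            _ld(["a", "b"], [[1, 0.5], [0.4, 1]])  # asymmetric
        with pytest.raises(ValueError):
            _ld(["a", "b"], [[0.9, 0.5], [0.5, 1]])  # diagonal != 1
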