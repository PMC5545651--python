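"""CNVR aggregation, stratification, reference confirmation, gene annotation."""

import numpy as np
import pytest

from cnvassoc.regions import (
    annotate_genes,
    build_cnvrs,
    classify_call_size,
    compute_frequencies,
    dgv_confirm,
    stratify_cnvrs,
)
from cnvassoc.types import (
    Ancestry,
    CNVCall,
    CNVRegion,
    Diagnosis,
    FreqClass,
    Region,
    RegionSet,
    SampleRecord,
    SizeClass,
)


def _call(sid="S1", chrom="1", start=100, end=1999, cn=1, markers=5):
    return CNVCall(sid, chrom, start, end, cn, markers)


def _samples(n, dx=Diagnosis.HC, prefix="s"):
    return [SampleRecord(f"{prefix}{i}", dx, Ancestry.EA, "b1", 0.1) for i in range(n)]


def _region(chrom="1", start=100, end=199, members=None):
    members = members or [_call(start=start, end=end)]
    return CNVRegion("r1", chrom, start, end, member_calls=members)


def _oracle_components(calls):
    """Connected components of the >=1 bp overlap graph via scipy csgraph."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(calls)
    starts = np.array([c.start for c in calls])
    ends = np.array([c.end for c in calls])
    chroms = np.array([int(c.chrom) for c in calls])
    adj = (
        (chroms[:, None] == chroms[None, :])
        & (starts[:, None] <= ends[None, :])
        & (ends[:, None] >= starts[None, :])
    )
    _, labels = connected_components(csr_matrix(adj), directed=False)
    comps = {}
    for i, lab in enumerate(labels):
        comps.setdefault(lab, set()).add(i)
    return {frozenset(c) for c in comps.values()}


def _component_sets(cnvrs, index):
    return {frozenset(index[id(c)] for c in r.member_calls) for r in cnvrs}


class TestSizeClassification:
    @pytest.mark.parametrize(
        "length,expected",
        [(500_000, SizeClass.LARGE), (499_999, SizeClass.SMALL), (1, SizeClass.SMALL)],
    )
    def test_half_megabase_threshold(self, length, expected):
        assert classify_call_size(_call(start=1, end=length)) is expected

    def test_agrees_with_direct_comparison_on_random_lengths(self):
        rng = np.random.default_rng(0)
        for length in rng.integers(1, 2_000_000, size=1000):
            c = _call(start=1, end=int(length))
            assert (classify_call_size(c) is SizeClass.LARGE) == (length >= 500_000)


class TestBuildCnvrs:
    def test_chain_merges_and_gap_splits(self):
        calls = [
            _call("a", "1", 100, 200),
            _call("b", "1", 150, 300),
            _call("c", "1", 301, 400),
        ]
        cnvrs = build_cnvrs(calls)
        spans = sorted((r.start, r.end) for r in cnvrs)
        assert spans == [(100, 300), (301, 400)]  # 300 and 301 do not overlap

    def test_single_call_is_its_own_region(self):
        (r,) = build_cnvrs([_call(start=5, end=50)])
        assert (r.start, r.end, r.carrier_count) == (5, 50, 1)

    def test_components_match_graph_oracle_under_permutation(self):
        rng = np.random.default_rng(1)
        calls = [
            _call(
                f"s{rng.integers(50)}", str(rng.integers(1, 4)),
                int(s := rng.integers(1, 10**6)), int(s + rng.integers(1000, 100_000)),
            )
            for _ in range(400)
        ]
        index = {id(c): i for i, c in enumerate(calls)}
        expected = _oracle_components(calls)
        for perm_seed in range(3):
            perm = np.random.default_rng(perm_seed).permutation(len(calls))
            got = _component_sets(build_cnvrs([calls[i] for i in perm]), index)
            assert got == expected

    def test_every_call_in_exactly_one_region(self):
        rng = np.random.default_rng(2)
        calls = [
            _call(f"s{i}", "2", int(s := rng.integers(1, 10**5)), int(s + 500))
            for i in range(100)
        ]
        cnvrs = build_cnvrs(calls)
        members = [id(c) for r in cnvrs for c in r.member_calls]
        assert sorted(members) == sorted(id(c) for c in calls)

    def test_adding_a_call_never_splits_components(self):
        rng = np.random.default_rng(3)
        calls = [
            _call(f"s{i}", "1", int(s := rng.integers(1, 10**5)), int(s + 2000))
            for i in range(60)
        ]
        index = {id(c): i for i, c in enumerate(calls)}
        before = _component_sets(build_cnvrs(calls), index)
        extra = _call("new", "1", 40_000, 70_000)
        index[id(extra)] = len(calls)
        after = _component_sets(build_cnvrs(calls + [extra]), index)
        for comp in before:
            assert any(comp <= new for new in after)


class TestFrequencies:
    def test_pooled_and_case_only_denominators(self):
        # 16 case carriers in a 2416-case / 2393-control pool
        cases = _samples(2416, Diagnosis.SZ, "sz")
        controls = _samples(2393, Diagnosis.HC, "hc")
        members = [_call(f"sz{i}", "22", 100, 199, cn=1) for i in range(16)]
        cnvr = _region("22", 100, 199, members)
        compute_frequencies(cnvr, cases + controls)
        assert cnvr.carrier_frequency == pytest.approx(16 / 4809, abs=1e-9)
        compute_frequencies(cnvr, cases + controls, lambda s: s.diagnosis is Diagnosis.SZ)
        assert cnvr.carrier_frequency == pytest.approx(0.00662, abs=5e-6)

    def test_hand_counts_on_ten_sample_fixture(self):
        samples = _samples(10)
        members = [
            _call("s0", cn=1), _call("s1", cn=0), _call("s2", cn=3),
            _call("s2", cn=1),  # s2 carries both a dup and a del
        ]
        cnvr = _region(members=members)
        compute_frequencies(cnvr, samples)
        assert cnvr.carrier_count == 3
        assert cnvr.carrier_frequency == pytest.approx(0.3)
        assert cnvr.del_frequency == pytest.approx(0.3)
        assert cnvr.dup_frequency == pytest.approx(0.1)

    def test_no_carriers_means_zero_everywhere(self):
        cnvr = _region(members=[_call("outsider")])
        compute_frequencies(cnvr, _samples(5))
        assert cnvr.carrier_frequency == 0.0
        assert cnvr.freq_class is FreqClass.RARE

    def test_empty_denominator_is_an_error(self):
        with pytest.raises(ValueError, match="denominator"):
            compute_frequencies(_region(), [])


class TestStratification:
    def _cnvr(self, length, freq, n_samples=1000):
        members = [
            _call(f"s{i}", "1", 1, length, cn=1)
            for i in range(max(1, round(freq * n_samples)))
        ]
        r = _region("1", 1, length, members)
        r.size_class = SizeClass.LARGE if length >= 500_000 else SizeClass.SMALL
        compute_frequencies(r, _samples(n_samples))
        return r

    def test_one_percent_frequency_gate_for_small_cnvrs(self):
        kept = self._cnvr(10_000, 0.01)
        dropped = self._cnvr(10_000, 0.009)
        strata = stratify_cnvrs([kept, dropped])
        assert kept in strata["small_common"]
        assert dropped in strata["dropped_small_rare"]

    def test_rare_large_cnvrs_are_kept(self):
        r = self._cnvr(600_000, 0.004)
        assert r in stratify_cnvrs([r])["large"]

    def test_singleton_flagged_untestable(self):
        r = self._cnvr(600_000, 0.001)
        assert r.carrier_count == 1 and r.singleton
        assert r in stratify_cnvrs([r])["large"]


class TestDgvConfirm:
    def test_full_containment_gives_ratio_one(self):
        cnvr = _region("1", 100, 199)
        confirmed, _ = dgv_confirm([cnvr], RegionSet([Region("1", 50, 500, "d")]))
        assert cnvr in confirmed and cnvr.dgv_overlap_ratio == pytest.approx(1.0)

    def test_half_overlap(self):
        cnvr = _region("1", 100, 199)
        dgv_confirm([cnvr], RegionSet([Region("1", 150, 249, "d")]))
        assert cnvr.dgv_overlap_ratio == pytest.approx(0.5)

    def test_no_overlap_excludes(self):
        cnvr = _region("1", 100, 199)
        confirmed, unconfirmed = dgv_confirm([cnvr], RegionSet([Region("2", 100, 199, "d")]))
        assert cnvr in unconfirmed and cnvr.dgv_confirmed is False

    def test_union_ratio_matches_bitmap_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            start = int(rng.integers(1, 5000))
            end = start + int(rng.integers(50, 3000))
            cnvr = _region("1", start, end)
            regions = []
            for j in range(rng.integers(1, 8)):
                s = int(rng.integers(1, 8000))
                regions.append(Region("1", s, s + int(rng.integers(10, 2000)), f"d{j}"))
            dgv_confirm([cnvr], RegionSet(regions))
            bitmap = np.zeros(end - start + 1, dtype=bool)
            for r in regions:
                lo, hi = max(start, r.start), min(end, r.end)
                if lo <= hi:
                    bitmap[lo - start : hi - start + 1] = True
            expected = bitmap.mean()
            assert cnvr.dgv_overlap_ratio == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= cnvr.dgv_overlap_ratio <= 1.0

    def test_empty_reference_set_is_an_error(self):
        with pytest.raises(ValueError):
            dgv_confirm([_region()], RegionSet([]))


class TestGeneAnnotation:
    def test_named_gene_attached(self):
        genes = RegionSet([Region("22", 150, 300, "COMT")])
        cnvr = _region("22", 100, 199)
        annotate_genes([cnvr], genes)
        assert cnvr.genes == ["COMT"]

    def test_gene_free_region_is_intergenic(self, tmp_path):
        from cnvassoc import io as cio

        cnvr = _region("22", 100, 199)
        annotate_genes([cnvr], RegionSet([Region("1", 100, 199, "FOO")]))
        assert cnvr.genes == []
        p = tmp_path / "r.tsv"
        cio.write_cnvr_report([cnvr], p)
        assert "Intergenic" in p.read_text()

    def test_matches_all_pairs_oracle_on_fifty_genes(self):
        rng = np.random.default_rng(5)
        genes = [
            Region("3", int(s := rng.integers(1, 10**6)), int(s + rng.integers(100, 50_000)), f"G{i}")
            for i in range(50)
        ]
        cnvr = _region("3", 400_000, 600_000)
        annotate_genes([cnvr], RegionSet(genes))
        expected = sorted(
            g.label for g in genes if g.start <= cnvr.end and g.end >= cnvr.start
        )
        assert sorted(cnvr.genes) == expected
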