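"""Filtering, duplicon chaining, coverage validation, inversion and
translocation detection."""

import copy

import numpy as np
import pytest

from lcr22map import haplotype_model as hm
from lcr22map import reconstruction as rec
from lcr22map import synthetic_data as sd
from lcr22map.alignment import LabelAlignment
from lcr22map.errors import ChainingGapError, ParseError

from oracles import recount_label_coverage

NOISELESS = sd.NoiseParams(fp_rate=0, fn_rate=0, sizing_cv=0)


def _a_chain(arch, homologs, molecules, **kw):
    inventory = hm.module_inventory(homologs, "LCR22A")
    rc = rec.region_candidates(arch, "LCR22A", inventory)
    return rec.chain_modules(molecules, arch, rc, **kw)


class TestFilterMolecules:
    def _mols(self, lengths):
        return [sd.Molecule(molecule_id=i + 1, length=float(ln),
                            labels=np.array([1000.0]),
                            qualities=np.array([0.9]))
                for i, ln in enumerate(lengths)]

    def test_length_cutoff_drops_short_molecule(self):
        mols = self._mols([140_000, 200_000, 160_000])
        kept = rec.filter_molecules(mols, 150_000)
        assert [m.molecule_id for m in kept] == [2, 3]

    def test_no_cutoff_is_identity_up_to_order(self):
        mols = self._mols([140_000, 200_000, 160_000])
        kept = rec.filter_molecules(mols, 0, None)
        assert sorted(m.molecule_id for m in kept) == [1, 2, 3]

    def test_total_target_keeps_longest_first(self):
        mols = self._mols([300_000, 250_000, 200_000, 180_000])
        kept = rec.filter_molecules(mols, 0, total_target=500_000)
        assert [m.molecule_id for m in kept] == [1, 2]

    def test_retained_total_bounded_by_target_plus_max_length(self):
        rng = np.random.default_rng(0)
        mols = self._mols(rng.uniform(150_000, 400_000, 60))
        target = 3_000_000
        kept = rec.filter_molecules(mols, 0, total_target=target)
        total = sum(m.length for m in kept)
        assert total <= target + max(m.length for m in mols)
        assert total >= min(target, sum(m.length for m in mols))

    def test_deterministic_tie_break_on_id(self):
        mols = self._mols([200_000, 200_000, 200_000])
        kept = rec.filter_molecules(mols, 0, total_target=380_000)
        assert [m.molecule_id for m in kept] == [1, 2]


class TestChainModules:
    def test_noiseless_der22_chain(self, arch, father):
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, father["der22"], 25, NOISELESS, seed=1),
            160_000)
        call = _a_chain(arch, father.values(), mols)
        assert call.copy_number == 3
        assert call.orientations == [hm.ORIENT_REF, hm.ORIENT_INV,
                                     hm.ORIENT_REF]
        assert call.assignments == ["DA1", "DA2", "DA3"]
        assert all(len(s) >= 1 for s in call.junction_support)

    def test_zero_copy_array_terminates_immediately(self, arch):
        d_mod = hm.make_module(arch, "d", hm.ORIENT_REF, (0,), (1,))
        hom = hm.build_intact_chr22(arch, "flat", [], [d_mod], False)
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, hom, 25, NOISELESS, seed=2), 160_000)
        inventory = [hm.make_module(arch, "c1", hm.ORIENT_REF, (0, 1), (2,))]
        rc = rec.region_candidates(arch, "LCR22A", inventory)
        call = rec.chain_modules(mols, arch, rc)
        assert call.copy_number == 0

    def test_observed_patterns_match_generating_modules(self, arch, father):
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, father["der22"], 30,
                                sd.NoiseParams(), seed=3), 160_000)
        call = _a_chain(arch, father.values(), mols)
        truth = father["der22"].array_block("LCR22A").modules
        for i, mod in enumerate(truth):
            assert call.pattern_tuple(i) == (mod.fingerprint5,
                                             mod.fingerprint3)

    def test_greedy_equals_exhaustive_on_small_arrays(self, arch):
        mods = [hm.make_module(arch, "u1", hm.ORIENT_REF, (0, 1, 3), (2, 4)),
                hm.make_module(arch, "u2", hm.ORIENT_INV, (1, 2, 5), (0, 3))]
        hom = hm.build_intact_chr22(
            arch, "two", mods,
            [hm.make_module(arch, "ud", hm.ORIENT_REF, (4,), (5,))], False)
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, hom, 20, NOISELESS, seed=4), 160_000)
        # restrict to the LCR22A neighbourhood to keep enumeration honest
        blk = hom.array_block("LCR22A")
        near = [m for m in mols
                if m.start < blk.end + 50_000 and m.end > blk.start - 50_000]
        inventory = mods + [hm.make_module(arch, "u3", hm.ORIENT_REF,
                                           (0, 4), (1, 5))]
        rc = rec.region_candidates(arch, "LCR22A", inventory)
        greedy = rec.chain_modules(near, arch, rc)
        exhaustive = rec.exhaustive_chain(near, arch, rc, max_copies=3)
        assert greedy.copy_number == exhaustive.copy_number == 2
        assert greedy.orientations == exhaustive.orientations
        assert greedy.assignments == exhaustive.assignments == ["u1", "u2"]

    def test_insufficient_molecules_raise_chaining_gap(self, arch, father):
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, father["der22"], 25, NOISELESS, seed=5),
            160_000)
        # keep only molecules that never reach the module array
        blk = father["der22"].array_block("LCR22A")
        gap = [m for m in mols if m.end < blk.start - 20_000
               or m.start > blk.end + 20_000]
        inventory = hm.module_inventory(father.values(), "LCR22A")
        rc = rec.region_candidates(arch, "LCR22A", inventory)
        with pytest.raises(ChainingGapError):
            rec.chain_modules(gap, arch, rc)

    def test_lcr22d_single_module_chains(self, arch, father):
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, father["der11"], 30,
                                sd.NoiseParams(), seed=6), 160_000)
        inventory = hm.module_inventory(father.values(), "LCR22D")
        rc = rec.region_candidates(arch, "LCR22D", inventory)
        call = rec.chain_modules(mols, arch, rc)
        assert call.copy_number == 1
        assert call.orientations == [hm.ORIENT_REF]
        assert call.assignments == ["FD2"]


class TestValidateCoverage:
    def _small_map_and_alignments(self, arch, coverage, seed):
        mod = hm.make_module(arch, "cov", hm.ORIENT_REF, (0, 3), (2, 5))
        hom = hm.build_intact_chr22(arch, "cov", [mod], [mod], False)
        pos = hm.synthesize_positions(arch, hom)
        # a window around the LCR22A array; the tracked set is the anchor and
        # duplicon-overlapping labels (window-edge labels are under-covered
        # by construction, like chromosome ends in real data)
        blk = hom.array_block("LCR22A")
        lo, hi = blk.start - 400_000, blk.end + 400_000
        window = pos[(pos >= lo) & (pos <= hi)]
        tracked = [j for j, p in enumerate(window)
                   if lo + 300_000 <= p <= hi - 300_000]
        mols = sd.simulate_molecules(window, (lo, hi), coverage,
                                     NOISELESS, seed=seed)
        als = [rec.align_molecule_fast(m, window) for m in mols]
        return window, als, tracked

    def test_saturating_coverage_passes(self, arch):
        window, als, tracked = self._small_map_and_alignments(arch, 100, 1)
        report = rec.validate_coverage(window, als, min_cov=5,
                                       tracked=tracked)
        assert report.passed and report.deficient == []

    def test_sub_threshold_coverage_fails_with_deficient_labels(self, arch):
        window, als, tracked = self._small_map_and_alignments(arch, 2, 2)
        report = rec.validate_coverage(window, als, min_cov=5,
                                       tracked=tracked)
        assert not report.passed
        assert len(report.deficient) > 0
        assert all(report.counts[j] < 5 for j in report.deficient)

    def test_counts_match_independent_recount(self, arch):
        window, als, _ = self._small_map_and_alignments(arch, 10, 3)
        report = rec.validate_coverage(window, als, min_cov=5)
        assert list(report.counts) == recount_label_coverage(len(window), als)

    def test_pass_is_monotone_in_added_molecules(self, arch):
        window, als, tracked = self._small_map_and_alignments(arch, 30, 4)
        passed_before = False
        for k in range(5, len(als), max(1, len(als) // 8)):
            report = rec.validate_coverage(window, als[:k], min_cov=5,
                                           tracked=tracked)
            if passed_before:
                assert report.passed
            passed_before = passed_before or report.passed
        assert rec.validate_coverage(window, als, min_cov=5,
                                     tracked=tracked).passed


class TestDetectInversion:
    def test_truth_map_states(self, arch, father, mother):
        expectations = [(father["chr22_intact"], "present"),
                        (father["der11"], "absent"),
                        (mother["chr22_h2"], "present"),
                        (mother["chr22_h1"], "absent")]
        for hom, expected in expectations:
            blk = hom.inversion_block()
            call = rec.detect_inversion(
                hm.synthesize_positions(arch, hom), (blk.start, blk.end), arch)
            assert call.status == expected

    def test_decisions_mutually_exclusive_on_template_and_mirror(self, arch):
        offs = np.asarray(arch.unique_labels("inv_seg"), dtype=float)
        lo = 1_000_000
        length = hm.INV_LEN - 1
        direct = lo + offs
        mirrored = lo + np.sort(length - offs)
        c_dir = rec.detect_inversion(direct, (lo, lo + length), arch)
        c_mir = rec.detect_inversion(mirrored, (lo, lo + length), arch)
        assert c_dir.status == "absent"
        assert c_mir.status == "present"

    def test_empty_window_is_no_call(self, arch):
        call = rec.detect_inversion(np.array([1.0]), (500_000, 585_000), arch)
        assert call.status == "no_call"

    def test_molecule_votes_recover_both_states(self, arch, father):
        for hom, expected in ((father["chr22_intact"], "present"),
                              (father["der11"], "absent")):
            blk = hom.inversion_block()
            v_dir = copy.deepcopy(hom)
            v_dir.inversion_block().orientation = hm.ORIENT_REF
            v_mir = copy.deepcopy(hom)
            v_mir.inversion_block().orientation = hm.ORIENT_INV
            md = hm.synthesize_positions(arch, v_dir)
            mm = hm.synthesize_positions(arch, v_mir)
            mols = rec.filter_molecules(
                sd.simulate_homolog(arch, hom, 40, sd.NoiseParams(), seed=8),
                150_000)
            near = [m for m in mols if m.start < blk.end + 20_000
                    and m.end > blk.start - 20_000]
            call = rec.detect_inversion_from_molecules(
                near, md, mm, (blk.start, blk.end))
            assert call.status == expected


@pytest.fixture(scope="module")
def ref_maps(arch):
    ref22, ref11 = hm.reference_homologs(arch)
    return (hm.synthesize_positions(arch, ref22),
            hm.synthesize_positions(arch, ref11))


class TestDetectTranslocation:
    def test_der22_breakpoints_overlap_printed_intervals(self, arch, father,
                                                         ref_maps):
        p22, p11 = ref_maps
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, father["der22"], 50,
                                sd.NoiseParams(), seed=24), 150_000)
        call = rec.detect_translocation(mols, p22, p11, min_support=3)
        assert call is not None
        c, d = call.chr22_interval, call.chr11_interval
        assert c[0] <= hm.JUNCTION_CHR22[1] and c[1] >= hm.JUNCTION_CHR22[0]
        assert d[0] <= hm.JUNCTION_CHR11[1] and d[1] >= hm.JUNCTION_CHR11[0]
        assert len(call.supporting_molecules) >= 3

    def test_intact_molecules_give_no_call(self, arch, father, ref_maps):
        p22, p11 = ref_maps
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, father["chr22_intact"], 15,
                                sd.NoiseParams(), seed=25), 150_000)
        assert rec.detect_translocation(mols, p22, p11, min_support=3) is None

    def test_interval_shrinks_as_support_grows(self, arch, father, ref_maps):
        # noiseless molecules: every split call carries the exact interval,
        # so adding supporters can only intersect it down (weakly)
        p22, p11 = ref_maps
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, father["der22"], 40, NOISELESS,
                                seed=26), 150_000)
        prev_width = None
        for frac in (0.4, 0.7, 1.0):
            subset = mols[:int(len(mols) * frac)]
            call = rec.detect_translocation(subset, p22, p11, min_support=2)
            if call is None:
                continue
            width = call.chr22_interval[1] - call.chr22_interval[0]
            if prev_width is not None:
                assert width <= prev_width + 1e-9
            prev_width = width
        assert prev_width is not None


class TestXmapIO:
    def test_round_trip(self, tmp_path):
        als = [LabelAlignment(1, "chr22", "+", [(0, 3), (1, 4)], 2.5),
               LabelAlignment(2, "chr11", "-", [(2, 7)], 0.75),
               LabelAlignment(3, "chr22", "+", [], 0.0)]
        path = tmp_path / "out.xmap"
        rec.write_xmap(als, path)
        back = rec.read_xmap(path)
        assert [(a.molecule_id, a.map_id, a.orientation, a.pairs)
                for a in back] == \
            [(a.molecule_id, a.map_id, a.orientation, a.pairs) for a in als]

    def test_malformed_row_raises(self, tmp_path):
        path = tmp_path / "bad.xmap"
        path.write_text("1\tchr22\t+\n")
        with pytest.raises(ParseError):
            rec.read_xmap(path)
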