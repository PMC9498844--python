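"""STRP parent-of-origin, fingerprint breakpoint localization, and the
quadrivalent consistency check."""

import copy
from itertools import combinations_with_replacement

import numpy as np
import pytest

from lcr22map import haplotype_model as hm
from lcr22map import nahr_inference as ni
from lcr22map import reconstruction as rec
from lcr22map import synthetic_data as sd
from lcr22map.errors import (DataConsistencyError, InconsistentMarkersError,
                             InsufficientMarkersError,
                             IrreconcilableDonorsError,
                             ModelInconsistencyError)

from oracles import classify_trio_marker


def _table(genotypes):
    """Hand-built StrpTable from {marker: (proband, mother, father)}."""
    g = {}
    for marker, (p, m, f) in genotypes.items():
        g[(marker, "proband")] = p
        g[(marker, "mother")] = m
        g[(marker, "father")] = f
    return sd.StrpTable(markers=list(genotypes),
                        individuals=["father", "mother", "proband"],
                        genotypes=g)


class TestClassifyMarker:
    def test_allele_only_in_mother_names_father_deleted(self):
        call = ni.classify_marker((150,), (150, 154), (158, 162))
        assert call.status == ni.INFORMATIVE_FATHER_DELETED

    def test_allele_in_both_parents_is_uninformative(self):
        call = ni.classify_marker((150,), (150, 154), (150, 162))
        assert call.status == ni.UNINFORMATIVE

    def test_allele_only_in_father_names_mother_deleted(self):
        call = ni.classify_marker((162,), (150, 154), (158, 162))
        assert call.status == ni.INFORMATIVE_MOTHER_DELETED

    def test_allele_in_neither_parent_flagged_uninformative(self):
        call = ni.classify_marker((170,), (150, 154), (158, 162))
        assert call.status == ni.UNINFORMATIVE and call.flagged

    def test_two_distinct_proband_alleles_rejected(self):
        with pytest.raises(DataConsistencyError):
            ni.classify_marker((150, 154), (150, 154), (158, 162))

    def test_truth_table_equivalence_over_six_allele_pool(self):
        pool = [100, 104, 108, 112, 116, 120]
        for mother in combinations_with_replacement(pool, 2):
            for father in combinations_with_replacement(pool, 2):
                for a in pool:
                    call = ni.classify_marker((a,), mother, father)
                    assert call.status == classify_trio_marker(a, mother,
                                                               father)


class TestAssignParentOfOrigin:
    def test_simulated_father_deleted_trio(self, catalog):
        table = sd.simulate_strp_trio(catalog, "father", seed=3)
        origin = ni.assign_parent_of_origin(table)
        assert origin.parent == "father"
        assert origin.informative_count >= 3

    def test_simulated_mother_deleted_trio(self, catalog):
        table = sd.simulate_strp_trio(catalog, "mother", seed=4)
        assert ni.assign_parent_of_origin(table).parent == "mother"

    def test_two_informative_markers_insufficient(self):
        table = _table({
            "M1": ((150,), (150, 154), (158, 162)),
            "M2": ((150,), (150, 154), (158, 162)),
            "M3": ((150,), (150, 154), (150, 162)),
        })
        with pytest.raises(InsufficientMarkersError):
            ni.assign_parent_of_origin(table)

    def test_all_uninformative_insufficient(self):
        table = _table({f"M{i}": ((150,), (150, 154), (150, 162))
                        for i in range(1, 9)})
        with pytest.raises(InsufficientMarkersError):
            ni.assign_parent_of_origin(table)

    def test_conflicting_informative_markers_rejected(self):
        table = _table({
            "M1": ((150,), (150, 154), (158, 162)),   # father deleted
            "M2": ((162,), (150, 154), (158, 162)),   # mother deleted
            "M3": ((150,), (150, 154), (158, 162)),
            "M4": ((150,), (150, 154), (158, 162)),
        })
        with pytest.raises(InconsistentMarkersError):
            ni.assign_parent_of_origin(table)


@pytest.fixture(scope="module")
def father_candidates(catalog):
    homs = catalog.individuals["father"]
    a = {n: h for n, h in homs.items() if h.array_block("LCR22A")}
    d = {n: h for n, h in homs.items() if h.array_block("LCR22D")}
    return a, d


class TestLocalizeNahr:
    def test_donors_identified_on_fixture(self, catalog, arch,
                                          father_candidates):
        a_c, d_c = father_candidates
        part = ni.localize_nahr(catalog.individuals["proband"]["del_hap"],
                                a_c, d_c, arch)
        assert part.donor_a == ("der22", 3)
        assert part.donor_d == ("chr22_intact", 1)
        assert part.status == "ok"

    def test_proband_carries_four_labels_at_3prime_locus(self, catalog, arch,
                                                         father_candidates):
        a_c, d_c = father_candidates
        part = ni.localize_nahr(catalog.individuals["proband"]["del_hap"],
                                a_c, d_c, arch)
        assert part.fp3_label_count == 4

    def test_a_confirmed_through_second_of_five_5prime_labels(
            self, catalog, arch, father_candidates):
        a_c, d_c = father_candidates
        prob = catalog.individuals["proband"]["del_hap"]
        part = ni.localize_nahr(prob, a_c, d_c, arch)
        blk = prob.array_block("LCR22A")
        t_start = blk.start + 2 * hm.MODULE_LEN
        terminal = blk.modules[2]
        fp5_positions = sorted(t_start + arch.slot5[s]
                               for s in terminal.fingerprint5)
        assert len(fp5_positions) == 5
        # the A-side is confirmed exactly through the 2nd of those 5 labels
        assert part.a_confirmed[1] == fp5_positions[1]

    def test_ambiguous_interval_contains_no_discriminating_site(
            self, catalog, arch, father_candidates):
        a_c, d_c = father_candidates
        part = ni.localize_nahr(catalog.individuals["proband"]["del_hap"],
                                a_c, d_c, arch)
        lo, hi = part.ambiguous
        for p in part.a_sites + part.d_sites:
            assert not lo <= p <= hi
        assert part.a_confirmed[1] < part.ambiguous[0] \
            <= part.ambiguous[1] < part.d_confirmed[0]

    def test_inversion_state_disambiguates_d_donor(self, catalog, arch):
        # give der11's LCR22D module the same fingerprints as the intact
        # homolog's: only the flanking-inversion state then separates them
        father = copy.deepcopy(catalog.individuals["father"])
        fd1 = father["chr22_intact"].array_block("LCR22D").modules[0]
        father["der11"].array_block("LCR22D").modules[0] = hm.ModuleUnit(
            uid="FD2", orientation=fd1.orientation,
            fingerprint5=fd1.fingerprint5, fingerprint3=fd1.fingerprint3,
            core_sites=fd1.core_sites)
        a_c = {n: h for n, h in father.items() if h.array_block("LCR22A")}
        d_c = {n: h for n, h in father.items() if h.array_block("LCR22D")}
        part = ni.localize_nahr(catalog.individuals["proband"]["del_hap"],
                                a_c, d_c, catalog.arch)
        assert part.donor_d == ("chr22_intact", 1)

    def test_no_consistent_donor_pair_raises(self, catalog, arch,
                                             father_candidates):
        a_c, d_c = father_candidates
        # a haplotype whose terminal fingerprints match no catalog candidate
        mods = [hm.make_module(arch, "z1", hm.ORIENT_REF, (0, 5), (1, 5)),
                hm.make_module(arch, "z2", hm.ORIENT_REF, (2, 5), (0, 5))]
        alien = hm.build_deletion_haplotype(arch, "alien", mods, True)
        with pytest.raises(IrreconcilableDonorsError):
            ni.localize_nahr(alien, a_c, d_c, arch)


class TestInterpretQuadrivalent:
    def _origin(self, catalog):
        return ni.assign_parent_of_origin(
            sd.simulate_strp_trio(catalog, "father", seed=3))

    def test_fixture_end_to_end(self, catalog, arch, father_candidates):
        a_c, d_c = father_candidates
        part = ni.localize_nahr(catalog.individuals["proband"]["del_hap"],
                                a_c, d_c, arch)
        event = ni.interpret_quadrivalent(self._origin(catalog), part, catalog)
        assert event.donor_a == ("der22", 3)
        assert event.donor_d == ("chr22_intact", 1)
        assert event.meta["translocation_excluded"]
        assert hm.structure_equal(arch, event.product,
                                  catalog.individuals["proband"]["del_hap"])

    def test_swapped_donors_raise_model_inconsistency(self, catalog, arch,
                                                      father_candidates):
        a_c, d_c = father_candidates
        part = ni.localize_nahr(catalog.individuals["proband"]["del_hap"],
                                a_c, d_c, arch)
        bad = copy.deepcopy(part)
        bad.donor_a, bad.donor_d = ("chr22_intact", 1), ("der11", 1)
        with pytest.raises(ModelInconsistencyError):
            ni.interpret_quadrivalent(self._origin(catalog), bad, catalog)

    def test_succeeds_iff_product_matches_proband(self, catalog, arch,
                                                  father_candidates):
        a_c, d_c = father_candidates
        prob = catalog.individuals["proband"]["del_hap"]
        part = ni.localize_nahr(prob, a_c, d_c, arch)
        origin = self._origin(catalog)
        event = ni.interpret_quadrivalent(origin, part, catalog,
                                          proband_hap=prob)
        assert hm.structure_equal(arch, event.product, prob)
        # flip the proband's inversion state: the rebuilt product no longer
        # matches, so the interpretation must fail
        mutated = copy.deepcopy(prob)
        mutated.inversion_block().orientation = hm.ORIENT_REF
        with pytest.raises(ModelInconsistencyError):
            ni.interpret_quadrivalent(origin, part, catalog,
                                      proband_hap=mutated)


class TestEndToEndSingleFamily:
    def test_reconstructed_proband_supports_inference(self, catalog, arch):
        """Molecules -> chained structure -> localization, one family."""
        father = catalog.individuals["father"]
        prob = catalog.individuals["proband"]["del_hap"]
        mols = rec.filter_molecules(
            sd.simulate_homolog(arch, prob, 50, sd.NoiseParams(), seed=21),
            160_000)
        inventory = (hm.module_inventory(father.values(), "LCR22A")
                     + hm.module_inventory(father.values(), "LCR22D"))
        rc = rec.region_candidates(arch, "LCR22A", inventory)
        call = rec.chain_modules(mols, arch, rc)
        assert call.copy_number == 3
        mods = [hm.make_module(arch, call.assignments[i] or f"obs{i}",
                               call.orientations[i], *call.pattern_tuple(i))
                for i in range(call.copy_number)]
        # inversion state from molecule votes over the two realizations
        v_dir = hm.build_deletion_haplotype(arch, "v", mods, False)
        v_mir = hm.build_deletion_haplotype(arch, "v", mods, True)
        blk = v_dir.inversion_block()
        ic = rec.detect_inversion_from_molecules(
            [m for m in mols if m.start < blk.end + 20_000
             and m.end > blk.start - 20_000],
            hm.synthesize_positions(arch, v_dir),
            hm.synthesize_positions(arch, v_mir), (blk.start, blk.end))
        recon = hm.build_deletion_haplotype(arch, "recon", mods,
                                            ic.status == "present")
        a_c = {n: h for n, h in father.items() if h.array_block("LCR22A")}
        d_c = {n: h for n, h in father.items() if h.array_block("LCR22D")}
        part = ni.localize_nahr(recon, a_c, d_c, arch)
        assert part.donor_a == ("der22", 3)
        assert part.donor_d == ("chr22_intact", 1)
        assert part.fp3_label_count == 4
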