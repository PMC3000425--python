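import random

import pytest

import ablcp
from ablcp.digest import (
    MASS_SCALE,
    WATER_MASS,
    DigestMisuseError,
    DigestParams,
    build_mass_model,
    candidates_in_mass_window,
    compute_mass,
    digest_database,
    generate_full_specific,
    generate_nonspecific,
    generate_semi_specific,
)
from ablcp.enzyme import adjust_lcp_for_enzyme, build_cleavage_index, get_enzyme
from ablcp.redundancy_oracle import naive_digest
from ablcp.suffix_lcp import build_index

from conftest import digest_string_set, random_params, random_protein_db, run_generator

WIDE = DigestParams(specificity="none", min_length=1, max_length=60)


def build_all(db, enzyme_name):
    enz = get_enzyme(enzyme_name)
    idx = build_index(db)
    cl = build_cleavage_index(db, enz)
    return idx, adjust_lcp_for_enzyme(idx, cl, enz), cl, build_mass_model(db), enz


class TestNonSpecific:
    def test_suffix_vqvqv_generates_two_substrings(self, msq_db):
        idx = build_index(msq_db)
        peps = list(generate_nonspecific(msq_db, idx, build_mass_model(msq_db), WIDE))
        from_pos3 = sorted(p.sequence for p in peps if p.first_position == 3)
        assert from_pos3 == ["VQVQ", "VQVQV"]  # lengths LCP+1 .. suffix length

    def test_all_distinct_substrings_once(self, msq_db):
        idx = build_index(msq_db)
        peps = list(generate_nonspecific(msq_db, idx, build_mass_model(msq_db), WIDE))
        seqs = [p.sequence for p in peps]
        brute = {s[i:j] for s in ["MSQVQVQV"]
                 for i in range(len(s)) for j in range(i + 1, len(s) + 1)}
        assert len(seqs) == len(set(seqs)) == 26
        assert set(seqs) == brute

    def test_smallest_repeat_case(self):
        db = ablcp.from_sequences([("P1", "AA")])
        assert digest_string_set(db, WIDE) == {"A", "AA"}

    def test_count_identity(self):
        # emitted count = sum over residues of (distance-to-sentinel - LCP)+
        rng = random.Random(12)
        for _ in range(10):
            db = random_protein_db(rng)
            idx = build_index(db)
            peps = list(generate_nonspecific(db, idx, build_mass_model(db), WIDE))
            expected = 0
            for prot in db.proteins:
                for i in range(prot.start_offset, prot.end_offset):
                    cap = prot.end_offset - i
                    expected += max(cap - int(idx.lcp[i]), 0)
            assert len(peps) == expected

    def test_adjusted_lcp_is_misuse(self, mkar_db):
        idx, adj, cl, mass, enz = build_all(mkar_db, "trypsin")
        with pytest.raises(DigestMisuseError):
            list(generate_nonspecific(mkar_db, adj, mass, WIDE))


class TestFullSpecific:
    FULL = DigestParams(specificity="full", min_length=1, max_length=60)

    def test_tryptic_toy(self, mkar_db):
        peps = run_generator(mkar_db, self.FULL, get_enzyme("trypsin"))
        by_seq = {p.sequence: p for p in peps}
        assert set(by_seq) == {"MK", "AR", "MKAR"}
        assert by_seq["MK"].missed_cleavages == 0
        assert by_seq["AR"].missed_cleavages == 0
        assert by_seq["MKAR"].missed_cleavages == 1

    def test_protein_cterm_toggle(self):
        db = ablcp.from_sequences([("P1", "MKAA")])
        assert digest_string_set(db, self.FULL, get_enzyme("trypsin")) == \
            {"MK", "AA", "MKAA"}
        strict = DigestParams(specificity="full", min_length=1,
                              allow_protein_cterm=False)
        assert digest_string_set(db, strict, get_enzyme("trypsin")) == {"MK"}

    def test_adjustment_rescues_omitted_peptide(self, omission_db):
        idx, adj, cl, mass, enz = build_all(omission_db, "trypsin")
        with_adj = {p.sequence for p in
                    generate_full_specific(omission_db, adj, cl, mass, self.FULL, enz)}
        forced = idx.with_lcp(idx.lcp, enz.name)  # unadjusted values, flagged
        without = {p.sequence for p in
                   generate_full_specific(omission_db, forced, cl, mass, self.FULL, enz)}
        assert "AAK" in with_adj
        assert "AAK" not in without
        emitted = [p for p in
                   generate_full_specific(omission_db, adj, cl, mass, self.FULL, enz)
                   if p.sequence == "AAK"]
        assert emitted[0].first_position == 7

    def test_unadjusted_lcp_is_misuse(self, mkar_db):
        idx, adj, cl, mass, enz = build_all(mkar_db, "trypsin")
        with pytest.raises(DigestMisuseError):
            list(generate_full_specific(mkar_db, idx, cl, mass, self.FULL, enz))

    def test_trypsin_p_occurrence_rescue(self):
        # "AK" is invalid at its rank-first SS occurrence (followed by P)
        # but valid in the second protein; it must still be emitted once.
        db = ablcp.from_sequences([("P1", "RAKPW"), ("P2", "RAKGW")])
        peps = run_generator(db, self.FULL, get_enzyme("trypsin/p"))
        seqs = [p.sequence for p in peps]
        assert seqs.count("AK") == 1
        rescued = next(p for p in peps if p.sequence == "AK")
        assert db.protein_at(rescued.first_position).accession == "P2"
        assert set(seqs) == set(naive_digest(db, get_enzyme("trypsin/p"), self.FULL))


class TestSemiSpecific:
    SEMI = DigestParams(specificity="semi", min_length=1, max_length=60)

    def test_toy_matches_bruteforce(self, mkar_db):
        enz = get_enzyme("trypsin")
        got = digest_string_set(mkar_db, self.SEMI, enz)
        assert got == set(naive_digest(mkar_db, enz, self.SEMI))
        assert {"MK", "AR", "MKAR", "K", "R", "KAR", "MKA"} <= got

    def test_parts_partition_by_cterm_specificity(self):
        rng = random.Random(21)
        enz = get_enzyme("trypsin")
        for _ in range(10):
            db = random_protein_db(rng)
            peps = run_generator(db, self.SEMI, enz)
            part1 = {p.sequence for p in peps if p.cterm_specific}
            part2 = {p.sequence for p in peps if not p.cterm_specific}
            assert not part1 & part2

    @pytest.mark.parametrize("enzyme_name", ["trypsin", "trypsin/p"])
    def test_nested_between_full_and_nonspecific(self, enzyme_name):
        rng = random.Random(33)
        enz = get_enzyme(enzyme_name)
        for _ in range(10):
            db = random_protein_db(rng)
            mc = rng.randint(0, 3)
            mk = lambda s: DigestParams(specificity=s, max_missed_cleavages=mc,
                                        min_length=1, max_length=20)
            full = digest_string_set(db, mk("full"), enz)
            semi = digest_string_set(db, mk("semi"), enz)
            nonspec = digest_string_set(db, mk("none"))
            assert full <= semi <= nonspec


class TestEquivalenceAndRecords:
    @pytest.mark.parametrize("enzyme_name", ["trypsin", "trypsin/p", "glu-c", "asp-n"])
    @pytest.mark.parametrize("specificity", ["none", "full", "semi"])
    def test_string_set_equals_bruteforce(self, enzyme_name, specificity):
        rng = random.Random(hash((enzyme_name, specificity)) & 0xFFFF)
        enz = get_enzyme(enzyme_name)
        for _ in range(12):
            db = random_protein_db(rng)
            params = random_params(rng, specificity)
            peps = run_generator(db, params, None if specificity == "none" else enz)
            seqs = [p.sequence for p in peps]
            assert len(seqs) == len(set(seqs)), "a peptide string was emitted twice"
            expected = naive_digest(db, None if specificity == "none" else enz, params)
            assert sorted(set(seqs)) == expected

    def test_missed_cleavage_counts_are_intrinsic(self):
        rng = random.Random(8)
        enz = get_enzyme("trypsin")
        params = DigestParams(specificity="full", min_length=1,
                              max_missed_cleavages=3)
        for _ in range(10):
            db = random_protein_db(rng)
            for p in run_generator(db, params, enz):
                s = p.sequence
                # interior uncut boundaries: K/R anywhere but the last residue
                recount = sum(1 for c in s[:-1] if c in "KR")
                assert p.missed_cleavages == recount

    def test_sentinel_never_emitted(self):
        rng = random.Random(13)
        for _ in range(5):
            db = random_protein_db(rng)
            for p in run_generator(db, WIDE):
                assert "$" not in p.sequence

    def test_filter_widening_is_monotone(self):
        rng = random.Random(77)
        enz = get_enzyme("trypsin")
        db = random_protein_db(rng, max_proteins=3, max_len=50)
        narrow = DigestParams(specificity="full", max_missed_cleavages=1,
                              min_length=3, max_length=8,
                              min_mass=400 * MASS_SCALE, max_mass=900 * MASS_SCALE)
        wide = DigestParams(specificity="full", max_missed_cleavages=2,
                            min_length=2, max_length=12,
                            min_mass=200 * MASS_SCALE, max_mass=1500 * MASS_SCALE)
        assert digest_string_set(db, narrow, enz) <= digest_string_set(db, wide, enz)

    def test_unmassed_residues_are_skipped_only(self):
        db = ablcp.from_sequences([("P1", "AKXGK"), ("P2", "AKGGK")])
        got = digest_string_set(db, WIDE)
        assert all("X" not in s for s in got)
        assert got == set(naive_digest(db, None, WIDE))

    def test_first_position_is_an_occurrence(self):
        rng = random.Random(55)
        enz = get_enzyme("trypsin")
        params = DigestParams(specificity="semi", min_length=1, max_length=15)
        for _ in range(5):
            db = random_protein_db(rng)
            for p in run_generator(db, params, enz):
                i = p.first_position
                assert db.text[i:i + len(p.sequence)] == p.sequence


class TestMass:
    def test_ag_dipeptide(self):
        db = ablcp.from_sequences([("P1", "AG")])
        mm = build_mass_model(db)
        assert compute_mass(mm, 0, 2) == 1460692  # 146.0692 Da at x1e4

    def test_empty_span_is_water(self):
        db = ablcp.from_sequences([("P1", "AG")])
        mm = build_mass_model(db)
        assert compute_mass(mm, 1, 1) == WATER_MASS

    def test_prefix_difference_equals_direct_sum(self):
        rng = random.Random(2)
        db = random_protein_db(rng, max_proteins=3, max_len=40, force_krp=False)
        mm = build_mass_model(db)
        from ablcp.digest import RESIDUE_MASS
        for _ in range(200):
            prot = rng.choice(db.proteins)
            i = rng.randint(prot.start_offset, prot.end_offset)
            j = rng.randint(i, prot.end_offset)
            direct = WATER_MASS + sum(RESIDUE_MASS[c] for c in db.text[i:j])
            assert compute_mass(mm, i, j) == direct

    def test_domain_errors(self):
        db = ablcp.from_sequences([("P1", "AG"), ("P2", "GX")])
        mm = build_mass_model(db)
        with pytest.raises(ValueError, match="boundary"):
            compute_mass(mm, 0, 4)  # crosses the sentinel
        with pytest.raises(ValueError, match="mass"):
            compute_mass(mm, 3, 5)  # contains X


class TestMassWindow:
    def _ag_peptide(self):
        db = ablcp.from_sequences([("P1", "AG")])
        return run_generator(db, DigestParams(specificity="none", min_length=2))[0]

    def test_absolute_window(self):
        pep = self._ag_peptide()
        assert list(candidates_in_mass_window([pep], 1460692, 10000)) == [pep]
        assert list(candidates_in_mass_window([pep], 1480692, 10000)) == []

    def test_zero_tolerance(self):
        pep = self._ag_peptide()
        assert list(candidates_in_mass_window([pep], pep.mass, 0)) == [pep]
        assert list(candidates_in_mass_window([pep], pep.mass + 1, 0)) == []

    def test_ppm_rounds_outward(self):
        pep = self._ag_peptide()
        # 12 ppm of 1460692 integer units = 17.53 -> outward to 18
        assert list(candidates_in_mass_window([pep], pep.mass + 18, 12, ppm=True))
        assert not list(candidates_in_mass_window([pep], pep.mass + 19, 12, ppm=True))

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            list(candidates_in_mass_window([], 1000, -1))
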