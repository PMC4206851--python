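"""Code tables, wobble-rule anticodon generation, properties, null models."""

import pytest

from genehotel.algebra import named_subset, reverse_complement
from genehotel.codes import (
    AMINO_ACIDS,
    CodeTable,
    STOP,
    human_anticodons,
    load_anticodons,
    load_code,
    permute_labels,
    properties,
    random_code,
    sgc,
    standard_anticodons,
    write_anticodons,
    write_code,
)


class TestStandardGeneticCode:
    def test_basic_shape(self):
        code = sgc()
        assert len(code.mapping) == 64
        assert len(code.labels) == 21
        assert code.stop_codons == {"UAA", "UAG", "UGA"}
        assert len(code.sense_codons) == 61

    def test_initiator_codon(self):
        assert sgc()["AUG"] == "Met"

    def test_floor_occupancy(self):
        code = sgc()
        assert len(code.labels_on("NNC")) == 15
        # Trp and Met are encoded only on the roof NNG
        roof = named_subset("NNG")
        for aa in ("Trp", "Met"):
            codons = code.blocks()[aa]
            assert codons <= roof

    def test_synonymy_blocks_partition(self):
        blocks = sgc().blocks()
        assert sum(len(b) for b in blocks.values()) == 64
        seen = set()
        for b in blocks.values():
            assert not (b & seen)
            seen |= b

    def test_totality_enforced(self):
        with pytest.raises(ValueError, match="missing codons"):
            CodeTable(mapping={"AUG": "Met"}, name="partial")


class TestStandardAnticodons:
    def test_wobble_sharing(self):
        table = standard_anticodons()
        assert table["UUU"] == {"GAA"}
        assert table["UUC"] == {"GAA"}
        assert table["UUA"] == {"UAA"}
        assert table["UUG"] == {"CAA"}

    def test_unused_triplets(self):
        table = standard_anticodons()
        unused = table.unused_triplets()
        a_start = {t for t in unused if t.startswith("A")}
        assert a_start == named_subset("ANN")
        # the rest are the reverse complements of the three stop codons
        assert unused - a_start == {
            reverse_complement(c) for c in sgc().stop_codons
        }

    def test_counts(self):
        table = standard_anticodons()
        assert len(table.used_anticodons()) == 45
        assert table.n_species == 46
        assert table.species[-1] == ("CAU", "Met(initiator)")

    def test_every_g_anticodon_serves_two_codons(self):
        table = standard_anticodons()
        for ac in table.used_anticodons():
            served = table.codons_of(ac)
            assert len(served) == (2 if ac.startswith("G") else 1)

    def test_wobble_only_at_five_prime_base(self):
        for table in (standard_anticodons(), human_anticodons()):
            for codon, acs in table.mapping.items():
                rc = reverse_complement(codon)
                for ac in acs:
                    assert ac[1:] == rc[1:]


class TestHumanAnticodons:
    def test_shared_anticodon_sets(self):
        table = human_anticodons()
        shared = {
            ac for ac in table.used_anticodons()
            if len(table.codons_of(ac)) == 2
        }
        assert {ac for ac in shared if ac.startswith("G")} == {
            "GCC", "GUC", "GCU", "GUU", "GCA", "GUA", "GAA", "GUG"
        }
        assert {ac for ac in shared if ac.startswith("A")} == {
            "AAC", "AGC", "AAU", "AGU", "AGA", "ACG", "AAG", "AGG"
        }

    def test_inosine_flagging(self):
        table = human_anticodons()
        assert table["GCC"] == {"AGC"}
        assert table.flags["AGC"] == "inosine-5prime"
        # G-retained boxes carry no modification flag
        assert "GAA" not in table.flags

    def test_unused_triplets(self):
        table = human_anticodons()
        stop_rc = {reverse_complement(c) for c in sgc().stop_codons}
        unused = table.unused_triplets() - stop_rc
        assert len(unused) == 16
        assert sum(1 for t in unused if t.startswith("A")) == 8
        assert sum(1 for t in unused if t.startswith("G")) == 8

    def test_purine_start_anticodons_serve_two_codons(self):
        table = human_anticodons()
        for ac in table.used_anticodons():
            n = len(table.codons_of(ac))
            assert n == (2 if ac[0] in "AG" else 1)

    def test_pyrimidine_start_walls_fully_used(self):
        used = human_anticodons().used_anticodons()
        stop_rc = {reverse_complement(c) for c in sgc().stop_codons}
        assert named_subset("CNN") - used == {"CUA"}
        assert (named_subset("UNN") - used) == {"UUA", "UCA"}
        assert {"CUA", "UUA", "UCA"} == stop_rc
        assert len(used) == 45


class TestTableIO:
    def test_code_round_trip(self, tmp_path):
        path = tmp_path / "code.tsv"
        write_code(sgc(), path)
        assert load_code(path).mapping == sgc().mapping

    def test_anticodon_round_trip(self, tmp_path):
        path = tmp_path / "ac.tsv"
        table = human_anticodons()
        write_anticodons(table, path)
        loaded = load_anticodons(path)
        assert loaded.mapping == table.mapping
        assert loaded.flags == table.flags

    def test_missing_codon_reported(self, tmp_path):
        path = tmp_path / "partial.tsv"
        rows = [f"{c}\t{lab}" for c, lab in sorted(sgc().mapping.items())
                if c != "GGG"]
        path.write_text("codon\tlabel\n" + "\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="GGG"):
            load_code(path)

    def test_dna_alphabet_rejected(self, tmp_path):
        path = tmp_path / "dna.tsv"
        path.write_text("codon\tlabel\nATG\tMet\n")
        with pytest.raises(ValueError, match="RNA"):
            load_code(path)


class TestRandomCodes:
    def test_reproducible(self):
        assert random_code(7).mapping == random_code(7).mapping
        assert random_code(7, "shuffle-codons").mapping == \
            random_code(7, "shuffle-codons").mapping

    def test_identity_permutation_is_sgc(self):
        identity = {aa: aa for aa in AMINO_ACIDS}
        assert permute_labels(sgc(), identity).mapping == sgc().mapping

    def test_block_size_multiset_preserved(self):
        base_sizes = sorted(len(b) for b in sgc().blocks().values())
        for scheme in ("shuffle-labels", "shuffle-codons"):
            shuffled = random_code(3, scheme)
            assert sorted(len(b) for b in shuffled.blocks().values()) == base_sizes

    def test_shuffle_labels_keeps_stop_block(self):
        assert random_code(11).stop_codons == sgc().stop_codons

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            random_code(0, "bogus")


class TestPropertyTables:
    def test_totality(self):
        for name in ("polar_requirement", "hydropathy"):
            table = properties(name)
            assert set(table.values) == set(AMINO_ACIDS)

    def test_ser_mixed_class(self):
        table = properties("polar_requirement")
        assert table.class_of("Ser") == "mixed"
        assert table["Ser"] == 7.5

    def test_four_bin_classing(self):
        table = properties("polar_requirement")
        classes = set(table.classes().values())
        assert classes == {"q1", "q2", "q3", "q4", "mixed"}

    def test_hydropathy_no_mixed(self):
        table = properties("hydropathy")
        assert "mixed" not in set(table.classes().values())

    def test_unknown_property(self):
        with pytest.raises(ValueError, match="property"):
            properties("charge")
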