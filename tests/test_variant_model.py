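"""Normalization, maximal extension, classification and merging."""

import itertools
import random

import pytest

from anchorlift.variant_model import (
    Genotype,
    InMemoryGenome,
    MergeConflictError,
    UnanchorableAtEdgeError,
    VariantClass,
    VariantRecord,
    classify,
    classify_pair,
    is_allelic_primitive,
    maximally_extend,
    merge_biallelic,
    normalize,
    split_multiallelic,
)
from conftest import make_record


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """The sequence that results from substituting REF by ALT (1-based)."""
    assert seq[pos - 1:pos - 1 + len(ref)] == ref
    return seq[:pos - 1] + alt + seq[pos - 1 + len(ref):]


def brute_force_normalize(genome: str, rec: VariantRecord):
    """Enumerate every equivalent biallelic representation on a short contig
    and return the leftmost among the shortest ones."""
    edited = apply_edit(genome, rec.pos, rec.ref, rec.alts[0])
    delta = len(edited) - len(genome)
    best = None
    for pos in range(1, len(genome) + 1):
        for rlen in range(1, len(genome) - pos + 2):
            ref = genome[pos - 1:pos - 1 + rlen]
            alen = rlen + delta
            if alen < 1:
                continue
            # the replacement text is forced by (pos, rlen) and the edited seq
            alt = edited[pos - 1:pos - 1 + alen]
            if alt == ref:
                continue
            if apply_edit(genome, pos, ref, alt) == edited:
                cand = (rlen + len(alt), pos, ref, alt)
                if best is None or cand < best:
                    best = cand
    return best[1], best[2], best[3]


class TestNormalize:
    def test_str_deletion_left_aligned_parsimonious(self, str_genome):
        # deleting one CA unit, written mid-repeat
        rec = make_record("c", 5, "ACA", "A")
        out = normalize(rec, str_genome)
        assert (out.pos, out.ref, out.alts) == (3, "GCA", ("G",))

    def test_matches_brute_force_enumeration(self, str_genome):
        genome = "GGGCACACACAGGG"
        for pos, ref, alt in [(5, "ACA", "A"), (4, "C", "CCA"), (7, "A", "T"),
                              (6, "CACA", "CA"), (9, "ACAG", "AG")]:
            rec = make_record("c", pos, ref, alt)
            out = normalize(rec, str_genome)
            assert (out.pos, out.ref, out.alts[0]) == \
                brute_force_normalize(genome, rec), (pos, ref, alt)

    def test_snv_already_normalized(self, str_genome):
        rec = make_record("c", 7, "A", "T")
        assert normalize(rec, str_genome) == rec

    def test_idempotent_on_planted_records(self, pair_gap):
        g = pair_gap.src_genome
        for t in pair_gap.truth:
            once = normalize(t.record, g)
            assert normalize(once, g) == once

    def test_stops_at_contig_start(self):
        g = InMemoryGenome({"c": "AAAT"})
        # deletion of an A from a homopolymer touching position 1
        out = normalize(make_record("c", 2, "AA", "A"), g)
        assert out.pos == 1
        assert out.ref.startswith("A")


class TestMaximalExtension:
    def test_str_indel_extends_across_whole_repeat(self, str_genome):
        ext = maximally_extend(make_record("c", 3, "GCA", "G"), str_genome)
        assert ext.pos == 3
        assert ext.alleles == ("GCACACACAG", "GCACACAG")
        assert (ext.anchor5, ext.anchor3) == (3, 12)

    def test_extension_conditions_and_minimality(self, str_genome):
        ext = maximally_extend(make_record("c", 3, "GCA", "G"), str_genome)
        a, b = ext.alleles
        # no prefix/suffix relation; shared first and last base
        assert not a.startswith(b) and not a.endswith(b)
        assert a[0] == b[0] and a[-1] == b[-1]
        # minimality: every shorter trailing truncation breaks a condition
        for cut in range(1, len(b)):
            sa, sb = a[:-cut], b[:-cut]
            violates = (sa[-1] != sb[-1] or sa.startswith(sb) or sa.endswith(sb)
                        or sb.startswith(sa) or sb.endswith(sa))
            assert violates, cut

    def test_snv_gets_one_base_anchors_each_side(self):
        g = InMemoryGenome({"c": "AATAGTAA"})
        ext = maximally_extend(make_record("c", 5, "G", "C"), g)
        assert ext.alleles == ("AGT", "ACT")
        assert (ext.anchor5, ext.anchor3) == (4, 6)

    def test_all_equivalent_representations_extend_identically(self, str_genome):
        variants = [make_record("c", 5, "ACA", "A"), make_record("c", 3, "GCA", "G"),
                    make_record("c", 4, "CACA", "CA"), make_record("c", 6, "CAC", "C")]
        exts = {maximally_extend(v, str_genome) for v in variants}
        assert len(exts) == 1

    def test_normalizing_extended_recovers_normalized(self, str_genome):
        rec = make_record("c", 5, "ACA", "A")
        ext = maximally_extend(rec, str_genome)
        back = normalize(make_record("c", ext.pos, ext.alleles[0], ext.alleles[1]),
                         str_genome)
        assert back == normalize(rec, str_genome)

    def test_extension_preserves_the_edit(self, str_genome):
        genome = "GGGCACACACAGGG"
        rec = make_record("c", 5, "ACA", "A")
        ext = maximally_extend(rec, str_genome)
        assert apply_edit(genome, ext.pos, ext.alleles[0], ext.alleles[1]) == \
            apply_edit(genome, rec.pos, rec.ref, rec.alts[0])

    def test_contig_edge_is_an_error(self):
        g = InMemoryGenome({"c": "CACACA"})
        with pytest.raises(UnanchorableAtEdgeError):
            maximally_extend(make_record("c", 1, "CAC", "C"), g)

    def test_multiallelic_pairwise_over_alt_alt(self):
        # alt1 is a prefix of alt2: the alt-alt pair forces extension
        g = InMemoryGenome({"c": "TTGACGACGTT"})
        ext = maximally_extend(make_record("c", 3, "G", ("GACG", "GACGACG")), g)
        for x, y in itertools.combinations(ext.alleles, 2):
            s, l = (x, y) if len(x) < len(y) else (y, x)
            assert s == l or (not l.startswith(s) and not l.endswith(s))


class TestClassify:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", VariantClass.SNV),
        ("G", "GCA", VariantClass.INDEL),
        ("GCA", "G", VariantClass.INDEL),
        ("TTC", "TTCTC", VariantClass.INDEL),
        ("AT", "GC", VariantClass.MNV),
        ("AT", "G", VariantClass.COMPLEX),
        ("ACGT", "AGT", VariantClass.INDEL),
        ("A", "<DEL>", VariantClass.SYMBOLIC),
    ])
    def test_pair_classes(self, ref, alt, expected):
        assert classify_pair(ref, alt) == expected

    def test_overall_primitive_requires_every_pair(self):
        assert classify(make_record("c", 1, "T", ("C", "G"))) is VariantClass.SNV
        assert classify(make_record("c", 1, "TTC", ("T", "TTCTC"))) is VariantClass.INDEL
        # one MNV pair makes the whole record non-primitive
        mixed = make_record("c", 1, "CA", ("CAG", "TG"))
        assert not is_allelic_primitive(mixed)


class TestMerge:
    NUMBERS = {"AF": "A", "AD": "R", "PL": "G"}

    def test_same_ref_concatenates_alts(self):
        a = make_record("c", 10, "A", "AT")
        b = make_record("c", 10, "A", "AG")
        m = merge_biallelic([a, b])
        assert (m.ref, m.alts) == ("A", ("AT", "AG"))

    def test_ref_padding(self):
        a = make_record("c", 10, "AT", "A")
        b = make_record("c", 10, "A", "AG")
        m = merge_biallelic([a, b])
        assert (m.ref, m.alts) == ("AT", ("A", "AGT"))

    def test_merge_then_split_round_trips(self):
        g = InMemoryGenome({"c": "TTTTTATTTTTT"})
        a = make_record("c", 5, "TAT", "T",
                        info={"AF": (0.1,)},
                        samples=[{"GT": Genotype((0, 1)), "AD": (10, 2), "PL": (0, 10, 90)}])
        b = make_record("c", 5, "T", "TGC",
                        info={"AF": (0.2,)},
                        samples=[{"GT": Genotype((0, 0)), "AD": (11, 3), "PL": (0, 20, 80)}])
        m = merge_biallelic([a, b], numbers=self.NUMBERS)
        assert m.info["AF"] == (0.1, 0.2)
        assert m.samples[0]["GT"].indices == (0, 1)
        back = split_multiallelic(m, numbers=self.NUMBERS, genome=g)
        na, nb = normalize(a, g), normalize(b, g)
        assert [(r.pos, r.ref, r.alts, r.info["AF"]) for r in back] == \
            [(na.pos, na.ref, na.alts, (0.1,)), (nb.pos, nb.ref, nb.alts, (0.2,))]

    def test_genotype_reindexing_by_dosage(self):
        a = make_record("c", 10, "A", "AT", samples=[{"GT": Genotype((0, 1))}])
        b = make_record("c", 10, "A", "AG", samples=[{"GT": Genotype((0, 1))}])
        m = merge_biallelic([a, b])
        assert m.samples[0]["GT"].indices == (1, 2)

    def test_conflicting_dosage_refused(self):
        a = make_record("c", 10, "A", "AT", samples=[{"GT": Genotype((1, 1))}])
        b = make_record("c", 10, "A", "AG", samples=[{"GT": Genotype((0, 1))}])
        with pytest.raises(MergeConflictError):
            merge_biallelic([a, b])

    def test_incompatible_refs_rejected(self):
        a = make_record("c", 10, "AT", "A")
        b = make_record("c", 10, "AG", "A")
        with pytest.raises(ValueError):
            merge_biallelic([a, b])


class TestUniquenessProperty:
    """Randomly perturbed equivalent representations share one extension."""

    @staticmethod
    def perturb(rec, genome, rng, steps=3):
        pos, alleles = rec.pos, list(rec.alleles)
        clen = genome.length(rec.contig)
        for _ in range(steps):
            op = rng.choice(["pad_right", "pad_left", "shift"])
            end = pos + len(alleles[0]) - 1
            if op == "pad_right" and end < clen:
                base = genome.fetch(rec.contig, end + 1, end + 1)
                alleles = [a + base for a in alleles]
            elif op == "pad_left" and pos > 1:
                base = genome.fetch(rec.contig, pos - 1, pos - 1)
                alleles = [base + a for a in alleles]
                pos -= 1
            elif op == "shift" and end < clen and \
                    len({a[0] for a in alleles}) == 1 and all(len(a) > 1 for a in alleles):
                base = genome.fetch(rec.contig, end + 1, end + 1)
                alleles = [a[1:] + base for a in alleles]
                pos += 1
        from dataclasses import replace
        return replace(rec, pos=pos, ref=alleles[0], alts=tuple(alleles[1:]))

    def test_thousand_perturbations_one_extension(self, pair_gap):
        rng = random.Random(99)
        genome = pair_gap.src_genome
        checked = 0
        for t in pair_gap.truth:
            base_ext = maximally_extend(t.record, genome)
            base_norm = normalize(t.record, genome)
            for _ in range(5):
                alt_repr = self.perturb(t.record, genome, rng)
                assert maximally_extend(alt_repr, genome) == base_ext
                assert normalize(alt_repr, genome) == base_norm
                checked += 1
        assert checked >= 400


class TestRandomizedProperties:
    """Hypothesis-driven invariants on arbitrary short genomes and records."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    genomes = st.text(alphabet="ACGT", min_size=20, max_size=40)

    @staticmethod
    def _record_on(genome, pos, rlen, alt_seq):
        ref = genome[pos - 1:pos - 1 + rlen]
        alt = ref[0] + alt_seq if rlen > 1 or alt_seq else alt_seq or "G"
        if alt == ref:
            alt = ref + "A"
        return make_record("c", pos, ref, alt)

    @given(genome=genomes, pos=st.integers(2, 10), rlen=st.integers(1, 4),
           alt_seq=st.text(alphabet="ACGT", max_size=3))
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_normalize_idempotent_and_edit_preserving(self, genome, pos, rlen, alt_seq):
        g = InMemoryGenome({"c": genome})
        rec = self._record_on(genome, pos, rlen, alt_seq)
        out = normalize(rec, g)
        assert normalize(out, g) == out
        assert apply_edit(genome, out.pos, out.ref, out.alts[0]) == \
            apply_edit(genome, rec.pos, rec.ref, rec.alts[0])

    @given(genome=genomes, pos=st.integers(4, 10), rlen=st.integers(1, 3),
           alt_seq=st.text(alphabet="ACGT", max_size=3), pad=st.integers(1, 3))
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_extension_invariant_under_padding(self, genome, pos, rlen, alt_seq, pad):
        g = InMemoryGenome({"c": genome})
        rec = self._record_on(genome, pos, rlen, alt_seq)
        try:
            base = maximally_extend(rec, g)
        except UnanchorableAtEdgeError:
            return
        end = rec.pos + len(rec.ref) - 1
        if end + pad > len(genome):
            return
        tail = genome[end:end + pad]
        padded = make_record("c", rec.pos, rec.ref + tail,
                             tuple(a + tail for a in rec.alts))
        assert maximally_extend(padded, g) == base
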