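import numpy as np
import pytest

from ervkit.errors import FlankError, NotAProvirusError
from ervkit.provirus import (
    PBS_LYS3,
    PBS_LYS12,
    ProvirusRecord,
    classify_pbs,
    detect_tsd,
    extract_ltrs,
    extract_pbs,
    flanks_match,
    orf_status,
    validate_provirus,
)
from ervkit.seqio import SequenceRecord


def rand_seq(rng, n):
    return "".join(np.random.default_rng(rng).choice(list("ACGT"), n)) \
        if isinstance(rng, int) else "".join(rng.choice(list("ACGT"), n))


def mutate(seq, frac, rng):
    out = list(seq)
    k = int(round(frac * len(seq)))
    for i in rng.choice(len(seq), size=k, replace=False):
        out[i] = rng.choice([c for c in "ACGT" if c != seq[i]])
    return "".join(out)


class TestExtractLtrs:
    def test_exact_planted_repeats_recovered_exactly(self, rng):
        ltr = rand_seq(rng, 480)
        inner = rand_seq(rng, 7400)
        seq = ltr + inner + ltr
        l5, l3, ident = extract_ltrs(seq)
        assert l5 == (0, 480)
        assert l3 == (7880, 8360)
        assert ident == 1.0

    def test_diverged_repeats_recovered_with_identity(self, rng):
        ltr = rand_seq(rng, 480)
        inner = rand_seq(rng, 7400)
        ltr3 = mutate(ltr, 0.02, rng)
        seq = ltr + inner + ltr3
        l5, l3, ident = extract_ltrs(seq)
        # boundary mutations allow a few nt of slack
        assert abs(l5[0] - 0) + abs(l5[1] - 480) <= 6
        assert abs(l3[0] - 7880) + abs(l3[1] - 8360) <= 6
        assert ident == pytest.approx(0.98, abs=0.01)

    def test_random_sequence_is_not_a_provirus(self, rng):
        with pytest.raises(NotAProvirusError):
            extract_ltrs(rand_seq(rng, 8000))

    def test_too_short_sequence_rejected(self):
        with pytest.raises(NotAProvirusError):
            extract_ltrs("ACGT" * 100)

    def test_ancestor_ltrs_recovered(self, ancestor):
        l5, l3, ident = extract_ltrs(ancestor.locus)
        assert l5 == ancestor.ltr5_span
        assert l3 == ancestor.ltr3_span
        assert ident == 1.0


class TestDetectTsd:
    @pytest.mark.parametrize("tsd", ["ATTTGG", "TGGATA"])
    def test_planted_duplication_recovered(self, tsd, rng):
        prov = rand_seq(rng, 1000)
        locus = rand_seq(rng, 100) + tsd + prov + tsd + rand_seq(rng, 100)
        assert detect_tsd(locus, (106, 1106)) == tsd

    def test_single_mismatch_means_absent(self, rng):
        prov = rand_seq(rng, 1000)
        locus = rand_seq(rng, 100) + "ATTTGG" + prov + "ATTTGC" + rand_seq(rng, 100)
        assert detect_tsd(locus, (106, 1106)) is None

    def test_insufficient_flank_errors(self):
        with pytest.raises(FlankError):
            detect_tsd("AAA" + "C" * 50 + "AAA", (3, 53))


class TestPBS:
    def test_consensus_references_classify_exactly(self):
        for pbs, label in [(PBS_LYS3, "lys3"), (PBS_LYS12, "lys12")]:
            call = classify_pbs(pbs)
            assert call.label == label
            assert min(call.edit_distance_lys3, call.edit_distance_lys12) == 0
            assert call.variants == []

    def test_label_invariant_under_reference_order(self):
        # distance computation must not depend on comparison order
        call = classify_pbs(PBS_LYS12)
        assert call.edit_distance_lys12 == 0 < call.edit_distance_lys3

    def test_equidistant_witness_is_ambiguous(self, rng):
        # brute-force search for an 18-mer equidistant from both references
        import edlib

        witness = None
        for _ in range(5000):
            cand = rand_seq(rng, 18)
            d3 = edlib.align(cand, PBS_LYS3, mode="NW")["editDistance"]
            d12 = edlib.align(cand, PBS_LYS12, mode="NW")["editDistance"]
            if d3 == d12:
                witness = cand
                break
        assert witness is not None
        assert classify_pbs(witness).label == "ambiguous"

    def test_extract_from_planted_provirus(self, ancestor):
        pbs = extract_pbs(ancestor.locus, ancestor.ltr5_span)
        assert pbs == PBS_LYS3

    def test_single_insertion_extends_window(self, ancestor):
        s = ancestor.locus.residues
        end = ancestor.ltr5_span[1]
        # insert a T after position 8 of the PBS (the common variant)
        mutated = s[: end + 9] + "T" + s[end + 9:]
        pbs = extract_pbs(mutated, ancestor.ltr5_span)
        assert len(pbs) == 19
        call = classify_pbs(pbs)
        assert call.edit_distance_lys3 == 1
        assert any(v.startswith("ins") for _, v in call.variants)

    def test_truncated_record_errors(self):
        with pytest.raises(FlankError):
            extract_pbs("A" * 490, (0, 485))


class TestOrfStatus:
    def test_open_reference_gene(self):
        gene = "ATGGCTGCTGCT" * 10 + "TAA"  # internal codons are non-stop
        st = orf_status(gene, len(gene))
        assert st.state == "open"

    def test_single_deletion_is_frameshift(self):
        gene = "ATGGCTGCTGCTTAA"
        st = orf_status(gene[:-1], len(gene))
        assert st.state == "frameshift_indel"

    def test_cga_to_tga_premature_stop_positioned(self):
        gene = "ATG" + "CGA" + "GCT" * 5 + "TAA"
        mutated = "ATG" + "TGA" + "GCT" * 5 + "TAA"
        assert orf_status(gene, len(gene)).state == "open"
        st = orf_status(mutated, len(gene))
        assert st.state == "premature_stop"
        assert st.detail == 4  # first nt of the second codon

    def test_open_stable_under_synonymous_change(self):
        gene = "ATGCTTGCTTAA"
        syn = "ATGCTAGCTTAA"  # CTT->CTA, still Leu, no stop introduced
        assert orf_status(gene, len(gene)).state == "open"
        assert orf_status(syn, len(gene)).state == "open"


def _record_with_ltrs(rng, ltr=None, ltr3=None, flank=60):
    ltr = rand_seq(rng, 450) if ltr is None else ltr
    inner = rand_seq(rng, 2000)
    ltr3 = ltr if ltr3 is None else ltr3
    prov = ltr + inner + ltr3
    f5, f3 = rand_seq(rng, flank), rand_seq(rng, flank)
    locus = SequenceRecord("p", f5 + prov + f3)
    return ProvirusRecord(
        id="p", locus=locus,
        ltr5_span=(flank, flank + 450),
        ltr3_span=(flank + 450 + 2000, flank + 450 + 2000 + 450),
    )


class TestValidateProvirus:
    def test_typical_distance_is_valid(self, rng):
        ltr = rand_seq(rng, 450)
        rec = _record_with_ltrs(rng, ltr=ltr, ltr3=mutate(ltr, 0.02, rng))
        assert validate_provirus(rec, [0.03, 0.02, 0.04]) == "valid"

    def test_identical_ltrs_valid_at_zero(self, rng):
        rec = _record_with_ltrs(rng)
        assert validate_provirus(rec, [0.0, 0.01]) == "valid"

    def test_shuffled_ltr_is_suspect(self, rng):
        shuffled = rand_seq(rng, 450)  # unrelated: ~75% divergence
        rec = _record_with_ltrs(rng, ltr3=shuffled)
        assert validate_provirus(rec, [0.02, 0.03]) == "suspect_assembly"

    def test_moderate_outlier_exceeds_median_multiple(self, rng):
        ltr = rand_seq(rng, 450)
        rec = _record_with_ltrs(rng, ltr=ltr, ltr3=mutate(ltr, 0.12, rng))
        assert validate_provirus(rec, [0.02, 0.03, 0.02]) == "suspect_assembly"


class TestFlanksMatch:
    def test_same_integration_site_matches(self, rng):
        a = _record_with_ltrs(rng)
        host5, host3 = a.locus.residues[:60], a.locus.residues[-60:]
        prov2 = rand_seq(rng, 2900)
        b = ProvirusRecord(
            id="q", locus=SequenceRecord("q", host5 + prov2 + host3),
            ltr5_span=(60, 510), ltr3_span=(2510, 2960),
        )
        assert flanks_match(a, b)

    def test_different_sites_do_not_match(self, rng):
        a = _record_with_ltrs(rng)
        b = _record_with_ltrs(rng)
        assert not flanks_match(a, b)

    def test_four_percent_flank_divergence_tolerated(self, rng):
        a = _record_with_ltrs(rng)
        h5 = mutate(a.locus.residues[:60], 0.04, rng)
        h3 = mutate(a.locus.residues[-60:], 0.04, rng)
        mid = a.locus.residues[60:-60]
        b = ProvirusRecord(
            id="q", locus=SequenceRecord("q", h5 + mid + h3),
            ltr5_span=a.ltr5_span, ltr3_span=a.ltr3_span,
        )
        assert flanks_match(a, b)

    def test_short_flank_errors(self, rng):
        a = _record_with_ltrs(rng, flank=10)
        b = _record_with_ltrs(rng, flank=10)
        with pytest.raises(FlankError):
            flanks_match(a, b)
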