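"""Alignment, per-read classification precedence, and summaries."""

import random

import pytest

from editaudit import (
    CallParams,
    ContractError,
    EmbryoScenario,
    InputError,
    align_read,
    call_read,
    classify_reads,
    indel_spectrum,
    simulate_embryo_reads,
    summarize_embryo,
    summarize_experiment,
)
from editaudit.synthetic import (
    COMPLEX,
    HDR_OLIGO,
    HDR_PARALOG,
    HDR_PARTIAL,
    NHEJ_INDEL,
    WT,
)

from .oracles import gotoh_score


def edit(target, pos, base=None, delete=0, insert=""):
    s = list(target)
    if base is not None:
        s[pos] = base
    out = "".join(s)
    if delete:
        out = out[:pos] + out[pos + delete:]
    if insert:
        out = out[:pos] + insert + out[pos:]
    return out


def with_donor_signatures(locus, donor, indices):
    s = list(locus.target_seq)
    for i in indices:
        pos, _ref, db = donor.signature_positions[i]
        s[pos] = db
    return "".join(s)


def with_paralog_bases(locus, positions):
    s = list(locus.target_seq)
    for pos, _tb, pb in locus.discriminating_positions:
        if pos in positions:
            s[pos] = pb
    return "".join(s)


class TestAlignRead:
    def test_identity_alignment(self, locus):
        aln = align_read(locus.target_seq, locus.target_seq)
        assert aln.indels == ()
        assert aln.score == 2 * len(locus.target_seq)

    def test_two_bp_deletion_at_cut(self, locus):
        cut = locus.cut_site
        read = edit(locus.target_seq, cut, delete=2)
        aln = align_read(read, locus.target_seq)
        assert len(aln.indels) == 1
        ind = aln.indels[0]
        assert ind.kind == "del" and ind.length == 2
        # left-normalized position may sit a few bases 5' in repeat context
        assert ind.pos <= cut and ind.overlaps(cut - 5, cut + 5)

    def test_six_substitutions_no_gaps(self, locus, donor):
        read = with_donor_signatures(locus, donor, range(6))
        aln = align_read(read, locus.target_seq)
        assert aln.indels == ()
        assert aln.score == 2 * (len(read) - 6) - 2 * 6

    def test_insertion_recovered(self, locus):
        cut = locus.cut_site
        read = edit(locus.target_seq, cut, insert="TTAC")
        aln = align_read(read, locus.target_seq)
        assert [i.kind for i in aln.indels] == ["ins"]
        assert aln.indels[0].length == 4

    def test_non_dna_rejected(self, locus):
        with pytest.raises(InputError):
            align_read("ACGU", locus.target_seq)
        with pytest.raises(InputError):
            align_read("", locus.target_seq)

    def test_score_matches_independent_dp_oracle(self):
        rng = random.Random(42)
        for _ in range(40):
            n = rng.randint(20, 80)
            target = "".join(rng.choice("ACGT") for _ in range(n))
            read = list(target[: rng.randint(15, n)])
            for _ in range(rng.randint(0, 6)):  # random substitutions
                i = rng.randrange(len(read))
                read[i] = rng.choice("ACGT")
            if rng.random() < 0.5 and len(read) > 10:  # random small indel
                i = rng.randrange(5, len(read) - 5)
                if rng.random() < 0.5:
                    del read[i : i + rng.randint(1, 3)]
                else:
                    read[i:i] = rng.choice("ACGT")
            read = "".join(read)
            assert align_read(read, target).score == gotoh_score(target, read)


class TestCallPrecedence:
    def test_wild_type(self, locus, donor, params):
        aln = align_read(locus.target_seq, locus.target_seq)
        assert call_read(aln, locus, donor, params).category == WT

    def test_cut_indel_is_nhej(self, locus, donor, params):
        read = edit(locus.target_seq, locus.cut_site, delete=3)
        call = call_read(align_read(read, locus.target_seq), locus, donor, params)
        assert call.category == NHEJ_INDEL
        assert call.cut_disrupted and call.indel.kind == "del"

    def test_all_donor_signatures_is_oligo_hdr(self, locus, donor, params):
        read = with_donor_signatures(locus, donor, range(6))
        call = call_read(align_read(read, locus.target_seq), locus, donor, params)
        assert call.category == HDR_OLIGO
        assert all(s == "donor" for p, s in call.signature_states
                   if p in donor.signature_coords)

    def test_four_tandem_paralog_bases_is_paralog_hdr(self, locus, donor, params):
        read = with_paralog_bases(locus, set(locus.disc_coords))
        call = call_read(align_read(read, locus.target_seq), locus, donor, params)
        assert call.category == HDR_PARALOG

    def test_partial_donor_conversion(self, locus, donor, params):
        read = with_donor_signatures(locus, donor, range(4))
        call = call_read(align_read(read, locus.target_seq), locus, donor, params)
        assert call.category == HDR_PARTIAL

    def test_indel_plus_signatures_is_complex(self, locus, donor, params):
        read = with_donor_signatures(locus, donor, range(3))
        read = edit(read, locus.cut_site, delete=2)
        call = call_read(align_read(read, locus.target_seq), locus, donor, params)
        assert call.category == COMPLEX and call.cut_disrupted

    def test_min_tract_run_boundary(self, locus, donor, params):
        coords = locus.disc_coords
        two = with_paralog_bases(locus, set(coords[:2]))
        one = with_paralog_bases(locus, {coords[0]})
        two_call = call_read(align_read(two, locus.target_seq), locus, donor, params)
        one_call = call_read(align_read(one, locus.target_seq), locus, donor, params)
        assert two_call.category == HDR_PARALOG
        # a single converted base is below the tract threshold -> not paralog HDR
        assert one_call.category == COMPLEX

    def test_nonconsecutive_paralog_bases_not_a_tract(self, locus, donor, params):
        coords = locus.disc_coords
        read = with_paralog_bases(locus, {coords[0], coords[2]})
        call = call_read(align_read(read, locus.target_seq), locus, donor, params)
        assert call.category == COMPLEX

    def test_stray_substitution_is_complex(self, locus, donor, params):
        pos = 10
        assert pos not in locus.disc_coords
        read = edit(locus.target_seq, pos,
                    base="A" if locus.target_seq[pos] != "A" else "C")
        call = call_read(align_read(read, locus.target_seq), locus, donor, params)
        assert call.category == COMPLEX

    def test_far_indel_is_complex_not_nhej(self, locus, donor, params):
        read = edit(locus.target_seq, 30, delete=2)
        call = call_read(align_read(read, locus.target_seq), locus, donor, params)
        assert call.category == COMPLEX and not call.cut_disrupted

    def test_wrong_target_rejected(self, locus, donor, params):
        aln = align_read(locus.paralog_seq, locus.paralog_seq)
        with pytest.raises(ContractError):
            call_read(aln, locus, donor, params)


class TestSummaries:
    def make_calls(self, locus, donor, params, reads):
        return classify_reads(
            ((f"r{i}", "e1", s) for i, s in enumerate(reads)), locus, donor, params
        )

    def test_all_wt_embryo(self, locus, donor, params):
        calls = self.make_calls(locus, donor, params, [locus.target_seq] * 50)
        s = summarize_embryo(calls, "e1")
        assert not s.cleaved and s.n_distinct_alleles == 1 and not s.mosaic
        assert sum(s.allele_spectrum.values()) == 50

    def test_mixed_embryo_allele_spectrum(self, locus, donor, params):
        cut = locus.cut_site
        reads = ([locus.target_seq] * 5
                 + [edit(locus.target_seq, cut, delete=2)] * 3
                 + [edit(locus.target_seq, cut - 1, insert="A")] * 2
                 + [with_donor_signatures(locus, donor, range(6))] * 2)
        calls = self.make_calls(locus, donor, params, reads)
        s = summarize_embryo(calls, "e1")
        assert s.cleaved and s.hdr_oligo and not s.hdr_paralog
        assert s.n_distinct_alleles == 4 and s.mosaic
        assert sum(s.allele_spectrum.values()) == len(reads)

    def test_adding_non_wt_read_never_uncleaves(self, locus, donor, params):
        cut = locus.cut_site
        base = self.make_calls(locus, donor, params,
                               [locus.target_seq] * 3
                               + [edit(locus.target_seq, cut, delete=1)])
        extra = self.make_calls(locus, donor, params,
                                [with_donor_signatures(locus, donor, range(6))])
        assert summarize_embryo(base, "e1").cleaved
        assert summarize_embryo(base + extra, "e1").cleaved

    def test_contract_errors(self, locus, donor, params):
        with pytest.raises(ContractError):
            summarize_embryo([], "e1", amplified=True)
        calls = self.make_calls(locus, donor, params, [locus.target_seq])
        with pytest.raises(ContractError):
            summarize_embryo(calls, "e2")
        with pytest.raises(ContractError):
            summarize_embryo(calls, "e1", amplified=False)

    def test_experiment_percentages(self, locus, donor, params):
        cut = locus.cut_site
        cleaved_calls = self.make_calls(locus, donor, params,
                                        [edit(locus.target_seq, cut, delete=2)])
        wt_calls = self.make_calls(locus, donor, params, [locus.target_seq])
        summaries = []
        for i in range(28):
            s = summarize_embryo(cleaved_calls, "e1")
            s.embryo_id = f"c{i}"
            summaries.append(s)
        for i in range(26):
            s = summarize_embryo(wt_calls, "e1")
            s.embryo_id = f"w{i}"
            summaries.append(s)
        exp = summarize_experiment(summaries)
        assert exp.n_amplified == 54 and exp.n_cleaved == 28
        assert round(exp.pct_cleaved, 1) == 51.9

    def test_zero_cleaved_is_zero_percent(self, locus, donor, params):
        calls = self.make_calls(locus, donor, params, [locus.target_seq])
        exp = summarize_experiment([summarize_embryo(calls, "e1")])
        assert exp.pct_cleaved == 0.0
        assert exp.pct_hdr_oligo_of_cleaved == 0.0

    def test_no_amplified_embryos_percentage_undefined(self):
        from editaudit.outcomes import EmbryoSummary
        dropout = EmbryoSummary("d1", False, False, False, False, {}, 0)
        exp = summarize_experiment([dropout])
        with pytest.raises(ContractError):
            exp.pct_cleaved

    def test_indel_spectrum_counts_and_order(self, locus, donor, params):
        cut = locus.cut_site
        reads = ([edit(locus.target_seq, cut, delete=2)] * 10
                 + [edit(locus.target_seq, cut - 1, insert="A")] * 5)
        calls = self.make_calls(locus, donor, params, reads)
        df = indel_spectrum(calls)
        assert sorted(df["count"]) == [5, 10]
        assert list(df["pos"]) == sorted(df["pos"])

    def test_indel_spectrum_empty_for_wt(self, locus, donor, params):
        calls = self.make_calls(locus, donor, params, [locus.target_seq] * 3)
        assert indel_spectrum(calls).empty


class TestTruthRoundTrip:
    def test_classifier_recovers_simulation_truth(self, locus, donor, params):
        for seed in range(10):
            sc = EmbryoScenario(
                embryo_id="rt",
                mixture={"WT": 0.3, "NHEJ_INDEL": 0.3, "HDR_OLIGO": 0.2,
                         "HDR_PARALOG": 0.1, "HDR_PARTIAL": 0.1},
                n_reads=30, seed=seed,
            )
            reads = simulate_embryo_reads(locus, donor, sc)
            calls = classify_reads(((r.read_id, r.embryo_id, r.seq) for r in reads),
                                   locus, donor, params)
            truth = {r.read_id: r.true_category for r in reads}
            assert {c.read_id: c.category for c in calls} == truth
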