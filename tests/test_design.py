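"""Designer tests, anchored on independent brute-force oracles."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from riboverlap.design import (
    MotifSpec,
    Rejection,
    RejectionReason,
    RibosorConfig,
    RiboverlapCandidate,
    Stringency,
    apply_overlap,
    clear_frame,
    design,
    find_motif_sites,
    match_motif,
    pad_length,
)
from riboverlap.fixtures import random_cds
from riboverlap.seqcore import (
    CDSRecord,
    STANDARD_TABLE,
    SequenceError,
    count_synonymous_variants,
    synonymous_variants,
    translate,
)

PLANTED = "ATGAGGAGGCATCATCATGCATAA"  # AGGAGG at 3, spacer 7, ATG at 16 (frame +1)

#: A/G-biased codon usage so small random CDSs actually admit motifs
AG_BIAS = {"GAG": 3, "AAG": 3, "GGA": 1, "ATG": 1, "TGG": 1, "CAT": 2, "GCA": 1}


def brute_force_motif_check(seq: str, spec: MotifSpec):
    """Position-by-position motif checker, independent of match_motif."""
    hits = []
    k = len(spec.sd_consensus)
    for sd_start in range(len(seq)):
        for spacer in range(spec.spacer_min, spec.spacer_max + 1):
            start = sd_start + k + spacer
            if start + 3 > len(seq):
                continue
            mism = 0
            for i in range(k):
                if seq[sd_start + i] != spec.sd_consensus[i]:
                    mism += 1
            if mism <= spec.max_sd_mismatches and seq[start : start + 3] in spec.start_codons:
                hits.append((sd_start, spacer, start))
    return sorted(hits)


def exhaustive_motif_starts(cds: CDSRecord, spec: MotifSpec):
    """Alternate-frame motif starts over ALL full-sequence synonymous variants."""
    body, stop = cds.sequence[:-3], cds.sequence[-3:]
    starts = set()
    for var in synonymous_variants(body):
        for _, _, st_pos in match_motif(var + stop, spec):
            if st_pos % 3 != 0:
                starts.add(st_pos)
    return starts


class TestMatchMotif:
    def test_exact_consensus_placement(self):
        window = "AGGAGG" + "CCCCC" + "ATG"
        assert match_motif(window) == [(0, 5, 11)]

    def test_spacer_below_minimum_rejected(self):
        assert match_motif("AGGAGGCCATG") == []

    def test_one_mismatch_tolerated_two_rejected(self):
        assert match_motif("AGGAGC" + "CCC" + "ATG") == [(0, 3, 9)]
        assert match_motif("AGGACC" + "CCC" + "ATG") == []

    def test_sampled_equivalence_with_bruteforce_checker(self):
        import numpy as np

        rng = np.random.default_rng(42)
        spec = MotifSpec()
        bases = np.array(list("ACGT"))
        for _ in range(10_000):
            s = "".join(bases[rng.integers(0, 4, size=14)])
            assert match_motif(s, spec) == brute_force_motif_check(s, spec)


class TestFindMotifSites:
    def test_preplanted_motif_needs_zero_edits(self):
        cds = CDSRecord("toy", PLANTED)
        sites = find_motif_sites(cds, RibosorConfig())
        hit = [s for s in sites if s.start_nt == 16]
        assert len(hit) == 1
        assert hit[0].frame == 1 and hit[0].edits == () and hit[0].aa_cost == 0

    def test_exhaustive_fullsequence_oracle_equivalence(self):
        """The placement search finds a motif at position p iff some
        full-sequence synonymous variant carries one there."""
        config = RibosorConfig()
        n_checked = n_nonempty = 0
        for seed in range(60):
            cds = random_cds(10, usage_bias=AG_BIAS, seed=seed)
            if count_synonymous_variants(cds.sequence[:-3]) > 20_000:
                continue
            oracle = exhaustive_motif_starts(cds, config.motif)
            found = {s.start_nt for s in find_motif_sites(cds, config)}
            assert found == oracle, f"seed {seed}"
            n_checked += 1
            n_nonempty += bool(oracle)
        assert n_checked >= 20 and n_nonempty >= 2

    def test_no_motif_in_pyrimidine_rich_cds(self):
        # Leu/Phe/Ser-only body cannot form an AG-rich SD at stringency 0
        cds = CDSRecord("py", "ATG" + "CTTTTTTCT" * 3 + "TAA")
        assert exhaustive_motif_starts(cds, MotifSpec()) == set()
        assert find_motif_sites(cds, RibosorConfig()) == []

    def test_stringency_monotonicity_of_sites(self):
        for seed in range(10):
            cds = random_cds(25, usage_bias=AG_BIAS, seed=seed)
            sites = {}
            for s in (Stringency.S0, Stringency.S1, Stringency.S2plus):
                sites[s] = {
                    (x.start_nt, x.frame)
                    for x in find_motif_sites(cds, RibosorConfig(stringency=s))
                }
            assert sites[Stringency.S0] <= sites[Stringency.S1]
            assert sites[Stringency.S1] <= sites[Stringency.S2plus]

    def test_s1_sites_cost_at_most_one_aa(self):
        cds = random_cds(25, usage_bias=AG_BIAS, seed=3)
        for site in find_motif_sites(cds, RibosorConfig(stringency=Stringency.S1)):
            assert site.aa_cost <= 1


def _raw_site_at(cds, start_nt, config):
    sites = [s for s in find_motif_sites(cds, config) if s.start_nt == start_nt]
    assert sites, f"no raw site at {start_nt}"
    return sites[0]


class TestClearFrame:
    # planted motif (start 16, frame +1) followed by codons TTA AAA whose
    # new-frame reading contains TAA at nt 22
    LEU_STOP = "ATGAGGAGGCATCATCATGCATTAAAATAA"
    # same construction with ATG ATG under the new frame: TGA at nt 22 with
    # both overlapping codons synonym-free
    MET_STOP = "ATGAGGAGGCATCATCATGCAATGATGTAA"

    def test_stop_free_frame_needs_no_extra_edits(self):
        cds = CDSRecord("toy", PLANTED)
        config = RibosorConfig()
        cand = clear_frame(cds, _raw_site_at(cds, 16, config), config)
        assert isinstance(cand, RiboverlapCandidate)
        assert cand.frame_stop_free and cand.edits == ()

    def test_leucine_stop_fix_matches_exhaustive_oracle(self):
        """TTA AAA reads TAA in the +1 frame; enumerate all Leu x Lys
        recodings independently and require the minimal-edit fix."""
        cds = CDSRecord("toy", self.LEU_STOP)
        config = RibosorConfig()
        cand = clear_frame(cds, _raw_site_at(cds, 16, config), config)
        assert isinstance(cand, RiboverlapCandidate)
        assert cand.frame_stop_free and cand.aa_changes_made == 0

        # independent oracle over the two overlapping codons (21-26)
        table = STANDARD_TABLE
        fixes = []
        for leu, lys in itertools.product(table.synonyms("TTA"), table.synonyms("AAA")):
            seq = self.LEU_STOP[:21] + leu + lys + self.LEU_STOP[27:]
            stops = [
                p
                for p in range(16, len(seq) - 2, 3)
                if table.is_stop(seq[p : p + 3])
            ]
            if not stops:
                n_edits = sum(
                    a != b for a, b in zip(leu + lys, self.LEU_STOP[21:27])
                )
                fixes.append((n_edits, (leu, lys)))
        assert fixes, "oracle found no synonymous fix"
        best = min(fixes)
        assert {c for _, c in fixes if _ == best[0]} >= {best[1]}
        assert cand.edited_sequence[21:27] == "".join(best[1])
        # the exhaustive oracle agrees the Leu codon must become CTC
        assert cand.edited_sequence[21:24] == "CTC"

    def test_synonym_free_stop_rejected_at_s0(self):
        cds = CDSRecord("toy", self.MET_STOP)
        config = RibosorConfig(stringency=Stringency.S0)
        res = clear_frame(cds, _raw_site_at(cds, 16, config), config)
        assert isinstance(res, Rejection)
        assert res.reason is RejectionReason.IRREMOVABLE_STOP

    def test_synonym_free_stop_becomes_suggestion_at_s2plus(self):
        cds = CDSRecord("toy", self.MET_STOP)
        config = RibosorConfig(stringency=Stringency.S2plus)
        cand = clear_frame(cds, _raw_site_at(cds, 16, config), config)
        assert isinstance(cand, RiboverlapCandidate)
        assert cand.aa_changes_remaining >= 1
        assert not cand.frame_stop_free
        assert cand.suggestions and cand.suggestions[0][1]

    def test_synonym_free_stop_fixed_at_s1_with_one_aa_change(self):
        cds = CDSRecord("toy", self.MET_STOP)
        config = RibosorConfig(stringency=Stringency.S1)
        cand = clear_frame(cds, _raw_site_at(cds, 16, config), config)
        assert isinstance(cand, RiboverlapCandidate)
        assert cand.frame_stop_free and cand.aa_changes_made == 1


class TestDesign:
    def test_planted_first_candidate_overlap_fraction(self):
        cds = CDSRecord("toy", PLANTED)
        cands = design(cds, RibosorConfig())
        assert cands[0].start_nt == 16
        assert cands[0].overlap_fraction == pytest.approx((24 - 16) / 24)

    def test_s0_preserves_protein_exactly(self):
        config = RibosorConfig()
        for seed in range(200):
            cds = random_cds(20, usage_bias=AG_BIAS, seed=seed)
            for cand in design(cds, config):
                assert translate(cand.edited_sequence, 0) == translate(
                    cds.sequence, 0
                )
                assert cand.aa_changes_made == 0 == cand.aa_changes_remaining
                assert all(e.synonymous for e in cand.edits)

    def test_edits_are_exactly_the_sequence_differences(self):
        config = RibosorConfig(stringency=Stringency.S1)
        for seed in range(20):
            cds = random_cds(25, usage_bias=AG_BIAS, seed=seed)
            for cand in design(cds, config):
                diff = {
                    i
                    for i, (a, b) in enumerate(
                        zip(cds.sequence, cand.edited_sequence)
                    )
                    if a != b
                }
                assert diff == {e.position for e in cand.edits}
                for e in cand.edits:
                    assert cds.sequence[e.position] == e.ref
                    assert cand.edited_sequence[e.position] == e.alt

    def test_start_codon_out_of_frame_and_stop_free_when_flagged(self):
        config = RibosorConfig()
        for seed in range(50):
            cds = random_cds(20, usage_bias=AG_BIAS, seed=seed)
            for cand in design(cds, config):
                assert cand.start_nt % 3 == cand.frame != 0
                if cand.frame_stop_free:
                    new_prot = translate(cand.edited_sequence, cand.start_nt)
                    assert "*" not in new_prot

    def test_candidates_sorted_and_deterministic(self):
        cds = random_cds(40, usage_bias=AG_BIAS, seed=11)
        config = RibosorConfig(stringency=Stringency.S1)
        a = design(cds, config)
        b = design(cds, config)
        assert a == b
        starts = [c.start_nt for c in a]
        assert starts == sorted(starts)


class TestApplyOverlap:
    @pytest.mark.parametrize("L", [24, 30, 60])
    @pytest.mark.parametrize("frame", [1, 2])
    def test_pad_length_modular_arithmetic(self, L, frame):
        for s in range(frame, L, 3):
            k = pad_length(L, s)
            assert 0 <= k <= 2
            assert (L + k - s) % 3 == 0

    def test_translation_equals_extension_plus_downstream(self):
        """The overlap frame must read [N-terminal extension] + downstream
        protein, checked against independently translated parts."""
        config = RibosorConfig()
        downstream = CDSRecord("kanR", "ATG" + "AAAGAAGCT" * 4 + "TAA")
        down_protein = translate(downstream.sequence[3:], 0)
        n_built = 0
        for seed in range(300):
            if n_built >= 100:
                break
            cds = random_cds(20, usage_bias=AG_BIAS, seed=seed)
            for cand in design(cds, config):
                if not cand.frame_stop_free:
                    continue
                construct = apply_overlap(cds, cand, downstream)
                L = len(cand.edited_sequence)
                k = len(construct.pad)
                ext = translate(
                    construct.sequence[cand.start_nt : L + k], 0
                )
                assert construct.overlap_protein == ext + down_protein
                assert "*" not in construct.overlap_protein[:-1]
                assert construct.upstream_protein == translate(cds.sequence, 0)
                n_built += 1
        assert n_built >= 20

    def test_zero_length_downstream_rejected(self):
        cds = CDSRecord("toy", PLANTED)
        cand = design(cds, RibosorConfig())[0]
        with pytest.raises(SequenceError):
            # an ATG-only downstream gene has no coding body once its start
            # codon is dropped
            apply_overlap(cds, cand, CDSRecord("empty", "ATGTAA"))
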