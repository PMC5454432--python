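import random

import pytest

from sirvpop.crispr import (
    RepeatSpacerArray,
    Spacer,
    SpacerMatch,
    call_immunity,
    detect_arrays,
    detect_pam,
    iupac_match,
    match_spacer,
    orient_spacers,
)
from sirvpop.io import GenomeRecord, revcomp
from .oracles import spacer_match_oracle

REPEAT = "GATAATCTCTTATAGAATTGAAAGC" + "TTGAA"  # 30 nt


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _build_array(rng, n_repeats=4, spacer_len=35, repeat=REPEAT):
    spacers = [_random_seq(rng, spacer_len) for _ in range(n_repeats - 1)]
    return repeat + "".join(s + repeat for s in spacers), spacers


class TestDetectArrays:
    def test_constructed_array_exact_coordinates(self):
        rng = random.Random(0)
        array, spacers = _build_array(rng)
        left = _random_seq(rng, 500)
        genome = GenomeRecord("h", left + array + _random_seq(rng, 500))
        found = detect_arrays(genome)
        assert len(found) == 1
        arr = found[0]
        assert len(arr.spacers) == 3 and len(arr.repeats) == 4
        assert arr.repeat_consensus == REPEAT
        for k, (s, e) in enumerate(arr.spacers):
            expected_start = len(left) + (k + 1) * len(REPEAT) + k * 35
            assert (s, e) == (expected_start, expected_start + 35)
            assert genome.sequence[s:e] == spacers[k]

    def test_random_sequence_has_no_arrays(self):
        rng = random.Random(1)
        genome = GenomeRecord("h", _random_seq(rng, 10_000))
        assert detect_arrays(genome) == []

    def test_two_repeat_copies_below_threshold(self):
        rng = random.Random(2)
        seq = REPEAT + _random_seq(rng, 35) + REPEAT
        genome = GenomeRecord("h", _random_seq(rng, 200) + seq + _random_seq(rng, 200))
        assert detect_arrays(genome, min_repeats=3) == []

    def test_recall_on_simulated_hosts(self, small_population, small_config):
        """Every planted array is found with exact spacer coordinates."""
        for host in small_population.hosts:
            planted = sorted(
                (f.start, f.end) for f in host.features if f.kind == "spacer"
            )
            found = detect_arrays(host)
            assert len(found) == 1
            assert sorted(found[0].spacers) == planted


class TestOrientSpacers:
    def _array(self, genome, consensus, spacers):
        return RepeatSpacerArray(
            host_id="h",
            start=0,
            end=len(genome.sequence),
            repeat_consensus=consensus,
            repeats=[(0, 1)] * (len(spacers) + 1),
            spacers=spacers,
        )

    def test_forward_when_consensus_matches_reference(self):
        g = GenomeRecord("h", "AACCGGTTAACC")
        arr = self._array(g, "ACGTACGTA", [(2, 6)])
        sps = orient_spacers(arr, g, reference_repeat="ACGTACGTA")
        assert arr.orientation == "forward" and sps[0].sequence == "CCGG"

    def test_reverse_flips_and_reverses_order(self):
        g = GenomeRecord("h", "AACCGGTTAACC")
        ref = "ACGTACGTA"
        arr = self._array(g, revcomp(ref), [(2, 6), (8, 12)])
        sps = orient_spacers(arr, g, reference_repeat=ref)
        assert arr.orientation == "reverse"
        assert [s.sequence for s in sps] == [revcomp("AACC"), revcomp("CCGG")]

    def test_equidistant_consensus_ambiguous(self):
        g = GenomeRecord("h", "AACCGGTTAACC")
        # palindromic-distance case: consensus equally far from ref and rc(ref)
        arr = self._array(g, "ATAT", [(2, 6)])
        sps = orient_spacers(arr, g, reference_repeat="ATAT")
        # ATAT is its own reverse complement: hamming ties at 0
        assert arr.orientation == "ambiguous"
        assert {s.sequence for s in sps} == {"CCGG", revcomp("CCGG")}

    def test_incompatible_reference_length_rejected(self):
        g = GenomeRecord("h", "AACCGGTTAACC")
        arr = self._array(g, "ACGTACGTA", [(2, 6)])
        with pytest.raises(ValueError, match="incompatible"):
            orient_spacers(arr, g, reference_repeat="ACGTACGTAACGTACGTA")


class TestMatchSpacer:
    def test_verbatim_plant_full_identity(self):
        rng = random.Random(3)
        spacer_seq = _random_seq(rng, 39)
        left = _random_seq(rng, 300)
        virus = GenomeRecord("v", left + spacer_seq + _random_seq(rng, 300))
        sp = Spacer("s1", "h1", spacer_seq, "a1", 0)
        matches = match_spacer(sp, virus)
        top = matches[0]
        assert top.full_identity == 1.0
        assert (top.start, top.end, top.strand) == (len(left), len(left) + 39, "+")

    def test_reverse_strand_plant(self):
        rng = random.Random(4)
        spacer_seq = _random_seq(rng, 39)
        left = _random_seq(rng, 200)
        virus = GenomeRecord("v", left + revcomp(spacer_seq) + _random_seq(rng, 200))
        matches = match_spacer(Spacer("s1", "h1", spacer_seq, "a1", 0), virus)
        top = matches[0]
        assert top.full_identity == 1.0 and top.strand == "-"
        assert (top.start, top.end) == (len(left), len(left) + 39)

    def test_threshold_is_strict(self):
        # 40-nt spacer: 22/40 = 0.55 reported; exactly 20/40 = 0.50 is not
        rng = random.Random(5)
        spacer_seq = _random_seq(rng, 40)

        def plant(n_match):
            # first n_match bases kept (includes a >=12 run), rest complemented
            window = spacer_seq[:n_match] + "".join(
                {"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in spacer_seq[n_match:]
            )
            return GenomeRecord("v", "T" * 100 + window + "T" * 100)

        sp = Spacer("s1", "h1", spacer_seq, "a1", 0)
        m55 = [m for m in match_spacer(sp, plant(22)) if m.strand == "+"]
        assert any(m.full_identity == pytest.approx(0.55) for m in m55)
        m50 = [
            m
            for m in match_spacer(sp, plant(20))
            if m.strand == "+" and m.full_identity == pytest.approx(0.50)
        ]
        assert m50 == []

    def test_agrees_with_sliding_window_oracle(self):
        rng = random.Random(6)
        genome_seq = _random_seq(rng, 2000)
        virus = GenomeRecord("v", genome_seq)
        for trial in range(30):
            L = rng.randint(20, 45)
            if trial % 3 == 0:  # plant a mutated copy so some trials match
                start = rng.randint(0, 2000 - L)
                seq = list(genome_seq[start : start + L])
                for _ in range(rng.randint(0, L // 4)):
                    k = rng.randint(0, L - 1)
                    seq[k] = rng.choice("ACGT")
                spacer_seq = "".join(seq)
            else:
                spacer_seq = _random_seq(rng, L)
            got = sorted(
                (m.start, m.strand, m.full_identity)
                for m in match_spacer(Spacer("s", "h", spacer_seq, "a", 0), virus)
            )
            want = spacer_match_oracle(spacer_seq, genome_seq)
            assert got == pytest.approx(want), (trial, spacer_seq)

    def test_strand_symmetry_under_genome_revcomp(self):
        rng = random.Random(7)
        genome_seq = _random_seq(rng, 1500)
        start = 700
        spacer_seq = genome_seq[start : start + 39]
        sp = Spacer("s", "h", spacer_seq, "a", 0)
        fwd = match_spacer(sp, GenomeRecord("v", genome_seq))
        rev = match_spacer(sp, GenomeRecord("v", revcomp(genome_seq)))
        flipped = sorted(
            (len(genome_seq) - m.end, {"+": "-", "-": "+"}[m.strand], m.full_identity)
            for m in rev
        )
        assert flipped == sorted((m.start, m.strand, m.full_identity) for m in fwd)

    def test_half5_and_seed_identities(self):
        spacer_seq = "A" * 20 + "C" * 19  # 39 nt
        window = "A" * 20 + "T" * 19  # 5' half matches fully, 3' half not
        virus = GenomeRecord("v", "G" * 50 + window + "G" * 50)
        m = match_spacer(Spacer("s", "h", spacer_seq, "a", 0), virus)[0]
        assert m.full_identity == pytest.approx(20 / 39)
        assert m.half5_identity == 1.0
        assert m.seed_identity == 1.0  # seed is 5'/PAM-proximal by default

    def test_spacer_longer_than_genome(self):
        assert match_spacer(Spacer("s", "h", "A" * 50, "a", 0), GenomeRecord("v", "ACGT")) == []


class TestPam:
    def _match(self, start, end, strand):
        return SpacerMatch("s", "v", start, end, strand, 1.0)

    def test_iupac(self):
        assert iupac_match("CCA", "CCN")
        assert not iupac_match("TTG", "CCN")
        assert not iupac_match("CNA", "CCN")  # N in genome never matches

    def test_plus_strand_upstream(self):
        virus = GenomeRecord("v", "TTCCA" + "ACGT" * 5)
        m = detect_pam(self._match(5, 15, "+"), virus, motif="CCN")
        assert m.pam_present and m.pam_sequence == "CCA"

    def test_plus_strand_negative(self):
        virus = GenomeRecord("v", "TTTTG" + "ACGT" * 5)
        m = detect_pam(self._match(5, 15, "+"), virus, motif="CCN")
        assert not m.pam_present and m.pam_sequence == "TTG"

    def test_reverse_strand_reads_revcomp_side(self):
        # protospacer on '-': its 5' flank is 3' in forward coordinates.
        # forward seq: [10 nt protospacer][TGG]; revcomp(TGG) = CCA -> PAM
        virus = GenomeRecord("v", "ACGTACGTAC" + "TGG" + "AAAA")
        m = detect_pam(self._match(0, 10, "-"), virus, motif="CCN")
        assert m.pam_present and m.pam_sequence == "CCA"

    def test_out_of_bounds_no_pam(self):
        virus = GenomeRecord("v", "ACGTACGTAC")
        m = detect_pam(self._match(0, 10, "+"), virus, motif="CCN")
        assert not m.pam_present and m.pam_sequence == ""


class TestCallImmunity:
    def _match(self, identity, pam):
        return SpacerMatch("s1", "v1", 0, 39, "+", identity, pam_present=pam)

    def test_perfect_match_no_clearing_concordant(self):
        call = call_immunity(
            "h", "v", [self._match(1.0, True)], observed={"high": 0, "medium": 0, "low": 0}
        )
        assert call.predicted == "immune" and call.discordance == "concordant"

    def test_no_match_full_clearing_concordant(self):
        call = call_immunity("h", "v", [], observed={"high": 3, "medium": 3, "low": 3})
        assert call.predicted == "susceptible" and call.discordance == "concordant"

    def test_qualifying_match_but_low_titer_clearing_is_anti_crispr(self):
        call = call_immunity(
            "h", "v", [self._match(0.9, True)], observed={"high": 3, "medium": 2, "low": 1}
        )
        assert call.discordance == "anti-crispr-candidate"

    def test_no_match_no_clearing_is_resistance_candidate(self):
        call = call_immunity("h", "v", [], observed={"high": 0, "medium": 0, "low": 0})
        assert call.discordance == "resistance-candidate"

    def test_pam_required_by_default(self):
        call = call_immunity("h", "v", [self._match(0.9, False)])
        assert call.predicted == "susceptible" and call.n_matches_no_pam == 1
        relaxed = call_immunity("h", "v", [self._match(0.9, False)], require_pam=False)
        assert relaxed.predicted == "immune"

    def test_threshold_strictness(self):
        call = call_immunity("h", "v", [self._match(0.5, True)])
        assert call.predicted == "susceptible"

    def test_no_observed_data_prediction_only(self):
        call = call_immunity("h", "v", [self._match(1.0, True)])
        assert call.predicted == "immune" and call.discordance == ""


class TestSyntheticRecovery:
    def test_local_zero_divergence_perfect_matches_and_silent_decoys(
        self, no_evolution_config
    ):
        import dataclasses

        from sirvpop.simulate import simulate_population

        cfg = dataclasses.replace(no_evolution_config, seed=5)
        pop = simulate_population(cfg)
        viruses = {v.id: v for v in pop.viruses}
        for st in pop.truth.spacers:
            sp = Spacer(st.spacer_id, st.host_id, st.sequence, "t", 0)
            if st.decoy:
                for v in viruses.values():
                    assert match_spacer(sp, v) == []
            elif st.n_mutations == 0:
                matches = match_spacer(sp, viruses[st.source_virus])
                assert any(
                    m.full_identity == 1.0
                    and (m.start, m.end, m.strand) == (st.start, st.end, st.strand)
                    for m in matches
                )

    def test_identity_recovery_tracks_divergence(self, small_config):
        """Mean (1 - identity) at the source locus is within 3 binomial SD of q."""
        import dataclasses

        import numpy as np

        from sirvpop.simulate import simulate_population

        q = 0.08
        cfg = dataclasses.replace(
            small_config,
            seed=9,
            spacer_divergence_local=q,
            spacer_divergence_foreign=q,
            decoy_fraction=0.0,
        )
        pop = simulate_population(cfg)
        viruses = {v.id: v for v in pop.viruses}
        obs = []
        for st in pop.truth.spacers:
            sp = Spacer(st.spacer_id, st.host_id, st.sequence, "t", 0)
            # word_size off: isolate identity estimation from seed finding
            matches = match_spacer(sp, viruses[st.source_virus], word_size=0)
            at_truth = [m for m in matches if m.start == st.start and m.strand == st.strand]
            if at_truth:
                obs.append(1.0 - at_truth[0].full_identity)
        n = len(obs) * cfg.spacer_length
        sd = (q * (1 - q) / n) ** 0.5
        assert len(obs) > 30
        assert abs(np.mean(obs) - q) < 3 * sd + 1e-9
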