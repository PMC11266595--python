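import itertools
import math

import pytest

from asorf.composition import GCModel, STOP_CODONS
from asorf.frame_model import Frame
from asorf.mutation_model import (
    GENETIC_CODE,
    MutationSpec,
    SIMILAR_AA,
    SelectionLevel,
    YEAST_BIAS,
    YEAST_RATE,
    event_probabilities,
    gain_crossover_length,
    orf_gain_probability,
    orf_loss_probability,
    sense_mutation_tolerated,
    substitution_class,
    substitution_probability,
)

SPEC = MutationSpec()


class TestSubstitutionProbability:
    def test_bias_table_values(self):
        assert substitution_probability(SPEC, "A", "G") == pytest.approx(YEAST_RATE * 0.144)
        assert substitution_probability(SPEC, "G", "A") == pytest.approx(YEAST_RATE * 0.349)

    def test_strand_symmetry(self):
        for a, b in itertools.permutations("ACGT", 2):
            comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
            assert substitution_class(a, b) == substitution_class(comp[a], comp[b])
        assert substitution_probability(SPEC, "T", "C") == substitution_probability(SPEC, "A", "G")

    def test_identical_bases_error(self):
        with pytest.raises(ValueError):
            substitution_probability(SPEC, "A", "A")

    def test_bias_weights_validated(self):
        with pytest.raises(ValueError):
            MutationSpec(bias={"A:T->T:A": 1.0})


class TestSelectionFilter:
    def test_similar_substitution_tolerated_only_when_weak(self):
        # GAT (Asp) -> GAA (Glu): chemically similar
        assert sense_mutation_tolerated("GAT", "GAA", SelectionLevel.WEAK)
        assert not sense_mutation_tolerated("GAT", "GAA", SelectionLevel.STRONG)
        assert sense_mutation_tolerated("GAT", "GAA", SelectionLevel.NONE)

    def test_nonsense_never_tolerated(self):
        for level in SelectionLevel:
            assert not sense_mutation_tolerated("TAT", "TAA", level)

    def test_synonymous_always_tolerated(self):
        for level in SelectionLevel:
            assert sense_mutation_tolerated("GGA", "GGT", level)

    def test_stop_source_is_error(self):
        with pytest.raises(ValueError):
            sense_mutation_tolerated("TAA", "TAT", SelectionLevel.NONE)

    def test_multi_site_change_is_error(self):
        with pytest.raises(ValueError):
            sense_mutation_tolerated("AAA", "TTA", SelectionLevel.NONE)

    def test_similarity_sets_are_symmetric(self):
        for a, partners in SIMILAR_AA.items():
            for b in partners:
                assert a in SIMILAR_AA[b]
        for aa in "CGNQ":
            assert not SIMILAR_AA[aa]


class TestEventProbabilities:
    def test_no_mutation_no_events(self):
        ev = event_probabilities(GCModel(0.5), MutationSpec(u=0.0), Frame.AS1)
        assert ev.p_stop_gain == 0.0 and ev.p_stop_loss == 0.0
        assert ev.p_atg_gain == 0.0 and ev.p_atg_loss == 0.0
        assert ev.p_stop_stay == ev.p_stop and ev.p_atg_stay == ev.p_atg

    def test_intergenic_stop_gain_matches_brute_force(self):
        # independent oracle: plain loops over the 61x9 codon neighborhoods
        g = 0.5
        w, s = (1 - g) / 2, g / 2
        p = {"A": w, "T": w, "G": s, "C": s}
        expected = 0.0
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            if codon in STOP_CODONS:
                continue
            mass = math.prod(p[b] for b in codon)
            for i, nb in itertools.product(range(3), "ACGT"):
                if nb == codon[i]:
                    continue
                if codon[:i] + nb + codon[i + 1:] in STOP_CODONS:
                    expected += mass * substitution_probability(SPEC, codon[i], nb)
        ev = event_probabilities(GCModel(g), SPEC, Frame.INTERGENIC)
        assert ev.p_stop_gain == pytest.approx(expected, rel=1e-12)
        assert ev.p_stop_gain > 0

    def test_selection_reduces_stop_gain(self):
        evs = {lv: event_probabilities(GCModel(0.5), SPEC, Frame.AS1, lv)
               for lv in SelectionLevel}
        assert evs[SelectionLevel.STRONG].p_stop_gain < evs[SelectionLevel.WEAK].p_stop_gain
        assert evs[SelectionLevel.WEAK].p_stop_gain < evs[SelectionLevel.NONE].p_stop_gain

    def test_events_scale_linearly_with_rate(self):
        ev1 = event_probabilities(GCModel(0.4), SPEC, Frame.AS1)
        ev2 = event_probabilities(GCModel(0.4), SPEC.scaled(2.0), Frame.AS1)
        assert ev2.p_stop_gain == pytest.approx(2 * ev1.p_stop_gain, rel=1e-12)
        assert ev2.p_stop_loss == pytest.approx(2 * ev1.p_stop_loss, rel=1e-12)


class TestGainLoss:
    def test_zero_rate(self):
        ev = event_probabilities(GCModel(0.5), MutationSpec(u=0.0), Frame.INTERGENIC)
        assert orf_gain_probability(ev, 50) == 0.0
        assert orf_loss_probability(ev, 50) == 0.0

    def test_short_orf_error(self):
        ev = event_probabilities(GCModel(0.5), SPEC, Frame.INTERGENIC)
        with pytest.raises(ValueError):
            orf_gain_probability(ev, 2)
        with pytest.raises(ValueError):
            orf_loss_probability(ev, 2)

    def test_overlap_protects_against_loss(self):
        ev_as = event_probabilities(GCModel(0.5), SPEC, Frame.AS1, SelectionLevel.STRONG)
        ev_ig = event_probabilities(GCModel(0.5), SPEC, Frame.INTERGENIC)
        assert orf_loss_probability(ev_as, 100) < orf_loss_probability(ev_ig, 100)

    def test_loss_monotone_in_length(self):
        ev = event_probabilities(GCModel(0.5), SPEC, Frame.INTERGENIC)
        losses = [orf_loss_probability(ev, k) for k in range(3, 300)]
        assert all(a < b for a, b in zip(losses, losses[1:]))

    def test_gain_decreasing_in_length(self):
        ev = event_probabilities(GCModel(0.5), SPEC, Frame.INTERGENIC)
        gains = [orf_gain_probability(ev, k) for k in range(10, 300)]
        assert all(a > b for a, b in zip(gains, gains[1:]))

    def test_selection_monotonicity_of_gain(self):
        for frame in (Frame.AS1, Frame.AS2):
            gains = []
            for lv in (SelectionLevel.NONE, SelectionLevel.WEAK, SelectionLevel.STRONG):
                ev = event_probabilities(GCModel(0.45), SPEC, frame, lv)
                gains.append(orf_gain_probability(ev, 80))
            assert gains[0] > gains[1] > gains[2]

    def test_internal_stop_term_switch(self):
        ev = event_probabilities(GCModel(0.4), SPEC, Frame.INTERGENIC)
        joint = orf_gain_probability(ev, 50, internal_stop_term="joint")
        literal = orf_gain_probability(ev, 50, internal_stop_term="literal")
        # the literal reading drops the existence factor of the internal
        # stop, so it must exceed the joint form
        assert literal > joint
        with pytest.raises(ValueError):
            orf_gain_probability(ev, 50, internal_stop_term="bogus")


class TestGainCrossover:
    def test_crossover_grows_with_gc(self):
        ks = [gain_crossover_length(GCModel(g), SPEC, Frame.AS1) for g in (0.3, 0.4, 0.5)]
        assert all(isinstance(k, int) for k in ks)
        assert ks == sorted(ks)

    def test_crossover_grows_with_selection_strength(self):
        # frozen values from the enumeration at 60% GC: the crossing moves
        # from 46 (no selection) to 108 (similarity-tolerant) to 124
        # (synonymous-only)
        out = [gain_crossover_length(GCModel(0.6), SPEC, Frame.AS1, lv)
               for lv in (SelectionLevel.NONE, SelectionLevel.WEAK, SelectionLevel.STRONG)]
        assert out == [46, 108, 124]

    def test_rate_invariance(self):
        a = gain_crossover_length(GCModel(0.4), SPEC, Frame.AS1)
        b = gain_crossover_length(GCModel(0.4), SPEC.scaled(10.0), Frame.AS1)
        assert a == b
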