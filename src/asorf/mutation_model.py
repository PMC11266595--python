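"""Transition probabilities: gain and loss of ORF features under mutation.

A locus gains ORF status when two of its three defining features (start
codon, terminal stop, stop-free interior) are present and the third arises
by a single-nucleotide mutation; it loses ORF status when any feature is
destroyed.  Per-feature event probabilities are obtained by exhaustive
enumeration of the codon (intergenic, frame 0) or dicodon (frames 1 and 2)
state space and its single-nucleotide mutation neighborhood, weighting
each state by the composition model and each mutation by the bias-weighted
rate m(a->b) = u * bias[class(a->b)].

Purifying selection on the sense ORF limits which mutations are available
to the antisense reading.  Three levels are modelled:

* ``none``   -- any sense mutation except a nonsense mutation (stop gain);
* ``weak``   -- synonymous mutations, or substitutions to a chemically
  similar amino acid (MHC-binding-covariance similarity sets);
* ``strong`` -- synonymous mutations only.

The per-generation ORF gain and loss probabilities for a locus of k codons
are then

    P_gain(k) = P_ATG-gain * P_stop-stay * B**(k-2)
              + P_ATG-stay * P_stop-gain * B**(k-2)
              + P_ATG-stay * P_stop-stay * [P_stop *] P_stop-loss
                * (k-2) * B**(k-3)          with B = 1 - P_stop - P_stop-gain

    P_loss(k) = P_ATG-loss + P_stop-loss + (k-2) * P_stop-gain / (1 - P_stop)

The bracketed ``P_stop`` factor in the third gain term (the probability
that the internal stop to be lost exists at all) is controlled by the
``internal_stop_term`` switch: ``"joint"`` (default) includes it,
``"literal"`` omits it.  The joint form is the physically consistent
first-order term and is the one validated by the forward-mutation
simulation oracle.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

from .composition import (
    ALL_DICODONS,
    ALL_TRIMERS,
    BASES,
    GCModel,
    OligomerModel,
    STOP_CODONS,
    oligomer_probability,
)
from .frame_model import (
    FRAME0_SENSE_CODONS,
    Frame,
    enumerate_stop_dicodons,
    start_probability,
)

# ---------------------------------------------------------------------------
# mutation rates

#: Substitution bias for S. cerevisiae, per base-pair substitution class.
#: Classes are strand-symmetric: an A->G mutation on one strand is a T->C
#: mutation on the other, so both draw the A:T->G:C weight.
YEAST_BIAS: Dict[str, float] = {
    "A:T->T:A": 0.063,
    "A:T->G:C": 0.144,
    "A:T->C:G": 0.110,
    "G:C->A:T": 0.349,
    "G:C->T:A": 0.182,
    "G:C->C:G": 0.152,
}

#: Per-nucleotide per-generation mutation rate for diploid S. cerevisiae.
YEAST_RATE = 1.7e-10

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def substitution_class(from_base: str, to_base: str) -> str:
    """Strand-symmetric substitution class of a base change."""
    if from_base == to_base:
        raise ValueError("identical bases do not define a substitution")
    if from_base in "AT":
        a, b = ("A", to_base) if from_base == "A" else ("A", _COMPLEMENT[to_base])
        return f"A:T->{b}:{_COMPLEMENT[b]}"
    a, b = ("G", to_base) if from_base == "G" else ("G", _COMPLEMENT[to_base])
    return f"G:C->{b}:{_COMPLEMENT[b]}"


@dataclass(frozen=True)
class MutationSpec:
    """Per-site mutation rate ``u`` and the six-class bias weights."""

    u: float = YEAST_RATE
    bias: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bias is None:
            object.__setattr__(self, "bias", dict(YEAST_BIAS))
        if self.u < 0:
            raise ValueError("mutation rate must be nonnegative")
        if set(self.bias) != set(YEAST_BIAS):
            raise ValueError(f"bias table must have classes {sorted(YEAST_BIAS)}")
        total = sum(self.bias.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"bias weights sum to {total}, not 1")

    def scaled(self, factor: float) -> "MutationSpec":
        return MutationSpec(self.u * factor, dict(self.bias))


def substitution_probability(spec: MutationSpec, from_base: str, to_base: str) -> float:
    """Per-generation probability of a specific base substitution:
    u times the weight of its strand-symmetric class."""
    return spec.u * spec.bias[substitution_class(from_base, to_base)]


# ---------------------------------------------------------------------------
# selection

GENETIC_CODE: Dict[str, str] = {}
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _c in enumerate(itertools.product("TCAG", repeat=3)):
    GENETIC_CODE["".join(_c)] = _AA_ORDER[_i]

#: Chemically similar amino acids (pairs with MHC-binding covariance > 0.05).
SIMILAR_AA: Dict[str, frozenset] = {
    "A": frozenset("PTV"), "C": frozenset(), "D": frozenset("E"), "E": frozenset("D"),
    "F": frozenset("IWY"), "G": frozenset(), "H": frozenset("KR"), "I": frozenset("FLMV"),
    "K": frozenset("HR"), "L": frozenset("IM"), "M": frozenset("IL"), "N": frozenset(),
    "P": frozenset("A"), "Q": frozenset(), "R": frozenset("HK"), "S": frozenset("T"),
    "T": frozenset("AS"), "V": frozenset("AI"), "W": frozenset("FY"), "Y": frozenset("FW"),
}


class SelectionLevel(enum.Enum):
    NONE = "none"
    WEAK = "weak"
    STRONG = "strong"


def sense_mutation_tolerated(codon_from: str, codon_to: str, level: SelectionLevel) -> bool:
    """Whether purifying selection on the sense ORF tolerates a single-site
    codon change.

    none: anything but a nonsense mutation; weak: synonymous or chemically
    similar substitution; strong: synonymous only.
    """
    if codon_from in STOP_CODONS:
        raise ValueError("sense codon under selection cannot be a stop codon")
    diffs = sum(a != b for a, b in zip(codon_from, codon_to))
    if diffs != 1:
        raise ValueError("codons must differ at exactly one position")
    if level is SelectionLevel.NONE:
        return codon_to not in STOP_CODONS
    if codon_to in STOP_CODONS:
        return False
    aa_from, aa_to = GENETIC_CODE[codon_from], GENETIC_CODE[codon_to]
    if aa_from == aa_to:
        return True
    if level is SelectionLevel.STRONG:
        return False
    return aa_to in SIMILAR_AA[aa_from]


def _tolerated_in_state(state_from: str, state_to: str, pos: int, level: SelectionLevel) -> bool:
    """Tolerance of a single-site mutation within a codon or dicodon state,
    judged on the sense codon containing the mutated position."""
    ci = (pos // 3) * 3
    return sense_mutation_tolerated(state_from[ci:ci + 3], state_to[ci:ci + 3], level)


# ---------------------------------------------------------------------------
# event probabilities

@dataclass(frozen=True)
class FrameEventProbabilities:
    """Per-feature existence and one-generation transition probabilities.

    ``p_stop_gain`` is joint (state lacks the feature and gains it);
    ``p_stop_loss`` is conditional on the feature existing.  Same for ATG.
    """

    frame: Frame
    level: Optional[SelectionLevel]
    p_stop: float
    p_stop_gain: float
    p_stop_loss: float
    p_atg: float
    p_atg_gain: float
    p_atg_loss: float

    @property
    def p_stop_stay(self) -> float:
        return self.p_stop * (1.0 - self.p_stop_loss)

    @property
    def p_atg_stay(self) -> float:
        return self.p_atg * (1.0 - self.p_atg_loss)


def _mutations(state: str) -> Iterator[Tuple[int, str, str]]:
    for i, b in enumerate(state):
        for nb in BASES:
            if nb != b:
                yield i, nb, state[:i] + nb + state[i + 1:]


def _state_measure(model, frame: Frame) -> Tuple[Iterable[str], "callable"]:
    """State space and probability function for the stop-codon context."""
    if frame in (Frame.AS1, Frame.AS2):
        if isinstance(model, OligomerModel):
            tab = model.table(6, True)
            return ALL_DICODONS, lambda s: tab.get(s, 0.0)
        return ALL_DICODONS, lambda s: model.probability(s)
    coding = frame is Frame.AS0
    if isinstance(model, OligomerModel):
        tab = model.table(3, coding)
        return ALL_TRIMERS, lambda s: tab.get(s, 0.0)
    return ALL_TRIMERS, lambda s: model.probability(s)


def _stop_set(frame: Frame) -> frozenset:
    if frame is Frame.INTERGENIC:
        return STOP_CODONS
    if frame is Frame.AS0:
        return FRAME0_SENSE_CODONS
    return enumerate_stop_dicodons(frame).overlapping_allowed


def _stop_events(model, spec: MutationSpec, frame: Frame,
                 level: SelectionLevel) -> Tuple[float, float, float]:
    """(P_stop, P_stop-gain, P_stop-loss) by neighborhood enumeration.

    Gain sums over source states that carry no antisense-frame stop and --
    for antisense frames -- no sense stop codon (sense ORF interiors are
    stop-free), weighting tolerated single mutations into the allowed stop
    set.  Loss is conditional on membership of the stop set.
    """
    states, prob = _state_measure(model, frame)
    stop_set = _stop_set(frame)
    antisense = frame is not Frame.INTERGENIC

    def reading_is_stop(s: str) -> bool:
        if frame in (Frame.AS1, Frame.AS2):
            from .frame_model import antisense_codon_of_dicodon
            return antisense_codon_of_dicodon(s, frame) in STOP_CODONS
        return s in stop_set

    p_stop = sum(prob(s) for s in stop_set)
    gain = 0.0
    for s in states:
        if reading_is_stop(s):
            continue
        if antisense and any(s[i:i + 3] in STOP_CODONS for i in range(0, len(s), 3)):
            continue
        mass = prob(s)
        if mass == 0.0:
            continue
        acc = 0.0
        for i, nb, s2 in _mutations(s):
            if s2 not in stop_set:
                continue
            if antisense and not _tolerated_in_state(s, s2, i, level):
                continue
            acc += substitution_probability(spec, s[i], nb)
        gain += mass * acc

    loss = 0.0
    if p_stop > 0.0:
        for s in stop_set:
            mass = prob(s)
            if mass == 0.0:
                continue
            acc = 0.0
            for i, nb, s2 in _mutations(s):
                if s2 in stop_set:
                    continue
                if antisense and not _tolerated_in_state(s, s2, i, level):
                    continue
                acc += substitution_probability(spec, s[i], nb)
            loss += (mass / p_stop) * acc
    return p_stop, gain, loss


def _atg_events(model, spec: MutationSpec, frame: Frame) -> Tuple[float, float, float]:
    """(P_ATG, P_ATG-gain, P_ATG-loss) on the plain 3-mer measure.

    The antisense overlap's effect on the start codon is ignored (the
    composition measure is the codon table for antisense frames under an
    OligomerModel, the trimer table for intergenic loci, and the product
    measure under a GCModel); no selection filter applies.
    """
    p_atg = start_probability(model)
    if isinstance(model, OligomerModel):
        coding = frame is not Frame.INTERGENIC
        try:
            tab = model.table(3, coding)
        except ValueError:
            tab = model.table(3, not coding)
        prob = lambda s: tab.get(s, 0.0)
    else:
        prob = model.probability
    gain = 0.0
    for i, nb, _s2 in _mutations("ATG"):
        # source is the ATG neighbor obtained by reverting the mutation
        src = "ATG"[:i] + nb + "ATG"[i + 1:]
        gain += prob(src) * substitution_probability(spec, nb, "ATG"[i])
    loss = sum(substitution_probability(spec, "ATG"[i], nb) for i, nb, _ in _mutations("ATG"))
    return p_atg, gain, loss


def event_probabilities(model, spec: MutationSpec, frame: Frame,
                        level: SelectionLevel = SelectionLevel.NONE) -> FrameEventProbabilities:
    """All Table-style per-feature event probabilities for a frame context.

    For antisense frames the selection level applies to the sense reading;
    for intergenic loci it is ignored.
    """
    lvl = level if frame is not Frame.INTERGENIC else None
    p_stop, sg, sl = _stop_events(model, spec, frame, level)
    p_atg, ag, al = _atg_events(model, spec, frame)
    return FrameEventProbabilities(
        frame=frame, level=lvl,
        p_stop=p_stop, p_stop_gain=sg, p_stop_loss=sl,
        p_atg=p_atg, p_atg_gain=ag, p_atg_loss=al,
    )


# ---------------------------------------------------------------------------
# ORF-level gain and loss

def orf_gain_probability(events: FrameEventProbabilities, k: int,
                         internal_stop_term: str = "joint") -> float:
    """Per-generation probability that a k-codon locus gains ORF status.

    Three single-feature paths: missing start gained; missing terminal stop
    gained; single internal stop lost.  ``internal_stop_term`` selects the
    joint (default) or literal form of the third path (module docstring).
    """
    if k < 3:
        raise ValueError(f"ORF length must be at least 3 codons, got {k}")
    if internal_stop_term not in ("joint", "literal"):
        raise ValueError("internal_stop_term must be 'joint' or 'literal'")
    e = events
    base = 1.0 - e.p_stop - e.p_stop_gain
    term1 = e.p_atg_gain * e.p_stop_stay * base ** (k - 2)
    term2 = e.p_atg_stay * e.p_stop_gain * base ** (k - 2)
    internal = e.p_stop_loss if internal_stop_term == "literal" else e.p_stop * e.p_stop_loss
    term3 = e.p_atg_stay * e.p_stop_stay * internal * (k - 2) * base ** (k - 3)
    return term1 + term2 + term3


def orf_loss_probability(events: FrameEventProbabilities, k: int) -> float:
    """Per-generation probability that a k-codon ORF loses ORF status:
    start lost, terminal stop lost, or an internal stop gained."""
    if k < 3:
        raise ValueError(f"ORF length must be at least 3 codons, got {k}")
    e = events
    return e.p_atg_loss + e.p_stop_loss + (k - 2) * e.p_stop_gain / (1.0 - e.p_stop)


def gain_crossover_length(model, spec: MutationSpec, frame: Frame,
                          level: SelectionLevel = SelectionLevel.NONE,
                          k_max: int = 400,
                          internal_stop_term: str = "joint") -> Optional[int]:
    """Length at which the antisense gain curve crosses the intergenic one.

    The two gain curves are evaluated on the integer grid k = 3..k_max and
    the zero of the log-ratio is located by linear interpolation between
    grid points; the integer part of that crossing is returned (ORFs
    strictly longer are more likely to emerge antisense than intergenic).
    Returns None if the antisense curve never overtakes within range.
    """
    ev_as = event_probabilities(model, spec, frame, level)
    ev_ig = event_probabilities(model, spec, Frame.INTERGENIC, level)
    prev_ratio = None
    for k in range(3, k_max + 1):
        g_ig = orf_gain_probability(ev_ig, k, internal_stop_term)
        if g_ig == 0.0:
            return None
        ratio = orf_gain_probability(ev_as, k, internal_stop_term) / g_ig
        if ratio > 1.0:
            if prev_ratio is None:
                return k
            frac = (1.0 - prev_ratio) / (ratio - prev_ratio)
            return int(k - 1 + frac)
        prev_ratio = ratio
    return None
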