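"""Stationary (existence) probabilities of ORFs by antisense reading frame.

An ORF antisense to a coding ORF can overlap it in three reading frames.
In frame 0 the antisense codons pair exactly with sense codons; in frames 1
and 2 each antisense codon is shifted one or two nucleotides toward the
sense 5' end, so its sequence is determined by two consecutive sense codons
(a *dicodon*).  A stop codon in the antisense reading therefore constrains
the overlapped dicodon, and because the sense ORF interior is stop-free,
some of those dicodons are forbidden:

* frame 1: 192 dicodons overlap an antisense stop, of which 64 contain a
  sense stop codon, leaving 128 allowed;
* frame 2: all 192 overlapping dicodons are free of sense stops, so the
  antisense stop probability is unconstrained, exactly as in frame 0 and
  in intergenic DNA.

The probability that a locus of k codons (start and terminal stop
included) is an ORF is

    P_ORF(k) = P_ATG * P_stop * (1 - P_stop)**(k - 2)

with the frame-appropriate stop probability.  Under a ``GCModel`` the
frame-specific stop probability is the *unnormalized* product-measure mass
of the allowed stop trimers/dicodons, which makes frames 0 and 2 exactly
equal to intergenic DNA for every length and GC content.  Under an
``OligomerModel`` the dicodon table is stop-free by construction, so the
empirical mode is intrinsically conditioned on the sense constraint.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from typing import FrozenSet, Optional

from .composition import (
    ALL_DICODONS,
    GCModel,
    OligomerModel,
    STOP_CODONS,
    oligomer_probability,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]


#: sense codons whose reverse complement is a stop codon (frame-0 overlap)
FRAME0_SENSE_CODONS = frozenset(revcomp(s) for s in STOP_CODONS)  # TTA, CTA, TCA


class Frame(enum.Enum):
    """Reading-frame context of an ORF locus.

    Antisense frame d is defined on sense-strand coordinates: an antisense
    codon pairing with sense positions {x, x+1, x+2} has d = (s - x) mod 3,
    where s is the start coordinate of any sense codon.
    """

    INTERGENIC = "intergenic"
    AS0 = "as0"
    AS1 = "as1"
    AS2 = "as2"

    @property
    def is_antisense(self) -> bool:
        return self is not Frame.INTERGENIC


def antisense_codon_of_dicodon(dicodon: str, frame: Frame) -> str:
    """The antisense codon read from a sense dicodon at frame 1 or 2.

    Within the 6-mer (two consecutive sense codons), the frame-1 antisense
    codon is the reverse complement of positions 2..4 (0-based) and the
    frame-2 codon that of positions 1..3.
    """
    if frame is Frame.AS1:
        return revcomp(dicodon[2:5])
    if frame is Frame.AS2:
        return revcomp(dicodon[1:4])
    raise ValueError(f"dicodon reading undefined for {frame}")


@dataclass(frozen=True)
class DicodonSets:
    """Dicodons overlapping an antisense stop codon in a given frame."""

    frame: Frame
    overlapping_all: FrozenSet[str]
    overlapping_allowed: FrozenSet[str]


@lru_cache(maxsize=None)
def enumerate_stop_dicodons(frame: Frame) -> DicodonSets:
    """Exhaustively enumerate the 6-mers whose antisense reading at
    ``frame`` is a stop codon, and the subset free of sense stop codons."""
    if frame not in (Frame.AS1, Frame.AS2):
        raise ValueError("dicodon enumeration applies to frames as1 and as2 only")
    full = frozenset(
        d for d in ALL_DICODONS if antisense_codon_of_dicodon(d, frame) in STOP_CODONS
    )
    allowed = frozenset(
        d for d in full if d[:3] not in STOP_CODONS and d[3:] not in STOP_CODONS
    )
    return DicodonSets(frame, full, allowed)


def stop_probability(model, frame: Frame) -> float:
    """Per-locus probability of a stop codon in the given frame context.

    intergenic: mass of TAA/TAG/TGA under the trimer measure.
    as0:        mass of the sense codons TTA/CTA/TCA under the codon measure.
    as1/as2:    mass of the allowed stop-overlapping dicodons.

    Under GCModel these are unnormalized product-measure masses (see module
    docstring); under OligomerModel the codon/dicodon tables are stop-free
    by construction, so the empirical mode is already conditioned.
    """
    if frame is Frame.INTERGENIC:
        return sum(oligomer_probability(model, s, coding=False) for s in STOP_CODONS)
    if frame is Frame.AS0:
        return sum(oligomer_probability(model, c, coding=True) for c in FRAME0_SENSE_CODONS)
    allowed = enumerate_stop_dicodons(frame).overlapping_allowed
    return sum(oligomer_probability(model, d) for d in allowed)


def start_probability(model) -> float:
    """Probability of an ATG start codon, identical for all frames.

    The effect of the antisense overlap on the start codon is ignored
    (it is small); under an OligomerModel the codon table is preferred,
    falling back to the trimer table.
    """
    if isinstance(model, GCModel):
        return model.probability("ATG")
    if isinstance(model, OligomerModel):
        tab = model.codon_freqs if model.codon_freqs is not None else model.trimer_freqs
        if tab is None:
            raise ValueError("model has no 3-mer table for the start codon")
        return tab.get("ATG", 0.0)
    raise TypeError(f"unsupported model {model!r}")


def orf_probability(model, frame: Frame, k: int) -> float:
    """Stationary probability that a locus of k codons is an ORF.

    P_ORF(k) = P_ATG * P_stop * (1 - P_stop)**(k-2); k counts codons
    including the start and the terminal stop (length in nt = 3k).
    """
    if k < 3:
        raise ValueError(f"ORF length must be at least 3 codons, got {k}")
    p_stop = stop_probability(model, frame)
    return start_probability(model) * p_stop * (1.0 - p_stop) ** (k - 2)


def crossover_length(model, frame: Frame, k_max: int = 300) -> Optional[int]:
    """Smallest k in [3, k_max] with P_ORF(frame, k) > P_ORF(intergenic, k),
    or None if the antisense frame never overtakes within range."""
    p_as = stop_probability(model, frame)
    p_ig = stop_probability(model, Frame.INTERGENIC)
    for k in range(3, k_max + 1):
        if p_as * (1.0 - p_as) ** (k - 2) > p_ig * (1.0 - p_ig) ** (k - 2):
            return k
    return None
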