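"""Nucleotide composition models.

All codon, dicodon and trimer probabilities used by the ORF existence and
gain/loss calculations derive from one of two composition models:

``GCModel``
    A uniform, independent-site model parameterised by GC content *g*:
    ``p(G) = p(C) = g/2`` and ``p(A) = p(T) = (1-g)/2``.  The probability of
    an oligomer is the product of its per-base probabilities.

``OligomerModel``
    Empirical frequency tables estimated from sequence data: sliding-window
    trimer frequencies from intergenic DNA, and non-overlapping codon
    (every third position) and dicodon (every sixth position) frequencies
    from annotated coding ORFs.  Because annotated ORF interiors contain no
    stop codons, the codon and dicodon tables carry zero mass on any codon
    or 6-mer containing a stop codon.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
ALL_TRIMERS = tuple("".join(t) for t in itertools.product(BASES, repeat=3))
ALL_DICODONS = tuple("".join(t) for t in itertools.product(BASES, repeat=6))

_SUM_TOL = 1e-9


def _check_table(freqs: Mapping[str, float], length: int, stop_free: bool, name: str) -> Dict[str, float]:
    total = sum(freqs.values())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} frequencies sum to {total!r}, not 1")
    for oligo, f in freqs.items():
        if len(oligo) != length or any(b not in BASES for b in oligo):
            raise ValueError(f"invalid {name} key {oligo!r}")
        if f < 0:
            raise ValueError(f"negative frequency for {oligo!r}")
        if stop_free and f > 0 and _contains_stop_codon(oligo):
            raise ValueError(f"{name} table has nonzero mass on stop-containing {oligo!r}")
    return dict(freqs)


def _contains_stop_codon(oligo: str) -> bool:
    return any(oligo[i:i + 3] in STOP_CODONS for i in range(0, len(oligo), 3))


@dataclass(frozen=True)
class GCModel:
    """Uniform independent-site composition model with GC content ``g``."""

    g: float

    def __post_init__(self) -> None:
        if not 0.0 < self.g < 1.0:
            raise ValueError(f"GC content must lie in (0, 1), got {self.g}")

    @property
    def base_probs(self) -> Dict[str, float]:
        w = (1.0 - self.g) / 2.0
        s = self.g / 2.0
        return {"A": w, "T": w, "G": s, "C": s}

    def probability(self, oligomer: str) -> float:
        p = self.base_probs
        out = 1.0
        for b in oligomer:
            out *= p[b]
        return out


@dataclass(frozen=True)
class OligomerModel:
    """Empirical composition model backed by frequency tables.

    Any subset of the three tables may be supplied; operations that need a
    missing table raise ``ValueError``.
    """

    trimer_freqs: Optional[Dict[str, float]] = None
    codon_freqs: Optional[Dict[str, float]] = None
    dicodon_freqs: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.trimer_freqs is None and self.codon_freqs is None and self.dicodon_freqs is None:
            raise ValueError("OligomerModel needs at least one frequency table")
        if self.trimer_freqs is not None:
            object.__setattr__(self, "trimer_freqs", _check_table(self.trimer_freqs, 3, False, "trimer"))
        if self.codon_freqs is not None:
            object.__setattr__(self, "codon_freqs", _check_table(self.codon_freqs, 3, True, "codon"))
        if self.dicodon_freqs is not None:
            object.__setattr__(self, "dicodon_freqs", _check_table(self.dicodon_freqs, 6, True, "dicodon"))

    def table(self, length: int, coding: bool) -> Dict[str, float]:
        """Return the table for oligomers of ``length``; ``coding`` selects
        codon over trimer frequencies for 3-mers."""
        if length == 6:
            if self.dicodon_freqs is None:
                raise ValueError("model has no dicodon table")
            return self.dicodon_freqs
        if length == 3:
            first = self.codon_freqs if coding else self.trimer_freqs
            second = self.trimer_freqs if coding else self.codon_freqs
            tab = first if first is not None else second
            if tab is None:
                raise ValueError("model has no 3-mer table")
            return tab
        raise ValueError(f"no table for oligomer length {length}")


CompositionModel = (GCModel, OligomerModel)


def oligomer_probability(model, oligomer: str, coding: bool = False) -> float:
    """Probability of a 3- or 6-mer under ``model``.

    GCModel: product of per-base probabilities.  OligomerModel: table lookup
    (absent keys have probability 0).  ``coding`` selects the codon table
    over the trimer table for 3-mers of an OligomerModel.
    """
    if len(oligomer) not in (3, 6):
        raise ValueError(f"oligomer length must be 3 or 6, got {len(oligomer)}")
    if any(b not in BASES for b in oligomer):
        raise ValueError(f"oligomer {oligomer!r} contains non-ACGT characters")
    if isinstance(model, GCModel):
        return model.probability(oligomer)
    return model.table(len(oligomer), coding).get(oligomer, 0.0)


def gc_content(sequences: Iterable[str] | str) -> float:
    """Fraction (G+C)/(A+C+G+T); ambiguous bases are excluded entirely."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = at = 0
    for seq in sequences:
        s = str(seq).upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no countable (ACGT) bases in input")
    return gc / (gc + at)


def trimer_frequencies(sequences: Iterable[str] | str) -> Dict[str, float]:
    """Sliding-window trimer frequencies.

    Every length-3 window at every offset of every sequence is counted
    (windows do not cross record boundaries).  Windows containing a
    non-ACGT character are skipped and the skip count is logged.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts: Counter = Counter()
    skipped = 0
    for seq in sequences:
        s = str(seq).upper()
        for i in range(len(s) - 2):
            w = s[i:i + 3]
            if all(b in BASES for b in w):
                counts[w] += 1
            else:
                skipped += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable trimers")
    if skipped:
        logger.info("trimer_frequencies: skipped %d windows with ambiguous bases", skipped)
    return {t: c / total for t, c in counts.items()}


def _valid_orf(seq: str) -> Optional[str]:
    """Return a rejection reason for an ORF sequence, or None if valid."""
    if len(seq) % 3 != 0 or len(seq) < 9:
        return "length not a positive multiple of 3 (>= 9 nt)"
    if any(b not in BASES for b in seq):
        return "contains non-ACGT characters"
    if seq[:3] != "ATG":
        return "does not begin with ATG"
    if seq[-3:] not in STOP_CODONS:
        return "does not end with a stop codon"
    for i in range(3, len(seq) - 3, 3):
        if seq[i:i + 3] in STOP_CODONS:
            return "internal stop codon"
    return None


def codon_dicodon_frequencies(
    orf_sequences: Iterable[str],
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Codon and dicodon frequency tables from coding ORF sequences.

    Codons are counted non-overlapping (every third position) and dicodons
    every sixth position, both starting from the first position of each
    ORF.  The terminal stop codon is excluded from both tables, so the
    resulting tables are stop-free.  Sequences violating the ORF contract
    (ATG start, stop end, stop-free interior, length divisible by 3) are
    rejected individually with a warning.
    """
    codons: Counter = Counter()
    dicodons: Counter = Counter()
    n_valid = 0
    for seq in orf_sequences:
        s = str(seq).upper()
        reason = _valid_orf(s)
        if reason is not None:
            logger.warning("codon_dicodon_frequencies: rejected sequence (%s)", reason)
            continue
        n_valid += 1
        coding = s[:-3]  # drop the terminal stop
        for i in range(0, len(coding), 3):
            codons[coding[i:i + 3]] += 1
        for i in range(0, len(coding) - 5, 6):
            dicodons[coding[i:i + 6]] += 1
    if n_valid == 0:
        raise ValueError("no valid ORF sequences")
    ctot = sum(codons.values())
    dtot = sum(dicodons.values())
    codon_freqs = {c: n / ctot for c, n in codons.items()}
    dicodon_freqs = {d: n / dtot for d, n in dicodons.items()} if dtot else {}
    return codon_freqs, dicodon_freqs


def write_frequency_table(freqs: Mapping[str, float], path) -> None:
    """Write a 2-column (oligomer, frequency) TSV."""
    with open(path, "w") as fh:
        for oligo in sorted(freqs):
            fh.write(f"{oligo}\t{freqs[oligo]:.12g}\n")


def read_frequency_table(path) -> Dict[str, float]:
    out: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            oligo, val = line.split("\t")
            out[oligo] = float(val)
    return out
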