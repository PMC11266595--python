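"""Expected numbers of antisense and intergenic ORFs over annotated regions.

For an antisense-overlap region A of length l_A nucleotides, the number of
loci at which an ORF of k codons could exist in one specific antisense
frame is

    nLoci(A, k) = (l_A - 3k + 1) / 3

(one third of the nucleotide start offsets fall in each frame), while an
intergenic region admits every offset:

    nLoci(I, k) = l_I - 3k + 1.

Expected ORF counts sum P_ORF(f, k) * nLoci over regions and over
k >= 10 with 3k < l; non-integral loci counts are kept as real numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .composition import gc_content, GCModel
from .frame_model import Frame, orf_probability

K_MIN = 10  #: smallest ORF length counted, in codons (30 nt)


@dataclass(frozen=True)
class Region:
    """An annotated region: antisense-overlap span or intergenic stretch."""

    region_id: str
    length: int
    sequence: Optional[str] = None  # sense-strand sequence, for per-locus GC

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"region {self.region_id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"region {self.region_id}: sequence/length mismatch")


@dataclass
class RegionSet:
    antisense: List[Region] = field(default_factory=list)
    intergenic: List[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.antisense] + [r.region_id for r in self.intergenic]
        if len(ids) != len(set(ids)):
            raise ValueError("region identifiers must be unique")


def n_loci_antisense(l_a: int, k: int) -> float:
    """Per-frame loci count (l_A - 3k + 1)/3; requires 3k < l_A."""
    if k < K_MIN or 3 * k >= l_a:
        raise ValueError(f"k={k} out of bounds for region length {l_a}")
    return (l_a - 3 * k + 1) / 3.0


def n_loci_intergenic(l_i: int, k: int) -> float:
    """Intergenic loci count l_I - 3k + 1 (any offset starts a frame)."""
    if k < K_MIN or 3 * k >= l_i:
        raise ValueError(f"k={k} out of bounds for region length {l_i}")
    return float(l_i - 3 * k + 1)


def _k_range(length: int):
    return range(K_MIN, (length - 1) // 3 + 1)  # largest k with 3k < length


def total_loci(regions: Sequence[Region], intergenic: bool = False) -> float:
    """Total loci over a region set, summed over regions and k."""
    f = n_loci_intergenic if intergenic else n_loci_antisense
    return sum(f(r.length, k) for r in regions for k in _k_range(r.length))


def _region_model(region: Region, model):
    if model is not None:
        return model
    if region.sequence is None:
        raise ValueError(f"region {region.region_id}: no model and no sequence for per-locus GC")
    return GCModel(gc_content(region.sequence))


def expected_orf_count(regions: Sequence[Region], frame: Frame, model=None) -> float:
    """Expected number of ORFs in ``frame`` over ``regions``.

    ``model`` may be a single global composition model; if None, a GCModel
    is computed from each region's own sequence (per-locus GC mode).
    Antisense frames use the per-frame loci count, intergenic the
    all-offsets count.
    """
    if not regions:
        import logging
        logging.getLogger(__name__).warning("expected_orf_count: empty region set")
        return 0.0
    intergenic = frame is Frame.INTERGENIC
    n_loci = n_loci_intergenic if intergenic else n_loci_antisense
    out = 0.0
    for r in regions:
        m = _region_model(r, model)
        for k in _k_range(r.length):
            out += orf_probability(m, frame, k) * n_loci(r.length, k)
    return out


ANTISENSE_FRAMES = (Frame.AS0, Frame.AS1, Frame.AS2)


def observed_vs_expected_table(
    region_set: RegionSet,
    observed: Dict[Frame, int],
    observed_with_sub_orfs: Optional[Dict[Frame, int]] = None,
    model=None,
    per_locus_gc: bool = False,
) -> pd.DataFrame:
    """Expected-versus-observed ORF report, one column per frame context.

    Rows: total loci, expected number, observed number, observed number
    including sub-ORFs, and the corresponding frequencies (counts / loci).
    ``per_locus_gc=True`` recomputes a GCModel from each region's sequence
    instead of using the global ``model``.
    """
    frames = list(ANTISENSE_FRAMES) + [Frame.INTERGENIC]
    unknown = set(observed) - set(frames)
    if unknown:
        raise ValueError(f"observed counts for unknown frames: {unknown}")
    cols = {}
    for f in frames:
        regions = region_set.intergenic if f is Frame.INTERGENIC else region_set.antisense
        loci = total_loci(regions, intergenic=f is Frame.INTERGENIC)
        exp = expected_orf_count(regions, f, None if per_locus_gc else model)
        obs = observed.get(f, 0)
        obs_sub = (observed_with_sub_orfs or {}).get(f, obs)
        cols[f.value] = {
            "total_loci": loci,
            "expected_n": exp,
            "observed_n": obs,
            "observed_n_with_sub_orfs": obs_sub,
            "expected_frequency": exp / loci if loci else float("nan"),
            "observed_frequency": obs_sub / loci if loci else float("nan"),
        }
    return pd.DataFrame(cols)
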