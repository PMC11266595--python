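"""Observed-ORF pipeline: ORF extraction, antisense frame classification,
sub-ORFs, overlap fractions and GC comparisons.

All internal coordinates are 0-based half-open on the plus strand; GFF3
(1-based closed) is converted at the boundary.  An ORF is the longest
in-frame stretch from the most 5' ATG to a stop codon (one record per
stop, the getorf convention); shorter ORFs beginning at internal in-frame
ATGs and sharing the terminal stop are *sub-ORFs*.

The antisense frame of an ORF relative to a sense CDS on the opposite
strand is d = (s - x) mod 3, where s is the start of any sense codon and
x the leftmost plus-strand position of the pairing span of the ORF's
first codon: d = 0 means exact antiparallel codon overlap, d = 1/2 a
shift of one/two nucleotides toward the sense 5' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .composition import BASES, STOP_CODONS, gc_content
from .frame_model import revcomp
from .stats_compare import length_comparison_test

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 30  # nt, terminal stop included (10 codons)


@dataclass(frozen=True)
class Feature:
    """A located annotation (CDS, transcript, intergenic region)."""

    seq_id: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    feature_id: str = ""
    feature_type: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Feature") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class ORFRecord:
    """A located ORF; coordinates are plus-strand 0-based half-open and
    ``sequence`` is in reading direction (starts ATG, ends with a stop)."""

    seq_id: str
    start: int
    end: int
    strand: str
    sequence: str
    is_sub_orf: bool = False

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def stop_anchor(self) -> int:
        """Plus-strand leftmost coordinate of the terminal stop codon."""
        return self.end - 3 if self.strand == "+" else self.start

    def validate(self) -> None:
        s = self.sequence
        if self.length_nt != len(s):
            raise ValueError("coordinate span does not match sequence length")
        if len(s) < DEFAULT_MIN_LEN or len(s) % 3:
            raise ValueError("ORF length must be >= 30 nt and divisible by 3")
        if s[:3] != "ATG" or s[-3:] not in STOP_CODONS:
            raise ValueError("ORF must begin ATG and end with a stop codon")
        if any(s[i:i + 3] in STOP_CODONS for i in range(3, len(s) - 3, 3)):
            raise ValueError("ORF has an internal stop codon")


@dataclass(frozen=True)
class AntisenseOverlap:
    """Frame-of-overlap relation between an asORF and a sense CDS."""

    orf: ORFRecord
    cds: Feature
    frame: int
    overlap_fraction: float


def find_orfs(sequence: str, seq_id: str = "seq", min_len: int = DEFAULT_MIN_LEN) -> List[ORFRecord]:
    """ORFs in the reading direction of ``sequence`` (single strand).

    For every stop codon in each of the three frames, the ORF from the
    most 5' in-frame ATG with no intervening stop is reported (longest per
    stop); ``min_len`` counts the terminal stop.  Codons with ambiguous
    bases act as barriers.
    """
    s = str(sequence).upper()
    out: List[ORFRecord] = []
    for offset in range(3):
        atg: Optional[int] = None
        for i in range(offset, len(s) - 2, 3):
            codon = s[i:i + 3]
            if any(b not in BASES for b in codon):
                atg = None
            elif codon in STOP_CODONS:
                if atg is not None and i + 3 - atg >= min_len:
                    out.append(ORFRecord(seq_id, atg, i + 3, "+", s[atg:i + 3]))
                atg = None
            elif codon == "ATG" and atg is None:
                atg = i
    return sorted(out, key=lambda r: (r.start, r.end))


def sub_orfs(orf: ORFRecord, min_len: int = DEFAULT_MIN_LEN) -> List[ORFRecord]:
    """Sub-ORFs of ``orf``: one record per internal in-frame ATG with at
    least ``min_len`` nt remaining to the shared terminal stop."""
    out: List[ORFRecord] = []
    seq = orf.sequence
    for j in range(3, len(seq) - 3, 3):
        if seq[j:j + 3] == "ATG" and len(seq) - j >= min_len:
            if orf.strand == "+":
                rec = replace(orf, start=orf.start + j, sequence=seq[j:], is_sub_orf=True)
            else:
                rec = replace(orf, end=orf.end - j, sequence=seq[j:], is_sub_orf=True)
            out.append(rec)
    return out


def classify_frame(orf: ORFRecord, cds: Feature) -> AntisenseOverlap:
    """Antisense frame and overlap fraction of an ORF against a sense CDS.

    The ORF and CDS must lie on opposite strands of the same contig and
    overlap by at least one base.
    """
    if orf.strand == cds.strand:
        raise ValueError("asORF and sense CDS must be on opposite strands")
    as_feat = Feature(orf.seq_id, orf.start, orf.end, orf.strand)
    ov = as_feat.overlap(cds)
    if ov == 0:
        raise ValueError("asORF does not overlap the CDS")
    if cds.strand == "+":
        d = (cds.start - orf.end) % 3
    else:
        d = (orf.start - cds.end) % 3
    return AntisenseOverlap(orf, cds, d, ov / orf.length_nt)


# ---------------------------------------------------------------------------
# whole-genome scanning

def _transcript_sequence(genome: Dict[str, str], feat: Feature) -> str:
    try:
        contig = genome[feat.seq_id]
    except KeyError:
        raise ValueError(f"contig {feat.seq_id!r} missing from genome") from None
    seg = contig[feat.start:feat.end].upper()
    return seg if feat.strand == "+" else revcomp(seg)


def _to_genomic(orf: ORFRecord, tx: Feature) -> ORFRecord:
    """Map a transcript-relative ORF record onto genome coordinates."""
    if tx.strand == "+":
        start, end = tx.start + orf.start, tx.start + orf.end
    else:
        start, end = tx.end - orf.end, tx.end - orf.start
    return replace(orf, seq_id=tx.seq_id, start=start, end=end, strand=tx.strand)


@dataclass
class ScanResult:
    """Classified asORFs and per-frame summaries from a genome scan."""

    asorfs: List[AntisenseOverlap] = field(default_factory=list)
    multi_cds: List[AntisenseOverlap] = field(default_factory=list)

    def frame_counts(self, include_sub_orfs: bool = True) -> Dict[int, int]:
        counts = {0: 0, 1: 0, 2: 0}
        for ov in self.asorfs:
            if include_sub_orfs or not ov.orf.is_sub_orf:
                counts[ov.frame] += 1
        return counts

    def frame_lengths(self, include_sub_orfs: bool = False) -> Dict[int, List[int]]:
        lens: Dict[int, List[int]] = {0: [], 1: [], 2: []}
        for ov in self.asorfs:
            if include_sub_orfs or not ov.orf.is_sub_orf:
                lens[ov.frame].append(ov.orf.length_nt)
        return lens

    def summary(self) -> pd.DataFrame:
        lens = self.frame_lengths()
        counts = self.frame_counts(include_sub_orfs=False)
        counts_sub = self.frame_counts(include_sub_orfs=True)
        rows = {}
        for f in (0, 1, 2):
            ls = lens[f]
            rows[f"frame{f}"] = {
                "n_orfs": counts[f],
                "n_orfs_with_sub_orfs": counts_sub[f],
                "median_length_nt": float(pd.Series(ls).median()) if ls else float("nan"),
                "cumulative_length_nt": int(sum(ls)),
            }
        return pd.DataFrame(rows)


def scan_antisense_transcripts(
    genome: Dict[str, str],
    cds_features: Sequence[Feature],
    transcript_features: Sequence[Feature],
    min_len: int = DEFAULT_MIN_LEN,
    min_overlap_fraction: float = 1.0,
    include_sub_orfs: bool = False,
) -> ScanResult:
    """Find and classify ORFs in antisense transcripts.

    Each transcript is scanned single-stranded in its own reading
    direction; ORFs are mapped to genome coordinates and matched against
    CDS features on the opposite strand with at least
    ``min_overlap_fraction`` of the ORF overlapped.  ORFs matching more
    than one CDS are recorded separately and excluded from per-frame
    counts.
    """
    result = ScanResult()
    for tx in transcript_features:
        seq = _transcript_sequence(genome, tx)
        orfs = find_orfs(seq, seq_id=tx.feature_id or tx.seq_id, min_len=min_len)
        genomic = [_to_genomic(o, tx) for o in orfs]
        if include_sub_orfs:
            genomic += [s for o in genomic for s in sub_orfs(o, min_len)]
        for orf in genomic:
            hits = []
            for cds in cds_features:
                if cds.strand == orf.strand or cds.seq_id != orf.seq_id:
                    continue
                ov = Feature(orf.seq_id, orf.start, orf.end, orf.strand).overlap(cds)
                if ov / orf.length_nt >= min_overlap_fraction and ov > 0:
                    hits.append(classify_frame(orf, cds))
            if len(hits) == 1:
                result.asorfs.append(hits[0])
            elif len(hits) > 1:
                logger.info("asORF %s overlaps %d CDS features; excluded from frame counts",
                            orf, len(hits))
                result.multi_cds.extend(hits)
    return result


def scan_intergenic(
    genome: Dict[str, str],
    intergenic_features: Sequence[Feature],
    min_len: int = DEFAULT_MIN_LEN,
    strands: str = "+",
    include_sub_orfs: bool = False,
) -> List[ORFRecord]:
    """Intergenic ORFs found by the same getorf-style extraction.

    ``strands`` is ``"+"``, ``"-"`` or ``"both"``; each requested strand
    of each intergenic region is scanned independently.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    wanted = ["+", "-"] if strands == "both" else [strands]
    out: List[ORFRecord] = []
    for feat in intergenic_features:
        for strand in wanted:
            view = Feature(feat.seq_id, feat.start, feat.end, strand, feat.feature_id)
            seq = _transcript_sequence(genome, view)
            orfs = [_to_genomic(o, view) for o in find_orfs(seq, feat.feature_id, min_len)]
            if include_sub_orfs:
                orfs += [s for o in orfs for s in sub_orfs(o, min_len)]
            out.extend(orfs)
    return out


def antisense_overlap_regions(
    genome: Dict[str, str],
    cds_features: Sequence[Feature],
    transcript_features: Sequence[Feature],
) -> List[Tuple[str, int, str]]:
    """Antisense overlap regions (id, length, sense-strand sequence).

    One region per (CDS, opposite-strand transcript) overlapping pair,
    spanning their intersection; the sequence is the CDS (sense) strand.
    """
    regions = []
    for cds in cds_features:
        for tx in transcript_features:
            if tx.strand == cds.strand or tx.seq_id != cds.seq_id:
                continue
            lo, hi = max(cds.start, tx.start), min(cds.end, tx.end)
            if hi <= lo:
                continue
            seg = genome[cds.seq_id][lo:hi].upper()
            if cds.strand == "-":
                seg = revcomp(seg)
            rid = f"{cds.feature_id or 'cds'}|{tx.feature_id or 'tx'}"
            regions.append((rid, hi - lo, seg))
    return regions


def exon_gc_comparison(
    overlapping_exons: Iterable[str],
    all_exons: Iterable[str],
    alternative: str = "less",
) -> Dict[str, float]:
    """Per-exon GC distributions of antisense-overlapped versus all coding
    exons, with a one-tailed Mann-Whitney test (default claim: overlapped
    exons have lower GC)."""
    gc_overlap = [gc_content(s) for s in overlapping_exons]
    gc_all = [gc_content(s) for s in all_exons]
    if not gc_overlap or not gc_all:
        raise ValueError("both exon sets must be nonempty")
    res = length_comparison_test(gc_overlap, gc_all, alternative=alternative)
    return {
        "median_overlap": res["median_a"],
        "median_all": res["median_b"],
        "U": res["U"],
        "p_value": res["p_value"],
        "alternative": alternative,
    }


# ---------------------------------------------------------------------------
# file I/O

def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_gff3(path, feature_types: Optional[Sequence[str]] = None) -> List[Feature]:
    """Features from a GFF3 file, converted to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    out = []
    for f in db.all_features():
        if feature_types and f.featuretype not in feature_types:
            continue
        if f.strand not in "+-":
            continue
        out.append(Feature(f.seqid, f.start - 1, f.end, f.strand,
                           feature_id=f.id, feature_type=f.featuretype))
    return out


def write_gff3(features: Sequence[Tuple[Feature, Dict[str, str]]], path, source: str = "asorf") -> None:
    """Write (feature, attributes) pairs as GFF3 (converting to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(f"{feat.seq_id}\t{source}\t{feat.feature_type or 'region'}\t"
                     f"{feat.start + 1}\t{feat.end}\t.\t{feat.strand}\t.\t{attr_s}\n")
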