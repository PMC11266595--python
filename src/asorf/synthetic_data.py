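"""Synthetic genomes with known ground truth, and a forward-mutation
Monte-Carlo oracle for the analytic gain/loss probabilities.

The generator emulates the empirical inputs of the scanning pipeline: a
contig of intergenic background drawn base-by-base from a GC model,
stop-free sense CDSs drawn codon-by-codon from the same model conditioned
on no stop, antisense transcripts covering a fraction of the CDSs, and
optionally asORFs planted at requested frames with known coordinates.

The Monte-Carlo functions draw large numbers of independent loci, apply
one generation of bias-weighted mutations (at an inflated rate so that
events are observable at desk scale), and measure empirical ORF gain and
loss frequencies for comparison with the analytic one-generation
probabilities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .composition import BASES, GCModel, OligomerModel, STOP_CODONS
from .frame_model import Frame, revcomp
from .genome_scan import Feature, write_fasta, write_gff3
from .mutation_model import (
    GENETIC_CODE,
    MutationSpec,
    SelectionLevel,
    sense_mutation_tolerated,
    substitution_probability,
)

# base encoding: A=0, C=1, G=2, T=3; complement(b) = 3 - b
_B2I = {b: i for i, b in enumerate("ACGT")}
_I2B = np.array(list("ACGT"))
_STOP_IDX = np.array(sorted(16 * _B2I[s[0]] + 4 * _B2I[s[1]] + _B2I[s[2]] for s in STOP_CODONS))
_IS_STOP = np.zeros(64, dtype=bool)
_IS_STOP[_STOP_IDX] = True
_ATG_IDX = 16 * _B2I["A"] + 4 * _B2I["T"] + _B2I["G"]

_ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_NONSTOP_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]


def _base_probs(g: float) -> np.ndarray:
    w, s = (1.0 - g) / 2.0, g / 2.0
    return np.array([w, s, s, w])  # A C G T


def _codon_probs(g: float, codons: Sequence[str]) -> np.ndarray:
    p = _base_probs(g)
    out = np.array([p[_B2I[c[0]]] * p[_B2I[c[1]]] * p[_B2I[c[2]]] for c in codons])
    return out / out.sum()


def exact_oligomer_model(g: float) -> OligomerModel:
    """The OligomerModel a perfectly estimated synthetic genome implies.

    Codon frequencies are the GC product measure conditioned on no stop,
    dicodon frequencies the product of two such codons, and trimer
    frequencies the plain product measure (intergenic background is drawn
    base by base).
    """
    p = _base_probs(g)
    trimers = {c: float(p[_B2I[c[0]]] * p[_B2I[c[1]]] * p[_B2I[c[2]]]) for c in _ALL_CODONS}
    cp = _codon_probs(g, _NONSTOP_CODONS)
    codons = {c: float(v) for c, v in zip(_NONSTOP_CODONS, cp)}
    dicodons = {
        a + b: codons[a] * codons[b] for a in _NONSTOP_CODONS for b in _NONSTOP_CODONS
    }
    return OligomerModel(trimer_freqs=trimers, codon_freqs=codons, dicodon_freqs=dicodons)


# ---------------------------------------------------------------------------
# sequence sampling

def _draw_bases(rng: np.random.Generator, shape, g: float) -> np.ndarray:
    return rng.choice(4, size=shape, p=_base_probs(g)).astype(np.uint8)


def _draw_nonstop_codons(rng: np.random.Generator, shape, g: float) -> np.ndarray:
    """(…, 3*m) base array of codons i.i.d. from the non-stop-conditioned
    codon measure; ``shape`` is (n, m) in codons."""
    idx = rng.choice(len(_NONSTOP_CODONS), size=shape, p=_codon_probs(g, _NONSTOP_CODONS))
    tri = np.array([[_B2I[b] for b in c] for c in _NONSTOP_CODONS], dtype=np.uint8)
    return tri[idx].reshape(shape[0], -1)


def _stop_codon_probs(g: float) -> np.ndarray:
    p = _base_probs(g)
    stops = sorted(STOP_CODONS)
    out = np.array([p[_B2I[s[0]]] * p[_B2I[s[1]]] * p[_B2I[s[2]]] for s in stops])
    return out / out.sum()


def draw_stop_free_cds(model, k: int, rng: np.random.Generator) -> str:
    """A k-codon coding sequence: ATG, k-2 interior codons i.i.d. from the
    model's codon measure conditioned on no stop, and a terminal stop."""
    if k < 3:
        raise ValueError("CDS needs at least 3 codons")
    if isinstance(model, GCModel):
        codons, probs = _NONSTOP_CODONS, _codon_probs(model.g, _NONSTOP_CODONS)
        stops = sorted(STOP_CODONS)
        stop_p = _stop_codon_probs(model.g)
    else:
        tab = model.table(3, True)
        codons = [c for c in _NONSTOP_CODONS if tab.get(c, 0.0) > 0]
        probs = np.array([tab[c] for c in codons])
        probs = probs / probs.sum()
        stops, stop_p = sorted(STOP_CODONS), np.ones(3) / 3.0
    interior = rng.choice(len(codons), size=k - 2, p=probs)
    stop = stops[rng.choice(3, p=stop_p)]
    return "ATG" + "".join(codons[i] for i in interior) + stop


# ---------------------------------------------------------------------------
# forward mutation

def _rate_matrix(spec: MutationSpec, rate_scale: float) -> np.ndarray:
    """4x4 per-generation substitution probability matrix (A,C,G,T order)."""
    R = np.zeros((4, 4))
    for i, a in enumerate("ACGT"):
        for j, b in enumerate("ACGT"):
            if a != b:
                R[i, j] = substitution_probability(spec, a, b) * rate_scale
    return R


def _tolerance_table(level: SelectionLevel) -> np.ndarray:
    """(64, 3, 4) boolean: is a substitution at codon position p to base b
    tolerated by selection on the (non-stop) sense codon."""
    tab = np.zeros((64, 3, 4), dtype=bool)
    for ci, codon in enumerate(_ALL_CODONS):
        if codon in STOP_CODONS:
            continue
        for p in range(3):
            for bi, b in enumerate("ACGT"):
                if b == codon[p]:
                    continue
                mut = codon[:p] + b + codon[p + 1:]
                tab[ci, p, bi] = sense_mutation_tolerated(codon, mut, level)
    return tab


def _mutate_array(
    arr: np.ndarray,
    spec: MutationSpec,
    rng: np.random.Generator,
    rate_scale: float = 1.0,
    tolerance: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One generation of independent per-site mutations on a base array.

    Each site mutates with probability u*rate_scale*sum(bias from its
    base); the destination is drawn proportionally to the bias weights.
    With a ``tolerance`` table, mutations whose sense-codon change is not
    tolerated are rejected (sites keep their original base); each
    proposed change is judged against the original codon.
    """
    R = _rate_matrix(spec, rate_scale)
    theta = R.sum(axis=1)
    if theta.max() >= 1.0:
        raise ValueError("per-site mutation probability reaches 1; lower rate_scale")
    if theta.max() == 0.0:
        return arr.copy()
    dest_cum = np.cumsum(R / theta[:, None], axis=1)
    hit = rng.random(arr.shape) < theta[arr]
    rows, cols = np.nonzero(hit)
    if rows.size == 0:
        return arr.copy()
    src = arr[rows, cols]
    r = rng.random(rows.size)
    dest = (r[:, None] > dest_cum[src]).sum(axis=1).astype(np.uint8)
    if tolerance is not None:
        ci = (cols // 3) * 3
        from_codon = (16 * arr[rows, ci] + 4 * arr[rows, ci + 1] + arr[rows, ci + 2])
        keep = tolerance[from_codon, cols - ci, dest]
        rows, cols, dest = rows[keep], cols[keep], dest[keep]
    out = arr.copy()
    out[rows, cols] = dest
    return out


def mutate_one_generation(
    sequence: str,
    spec: MutationSpec,
    rng: np.random.Generator,
    rate_scale: float = 1.0,
) -> Tuple[str, List[Tuple[int, str, str]]]:
    """Mutate a nucleotide sequence for one generation; returns the new
    sequence and an event log of (position, from, to)."""
    arr = np.array([_B2I[b] for b in sequence.upper()], dtype=np.uint8)[None, :]
    new = _mutate_array(arr, spec, rng, rate_scale)[0]
    events = [(int(i), "ACGT"[arr[0, i]], "ACGT"[new[i]])
              for i in np.nonzero(new != arr[0])[0]]
    return "".join(_I2B[new]), events


# ---------------------------------------------------------------------------
# ORF status of encoded loci

def _ig_status(arr: np.ndarray, k: int) -> np.ndarray:
    """ORF status of (n, 3k) intergenic loci read in their own frame."""
    cod = arr.reshape(arr.shape[0], k, 3)
    idx = 16 * cod[:, :, 0] + 4 * cod[:, :, 1] + cod[:, :, 2]
    stops = _IS_STOP[idx]
    return (idx[:, 0] == _ATG_IDX) & stops[:, -1] & ~stops[:, 1:-1].any(axis=1)


def _as1_status(arr: np.ndarray, k: int) -> np.ndarray:
    """ORF status of (n, 3k+3) sense-strand loci in antisense frame 1.

    Antisense codon j reads the reverse complement of sense positions
    3j+2..3j+4; the antisense ORF runs from high to low sense positions
    (ATG at j = k-1, terminal stop at j = 0).
    """
    p = 3 * np.arange(k) + 2
    idx = (16 * (3 - arr[:, p + 2]) + 4 * (3 - arr[:, p + 1]) + (3 - arr[:, p]))
    stops = _IS_STOP[idx]
    return (idx[:, -1] == _ATG_IDX) & stops[:, 0] & ~stops[:, 1:-1].any(axis=1)


def simulate_orf_gain(
    frame: Frame,
    g: float,
    k: int,
    n: int,
    spec: MutationSpec,
    rate_scale: float,
    level: SelectionLevel = SelectionLevel.NONE,
    seed: int = 0,
) -> Dict[str, float]:
    """One-generation ORF gain frequency over n stationary loci.

    Intergenic loci are i.i.d. bases at GC g; frame-1 loci are stop-free
    sense codon chains (k+1 codons) read antisense, with the selection
    filter applied to every sense codon change.  Returns the gain count,
    sample size and frequency.
    """
    rng = np.random.default_rng(seed)
    if frame is Frame.INTERGENIC:
        arr = _draw_bases(rng, (n, 3 * k), g)
        status, tol = _ig_status, None
    elif frame is Frame.AS1:
        arr = _draw_nonstop_codons(rng, (n, k + 1), g)
        status, tol = _as1_status, _tolerance_table(level)
    else:
        raise ValueError(f"simulation supports intergenic and as1, not {frame}")
    before = status(arr, k)
    after = status(_mutate_array(arr, spec, rng, rate_scale, tol), k)
    gained = int((~before & after).sum())
    return {"events": gained, "n": n, "frequency": gained / n}


def _draw_as1_orf_loci(rng: np.random.Generator, n: int, k: int, g: float) -> np.ndarray:
    """n sense-strand loci conditioned to be frame-1 antisense ORFs."""
    out = []
    need = n
    while need > 0:
        batch = max(1000, int(need / 0.5))
        arr = _draw_nonstop_codons(rng, (batch, k + 1), g)
        # antisense ATG at j=k-1: sense positions 3k-1..3k+1 read CAT;
        # codon k-1 becomes NNC (never a stop), codon k becomes ATN.
        arr[:, 3 * k - 1] = _B2I["C"]
        arr[:, 3 * k] = _B2I["A"]
        arr[:, 3 * k + 1] = _B2I["T"]
        # terminal antisense stop at j=0: resample codons 0 and 1 until the
        # antisense reading of sense positions 2..4 is a stop codon.
        while True:
            idx0 = (16 * (3 - arr[:, 4]) + 4 * (3 - arr[:, 3]) + (3 - arr[:, 2]))
            bad = ~_IS_STOP[idx0]
            if not bad.any():
                break
            arr[bad, :6] = _draw_nonstop_codons(rng, (int(bad.sum()), 2), g)
        ok = _as1_status(arr, k)
        out.append(arr[ok])
        need -= int(ok.sum())
    return np.concatenate(out)[:n]


def _draw_ig_orf_loci(rng: np.random.Generator, n: int, k: int, g: float) -> np.ndarray:
    arr = np.empty((n, 3 * k), dtype=np.uint8)
    arr[:, 0], arr[:, 1], arr[:, 2] = _B2I["A"], _B2I["T"], _B2I["G"]
    arr[:, 3:3 * k - 3] = _draw_nonstop_codons(rng, (n, k - 2), g)
    stops = sorted(STOP_CODONS)
    choice = rng.choice(3, size=n, p=_stop_codon_probs(g))
    stop_tri = np.array([[_B2I[b] for b in s] for s in stops], dtype=np.uint8)
    arr[:, 3 * k - 3:] = stop_tri[choice]
    return arr


def simulate_orf_loss(
    frame: Frame,
    g: float,
    k: int,
    n: int,
    spec: MutationSpec,
    rate_scale: float,
    level: SelectionLevel = SelectionLevel.NONE,
    seed: int = 0,
) -> Dict[str, float]:
    """One-generation ORF loss frequency over n loci conditioned to be
    ORFs, sampled from the stationary measure given ORF status."""
    rng = np.random.default_rng(seed)
    if frame is Frame.INTERGENIC:
        arr = _draw_ig_orf_loci(rng, n, k, g)
        status, tol = _ig_status, None
    elif frame is Frame.AS1:
        arr = _draw_as1_orf_loci(rng, n, k, g)
        status, tol = _as1_status, _tolerance_table(level)
    else:
        raise ValueError(f"simulation supports intergenic and as1, not {frame}")
    assert status(arr, k).all()
    after = status(_mutate_array(arr, spec, rng, rate_scale, tol), k)
    lost = int((~after).sum())
    return {"events": lost, "n": n, "frequency": lost / n}


# ---------------------------------------------------------------------------
# genome generation

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout and composition of a synthetic genome.

    Lengths are (min, max) ranges sampled uniformly; ``planted_per_frame``
    requests asORFs planted at frames 0, 1 and 2 with known coordinates
    (each plant occupies its own CDS).
    """

    seed: int = 0
    gc: float = 0.38
    n_cds: int = 20
    cds_length_codons: Tuple[int, int] = (100, 400)
    antisense_fraction: float = 0.5
    intergenic_length: Tuple[int, int] = (200, 800)
    planted_per_frame: Tuple[int, int, int] = (0, 0, 0)
    planted_length_codons: Tuple[int, int] = (12, 30)
    contig_id: str = "chr1"

    def __post_init__(self) -> None:
        if sum(self.planted_per_frame) > self.n_cds:
            raise ValueError("more planted asORFs than CDSs (one plant per CDS)")
        if self.cds_length_codons[0] < max(10, self.planted_length_codons[1] + 4):
            raise ValueError("CDSs too short to host the requested plants")


@dataclass
class SyntheticGenome:
    genome: Dict[str, str]
    cds: List[Feature]
    transcripts: List[Feature]
    ground_truth: pd.DataFrame
    spec: SyntheticGenomeSpec

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_gff3([(f, {"ID": f.feature_id}) for f in self.cds], outdir / "cds.gff3")
        write_gff3([(f, {"ID": f.feature_id}) for f in self.transcripts],
                   outdir / "antisense.gff3")
        self.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def _plant_local_cds(rng: np.random.Generator, g: float, k_cds: int, frame: int,
                     k_orf: int, max_attempts: int = 200) -> Tuple[str, int, int]:
    """A sense-local CDS sequence hosting one asORF at the given frame.

    Returns (cds_sequence, a_start, a_end) with the asORF span in local
    sense coordinates.  The antisense codon immediately 5' of the planted
    ATG is set to a stop so that the getorf-style scan recovers exactly
    the planted boundaries.  Raises if no attempt satisfies all codon
    constraints.
    """
    model = GCModel(g)
    L = 3 * k_cds
    # feasible right edges: a_end = x + 3 with x = (s - frame) for a codon
    # start s; guard codon occupies [a_end, a_end+3)
    ends = [e for e in range(3 * k_orf + 3, L - 5) if e % 3 == (3 - frame) % 3]
    ends = [e for e in ends if e - 3 * k_orf >= 3]
    if not ends:
        raise ValueError(f"no feasible position for a {k_orf}-codon frame-{frame} "
                         f"asORF in a {k_cds}-codon CDS")
    stops = sorted(STOP_CODONS)
    for _ in range(max_attempts):
        a_end = int(rng.choice(ends))
        a_start = a_end - 3 * k_orf
        asorf = draw_stop_free_cds(model, k_orf, rng)
        guard = stops[rng.choice(3)]
        sense = list(draw_stop_free_cds(model, k_cds, rng))
        sense[a_start:a_end] = revcomp(asorf)
        sense[a_end:a_end + 3] = revcomp(guard)
        seq = "".join(sense)
        # all sense codons except the terminal one must be non-stop
        if any(seq[i:i + 3] in STOP_CODONS for i in range(0, L - 3, 3)):
            continue
        # the scan must recover exactly the planted span: no in-frame ATG
        # 5' of the plant before a stop (the guard provides the stop), and
        # no earlier in-frame stop inside the plant (true by construction)
        anti = revcomp(seq)  # antisense strand, local reading direction
        o_start = L - a_end  # plant start within the antisense reading
        upstream_ok = True
        for p in range(o_start - 3, -1, -3):
            cod = anti[p:p + 3]
            if cod in STOP_CODONS:
                break
            if cod == "ATG":
                upstream_ok = False
                break
        if upstream_ok:
            return seq, a_start, a_end
    raise ValueError(f"could not place a frame-{frame} asORF of {k_orf} codons "
                     f"after {max_attempts} attempts")


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Deterministic synthetic genome with CDS and antisense annotations.

    The contig alternates intergenic background (i.i.d. bases at the
    requested GC) with stop-free CDSs on random strands.  Planted asORFs
    are assigned to the first CDSs; every planted CDS, plus a random
    fraction of the rest, receives an antisense transcript spanning it.
    """
    rng = np.random.default_rng(spec.seed)
    plants: List[Tuple[int, int]] = []  # (frame, k_orf) per planted CDS
    for frame, count in enumerate(spec.planted_per_frame):
        plants += [(frame, int(rng.integers(spec.planted_length_codons[0],
                                            spec.planted_length_codons[1] + 1)))
                   for _ in range(count)]
    parts: List[str] = []
    pos = 0
    cds_feats: List[Feature] = []
    tx_feats: List[Feature] = []
    truth_rows = []

    def add_intergenic() -> None:
        nonlocal pos
        n = int(rng.integers(spec.intergenic_length[0], spec.intergenic_length[1] + 1))
        parts.append("".join(_I2B[_draw_bases(rng, (1, n), spec.gc)[0]]))
        pos += n

    add_intergenic()
    for i in range(spec.n_cds):
        k_cds = int(rng.integers(spec.cds_length_codons[0], spec.cds_length_codons[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        plant = plants[i] if i < len(plants) else None
        if plant is not None:
            frame, k_orf = plant
            local, a_start, a_end = _plant_local_cds(rng, spec.gc, k_cds, frame, k_orf)
        else:
            local = draw_stop_free_cds(GCModel(spec.gc), k_cds, rng)
        L = len(local)
        segment = local if strand == "+" else revcomp(local)
        start, end = pos, pos + L
        cds_id = f"cds{i + 1}"
        cds_feats.append(Feature(spec.contig_id, start, end, strand, cds_id, "CDS"))
        wants_tx = plant is not None or rng.random() < spec.antisense_fraction
        if wants_tx:
            anti = "-" if strand == "+" else "+"
            tx_feats.append(Feature(spec.contig_id, start, end, anti,
                                    f"astx{i + 1}", "ncRNA"))
        if plant is not None:
            if strand == "+":
                g_start, g_end = start + a_start, start + a_end
            else:
                g_start, g_end = start + L - a_end, start + L - a_start
            truth_rows.append({
                "asorf_id": f"plant{len(truth_rows) + 1}",
                "seq_id": spec.contig_id,
                "start": g_start, "end": g_end,
                "strand": "-" if strand == "+" else "+",
                "frame": plant[0],
                "length_nt": 3 * plant[1],
                "cds_id": cds_id,
            })
        parts.append(segment)
        pos = end
        add_intergenic()

    genome = {spec.contig_id: "".join(parts)}
    truth = pd.DataFrame(truth_rows, columns=["asorf_id", "seq_id", "start", "end",
                                              "strand", "frame", "length_nt", "cds_id"])
    return SyntheticGenome(genome, cds_feats, tx_feats, truth, spec)


def intergenic_features(bundle: SyntheticGenome) -> List[Feature]:
    """The intergenic complement of the bundle's CDS annotations."""
    out = []
    for seq_id, seq in bundle.genome.items():
        covered = sorted((f.start, f.end) for f in bundle.cds if f.seq_id == seq_id)
        prev = 0
        n = 0
        for s, e in covered + [(len(seq), len(seq))]:
            if s > prev:
                n += 1
                out.append(Feature(seq_id, prev, s, "+", f"ig{seq_id}.{n}", "intergenic"))
            prev = max(prev, e)
    return out
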