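"""Sequence and alignment data model.

Coordinates are 1-based, inclusive, in alignment-column space throughout the
package, so positions printed in reports can be read directly against an
alignment viewer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = set("ACGTN-")

NONCODING = 0  # site-class label for intron / flank columns


class SeqFormatError(ValueError):
    """Raised on malformed FASTA/FASTQ input."""


class GeneModelError(ValueError):
    """Raised when a gene model is inconsistent with an alignment."""


@dataclass
class NucSequence:
    """A nucleotide sequence, optionally with per-base Phred qualities."""

    id: str
    residues: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.id!r}")
        self.residues = self.residues.upper()
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(f"quality/residue length mismatch in {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class AlignedSet:
    """A multiple alignment; all members share one column coordinate system."""

    members: list[NucSequence]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("alignment must contain at least one sequence")
        L = len(self.members[0])
        for m in self.members:
            if len(m) != L:
                raise ValueError(
                    f"aligned length mismatch: {m.id!r} has {len(m)} != {L}"
                )
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def length(self) -> int:
        return len(self.members[0])

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, key: str) -> NucSequence:
        for m in self.members:
            if m.id == key:
                return m
        raise KeyError(key)

    def column(self, col: int) -> str:
        """Residues at 1-based column ``col``."""
        return "".join(m.residues[col - 1] for m in self.members)

    def subset(self, ids: Iterable[str]) -> "AlignedSet":
        wanted = list(ids)
        return AlignedSet([self[i] for i in wanted])

    def to_matrix(self) -> np.ndarray:
        """Byte matrix (n_seqs x n_cols) of ASCII codes, for vector ops."""
        return np.frombuffer(
            "".join(m.residues for m in self.members).encode(), dtype=np.uint8
        ).reshape(len(self.members), self.length)


@dataclass
class GeneModel:
    """Exon structure of a locus in alignment-column coordinates.

    ``frame_offset`` is the codon phase of the first exonic column: 0 means
    the first exonic column is a first codon position, 1 that it is a second
    position (the leading 2 columns complete an upstream codon), etc.
    """

    exon_intervals: list[tuple[int, int]]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise GeneModelError("frame_offset must be 0, 1 or 2")
        prev_end = 0
        for s, e in self.exon_intervals:
            if s < 1 or e < s:
                raise GeneModelError(f"bad exon interval ({s}, {e})")
            if s <= prev_end:
                raise GeneModelError("exon intervals must be ordered, non-overlapping")
            prev_end = e

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exon_intervals)

    def exonic_columns(self) -> list[int]:
        cols: list[int] = []
        for s, e in self.exon_intervals:
            cols.extend(range(s, e + 1))
        return cols

    def shifted(self, offset: int) -> "GeneModel":
        return GeneModel(
            [(s + offset, e + offset) for s, e in self.exon_intervals],
            self.frame_offset,
        )


@dataclass
class SiteClassMap:
    """Per-column classification into noncoding vs codon positions.

    ``codon_index[c-1]`` is 0 for noncoding columns, otherwise the 1-based
    index of the codon the column belongs to; ``codon_pos`` holds the 1-3
    position within that codon.
    """

    length: int
    codon_index: np.ndarray  # int32, 0 = noncoding
    codon_pos: np.ndarray  # int8, 0 = noncoding

    @property
    def noncoding_columns(self) -> np.ndarray:
        """1-based columns labelled noncoding."""
        return np.flatnonzero(self.codon_index == 0) + 1

    @property
    def coding_columns(self) -> np.ndarray:
        return np.flatnonzero(self.codon_index > 0) + 1

    def codons(self) -> list[tuple[int, int, int]]:
        """1-based column triples of complete codons, in codon order.

        Codons truncated by the analysis window or by ``frame_offset`` (fewer
        than three columns present) are dropped.
        """
        out: list[tuple[int, int, int]] = []
        order = np.argsort(self.codon_index, kind="stable")
        cols_by_codon: dict[int, list[tuple[int, int]]] = {}
        for c in range(self.length):
            ci = int(self.codon_index[c])
            if ci > 0:
                cols_by_codon.setdefault(ci, []).append((int(self.codon_pos[c]), c + 1))
        for ci in sorted(cols_by_codon):
            entries = sorted(cols_by_codon[ci])
            if len(entries) == 3 and [p for p, _ in entries] == [1, 2, 3]:
                out.append(tuple(col for _, col in entries))  # type: ignore[arg-type]
        return out

    def to_table(self) -> str:
        """Tab-separated dump (column, class, codon, position) for debugging."""
        lines = ["column\tclass\tcodon\tposition"]
        for c in range(self.length):
            if self.codon_index[c] == 0:
                lines.append(f"{c + 1}\tNONCODING\t\t")
            else:
                lines.append(
                    f"{c + 1}\tCODON\t{self.codon_index[c]}\t{self.codon_pos[c]}"
                )
        return "\n".join(lines) + "\n"


@dataclass
class IndelEvent:
    """An insertion or deletion relative to the reference.

    ``position`` is the 1-based reference position of the first deleted base
    (deletions) or of the reference base immediately left of the inserted
    string (insertions; 0 means insertion before the first base).
    """

    kind: str  # "ins" | "del"
    position: int
    length: int
    sequence: str  # inserted or deleted bases

    def key(self) -> tuple[str, int, int, str]:
        return (self.kind, self.position, self.length, self.sequence)


@dataclass
class PairwiseAlignment:
    aligned_query: str
    aligned_ref: str
    score: float
    events: list[IndelEvent] = field(default_factory=list)

    @property
    def query(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace("-", "")


class BandTooNarrowError(ValueError):
    """The optimal alignment path reached the band edge; widen the band."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucSequence]:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise SeqFormatError(f"{path}: empty record {rec.id!r}")
        out.append(NucSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Sequence[NucSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[NucSequence]:
    path = Path(path)
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append(
                NucSequence(
                    rec.id,
                    str(rec.seq),
                    list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:  # Biopython signals truncation/length mismatch
        raise SeqFormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(seqs: Sequence[NucSequence], path: str | Path) -> None:
    records = []
    for s in seqs:
        quals = s.qualities if s.qualities is not None else [40] * len(s)
        rec = SeqRecord(Seq(s.residues), id=s.id, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Banded global alignment with affine gaps
# ---------------------------------------------------------------------------

_NEG_INF = -1e30


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8).copy()


try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=False)
def _banded_dp(q, r, match, mismatch, gap_open, gap_extend, band):
    """Affine-gap Needleman-Wunsch restricted to |j - i| <= band.

    Returns (score, pointer matrices M/Iq/Ir, hit_edge flag via traceback).
    Layer codes in pointers: 0=M, 1=Iq (gap in ref / insertion), 2=Ir
    (gap in query / deletion).
    """
    nq = q.shape[0]
    nr = r.shape[0]
    w = 2 * band + 1
    M = np.full((nq + 1, w), _NEG_INF)
    Iq = np.full((nq + 1, w), _NEG_INF)
    Ir = np.full((nq + 1, w), _NEG_INF)
    Mp = np.zeros((nq + 1, w), dtype=np.int8)
    Iqp = np.zeros((nq + 1, w), dtype=np.int8)
    Irp = np.zeros((nq + 1, w), dtype=np.int8)
    # column j maps to band slot k = j - i + band
    M[0, band] = 0.0
    for j in range(1, min(nr, band) + 1):
        k = j + band
        if k < w:
            Ir[0, k] = gap_open + gap_extend * (j - 1)
            Irp[0, k] = 2
    for i in range(1, nq + 1):
        jlo = max(0, i - band)
        jhi = min(nr, i + band)
        for j in range(jlo, jhi + 1):
            k = j - i + band
            if j == 0:
                Iq[i, k] = gap_open + gap_extend * (i - 1)
                Iqp[i, k] = 1
                continue
            # M: diagonal move consumes q[i-1], r[j-1]; same slot k in row i-1
            qb = q[i - 1]
            rb = r[j - 1]
            if qb == 78 or rb == 78:  # 'N'
                s = mismatch / 2.0
            elif qb == rb:
                s = match
            else:
                s = mismatch
            best = _NEG_INF
            ptr = 0
            if M[i - 1, k] > best:
                best = M[i - 1, k]
                ptr = 0
            if Iq[i - 1, k] > best:
                best = Iq[i - 1, k]
                ptr = 1
            if Ir[i - 1, k] > best:
                best = Ir[i - 1, k]
                ptr = 2
            if best > _NEG_INF / 2:
                M[i, k] = best + s
                Mp[i, k] = ptr
            # Iq: consumes q[i-1] only (gap in ref); from row i-1, slot k+1
            if k + 1 < w:
                bo = M[i - 1, k + 1] + gap_open
                be = Iq[i - 1, k + 1] + gap_extend
                if bo >= be:
                    if bo > _NEG_INF / 2:
                        Iq[i, k] = bo
                        Iqp[i, k] = 0
                else:
                    Iq[i, k] = be
                    Iqp[i, k] = 1
            # Ir: consumes r[j-1] only (gap in query); same row, slot k-1
            if k - 1 >= 0:
                bo = M[i, k - 1] + gap_open
                be = Ir[i, k - 1] + gap_extend
                if bo >= be:
                    if bo > _NEG_INF / 2:
                        Ir[i, k] = bo
                        Irp[i, k] = 0
                else:
                    Ir[i, k] = be
                    Irp[i, k] = 2
    return M, Iq, Ir, Mp, Iqp, Irp


def align_pair_global(
    query: NucSequence,
    ref: NucSequence,
    scoring: dict | None = None,
    band: int | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` to ``ref`` within a diagonal band.

    Scoring is affine: the first base of a gap costs ``gap_open``, each
    further base ``gap_extend``.  ``N`` against anything scores
    ``mismatch / 2``.  Indel events are reported in 1-based reference
    coordinates, left-aligned within homopolymer runs so the filter logic
    downstream sees one canonical placement.

    Raises :class:`BandTooNarrowError` if the optimal in-band path touches
    the band edge (the in-band optimum is then not certified global-optimal).
    """
    if not query.residues or not ref.residues:
        raise ValueError("both sequences must be non-empty")
    sc = {"match": 1.0, "mismatch": -1.0, "gap_open": -3.0, "gap_extend": -1.0}
    if scoring:
        sc.update(scoring)
    q = _encode(query.residues)
    r = _encode(ref.residues)
    nq, nr = len(q), len(r)
    if band is None:
        band = max(nq, nr)
    if band < abs(nq - nr):
        raise BandTooNarrowError(
            f"band {band} < length difference {abs(nq - nr)}"
        )
    M, Iq, Ir, Mp, Iqp, Irp = _banded_dp(
        q, r, sc["match"], sc["mismatch"], sc["gap_open"], sc["gap_extend"], band
    )
    kend = nr - nq + band
    scores = (M[nq, kend], Iq[nq, kend], Ir[nq, kend])
    layer = int(np.argmax(scores))
    score = float(scores[layer])
    if score <= _NEG_INF / 2:
        raise BandTooNarrowError("no alignment path inside the band")

    # traceback
    aq: list[str] = []
    ar: list[str] = []
    i, j = nq, nr
    hit_edge = False
    full_band = band >= max(nq, nr)
    while i > 0 or j > 0:
        k = j - i + band
        if not full_band and abs(j - i) == band and (i, j) != (nq, nr):
            hit_edge = True
        if layer == 0:
            ptr = Mp[i, k]
            aq.append(query.residues[i - 1])
            ar.append(ref.residues[j - 1])
            i -= 1
            j -= 1
            layer = int(ptr)
        elif layer == 1:
            ptr = Iqp[i, k]
            aq.append(query.residues[i - 1])
            ar.append("-")
            i -= 1
            layer = int(ptr)
        else:
            ptr = Irp[i, k]
            aq.append("-")
            ar.append(ref.residues[j - 1])
            j -= 1
            layer = int(ptr)
    if hit_edge:
        raise BandTooNarrowError(
            "optimal in-band path touches the band edge; widen the band"
        )
    aligned_q = "".join(reversed(aq))
    aligned_r = "".join(reversed(ar))
    events = _extract_events(aligned_q, aligned_r, ref.residues)
    return PairwiseAlignment(aligned_q, aligned_r, score, events)


def _extract_events(aq: str, ar: str, ref: str) -> list[IndelEvent]:
    events: list[IndelEvent] = []
    ref_pos = 0  # 1-based position of last consumed ref base
    i = 0
    n = len(aq)
    while i < n:
        if ar[i] == "-":  # insertion relative to ref
            start = i
            while i < n and ar[i] == "-":
                i += 1
            ins = aq[start:i]
            events.append(IndelEvent("ins", ref_pos, len(ins), ins))
        elif aq[i] == "-":  # deletion
            start = i
            while i < n and aq[i] == "-":
                i += 1
            length = i - start
            events.append(
                IndelEvent("del", ref_pos + 1, length, ref[ref_pos : ref_pos + length])
            )
            ref_pos += length
        else:
            ref_pos += 1
            i += 1
    return [_left_align(e, ref) for e in events]


def _left_align(event: IndelEvent, ref: str) -> IndelEvent:
    """Shift an indel left while the flanking context permits (homopolymers
    and short tandem repeats get one canonical placement)."""
    if event.kind == "del":
        pos, length, seq = event.position, event.length, event.sequence
        while pos > 1 and ref[pos - 2] == ref[pos + length - 2]:
            pos -= 1
            seq = ref[pos - 1 : pos - 1 + length]
        return IndelEvent("del", pos, length, seq)
    pos, seq = event.position, event.sequence
    while pos > 0 and ref[pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    return IndelEvent("ins", pos, event.length, seq)


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

def classify_sites(aln_length: int | AlignedSet, model: GeneModel) -> SiteClassMap:
    """Label every alignment column noncoding or (codon index, position 1-3).

    Codons spanning exon junctions are assembled across the junction: codon
    position simply continues from one exon into the next.
    """
    L = aln_length.length if isinstance(aln_length, AlignedSet) else int(aln_length)
    codon_index = np.zeros(L, dtype=np.int32)
    codon_pos = np.zeros(L, dtype=np.int8)
    exonic = model.exonic_columns()
    if exonic and exonic[-1] > L:
        raise GeneModelError(
            f"exon column {exonic[-1]} beyond alignment length {L}"
        )
    if (model.frame_offset + len(exonic)) % 3 != 0:
        raise GeneModelError(
            "exonic length not partitionable into codons under frame_offset"
        )
    for k, col in enumerate(exonic):
        phase = (k + model.frame_offset) % 3
        codon_index[col - 1] = (k + model.frame_offset) // 3 + 1
        codon_pos[col - 1] = phase + 1
    return SiteClassMap(L, codon_index, codon_pos)


def restrict(
    aln: AlignedSet, window: tuple[int, int], model: GeneModel | None = None
) -> tuple[AlignedSet, GeneModel | None]:
    """Cut an alignment (and optionally its gene model) to a column window.

    The window is 1-based inclusive.  Exons are clipped to the window and the
    frame offset recomputed so codon phases of retained columns are unchanged.
    """
    start, end = window
    if start > end:
        raise ValueError(f"inverted window ({start}, {end})")
    if start < 1 or end > aln.length:
        raise ValueError(f"window ({start}, {end}) outside 1..{aln.length}")
    cut = AlignedSet(
        [
            NucSequence(
                m.id,
                m.residues[start - 1 : end],
                m.qualities[start - 1 : end] if m.qualities else None,
            )
            for m in aln.members
        ]
    )
    if model is None:
        return cut, None
    full_map = classify_sites(aln.length, model)
    new_exons: list[tuple[int, int]] = []
    new_frame = 0
    first = True
    for s, e in model.exon_intervals:
        cs, ce = max(s, start), min(e, end)
        if cs > ce:
            continue
        if first:
            # phase of the first retained exonic column
            new_frame = int(full_map.codon_pos[cs - 1]) - 1
            first = False
        new_exons.append((cs - start + 1, ce - start + 1))
    if first:
        new_model = GeneModel([], 0)
    else:
        # trailing partial codon: pad frame bookkeeping by trimming columns that
        # cannot complete a codon; classify_sites requires exact partition, so
        # drop trailing exonic columns whose codon is cut by the window.
        exonic = []
        for s, e in new_exons:
            exonic.extend(range(s, e + 1))
        excess = (new_frame + len(exonic)) % 3
        while excess:
            s, e = new_exons[-1]
            drop = min(excess, e - s + 1)
            if drop == e - s + 1:
                new_exons.pop()
            else:
                new_exons[-1] = (s, e - drop)
            excess -= drop
        new_model = GeneModel(new_exons, new_frame)
    return cut, new_model


def pairwise_differences(
    a: str, b: str, columns: Iterable[int] | None = None
) -> tuple[int, int]:
    """(differences, compared sites) between two aligned strings.

    Sites where either sequence has a gap or N are excluded (pairwise
    deletion).  ``columns`` restricts the comparison to 1-based columns.
    """
    if columns is None:
        cols = range(1, len(a) + 1)
    else:
        cols = columns
    diffs = 0
    n = 0
    for c in cols:
        x, y = a[c - 1], b[c - 1]
        if x in "N-" or y in "N-":
            continue
        n += 1
        if x != y:
            diffs += 1
    return diffs, n
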