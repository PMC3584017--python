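"""Multiple sequence alignment per locus and multi-locus concatenation.

Two routes produce an :class:`Alignment`:

* the built-in progressive aligner (k-mer guide tree + consensus-based
  profile merging), adequate for the low-divergence, mostly-indel-free
  sequences a barcode study compares within genera, and
* pass-through of externally aligned FASTA, so results produced with any
  standalone aligner can be fed into the downstream analyses unchanged.

Concatenation restricts to samples present in every input locus (the only
samples for which a multi-locus barcode exists) and records the per-locus
column boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align as _bioalign

from barcodekit.io import LocusCollection, SequenceRecord

_BASES = "ACGT"


@dataclass
class Alignment:
    """Equal-length gapped rows over a set of samples.

    ``boundaries`` is non-empty only for concatenations: a list of
    (locus, start, end) with 0-based half-open column spans.
    """

    label: str
    ids: list[str]
    rows: list[str]
    boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sample ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, sample_id: str) -> str:
        return self.rows[self.ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "Alignment":
        idx = {sid: i for i, sid in enumerate(self.ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in alignment: {missing}")
        return Alignment(
            self.label,
            list(sample_ids),
            [self.rows[idx[s]] for s in sample_ids],
            list(self.boundaries),
        )

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path, label: str | None = None) -> "Alignment":
        from Bio import SeqIO

        ids, rows = [], []
        for entry in SeqIO.parse(str(path), "fasta"):
            ids.append(entry.id)
            rows.append(str(entry.seq).upper().replace("U", "T"))
        return cls(label or Path(path).stem, ids, rows)


def _global_aligner(match: float, mismatch: float, gap_open: float,
                    gap_extend: float) -> _bioalign.PairwiseAligner:
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # gap_open is the cost of a length-1 gap (first gapped position)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_align(
    a: str,
    b: str,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -4,
    gap_extend: float = -1,
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under affine gap scoring.

    ``gap_open`` is the score of a length-1 gap; a length-k gap scores
    ``gap_open + (k-1) * gap_extend``. Ties are broken deterministically
    (first optimal traceback). Returns (gapped a, gapped b, score).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aligner = _global_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb, aln.score


def kmer_distance(a: str, b: str, k: int = 6) -> float:
    """1 - Jaccard similarity of the two sequences' k-mer sets.

    Alignment-free and deterministic; used only to shape the guide tree.
    """
    sa = {a[i : i + k] for i in range(max(0, len(a) - k + 1))}
    sb = {b[i : i + k] for i in range(max(0, len(b) - k + 1))}
    if not sa and not sb:
        return 0.0
    union = len(sa | sb)
    return 1.0 - len(sa & sb) / union if union else 1.0


class _Profile:
    """Rows under alignment during progressive merging."""

    __slots__ = ("ids", "rows")

    def __init__(self, ids: list[str], rows: list[str]):
        self.ids = ids
        self.rows = rows

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def consensus(self) -> str:
        """Majority unambiguous base per column (gaps/ambiguity ignored;
        all-missing columns fall back to 'N' -> treated as 'A' for scoring)."""
        arr = np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            len(self.rows), -1
        )
        out = []
        for j in range(arr.shape[1]):
            col = arr[:, j]
            counts = [(int((col == b.encode()).sum()), b) for b in _BASES]
            n, base = max(counts)
            out.append(base if n > 0 else "A")
        return "".join(out)

    def insert_gaps(self, positions: Iterable[int]) -> None:
        """Insert a gap column before each original column index given
        (index == length appends); positions may repeat."""
        pos = sorted(positions)
        new_rows = []
        for row in self.rows:
            parts = []
            prev = 0
            for p in pos:
                parts.append(row[prev:p])
                parts.append("-")
                prev = p
            parts.append(row[prev:])
            new_rows.append("".join(parts))
        self.rows = new_rows


def _merge(p1: _Profile, p2: _Profile, match: float, mismatch: float,
           gap_open: float, gap_extend: float) -> _Profile:
    """Align two profiles via their consensus sequences and merge columns."""
    aligner = _global_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(p1.consensus(), p2.consensus())[0]
    # aligned coordinate blocks for each profile
    c1 = aln.coordinates[0]
    c2 = aln.coordinates[1]
    gaps1, gaps2 = [], []
    for k in range(len(c1) - 1):
        span1 = c1[k + 1] - c1[k]
        span2 = c2[k + 1] - c2[k]
        if span1 == 0:  # gap in profile 1 facing span2 columns of profile 2
            gaps1.extend([int(c1[k])] * int(span2))
        elif span2 == 0:
            gaps2.extend([int(c2[k])] * int(span1))
    p1.insert_gaps(gaps1)
    p2.insert_gaps(gaps2)
    assert p1.length == p2.length
    return _Profile(p1.ids + p2.ids, p1.rows + p2.rows)


def progressive_align(
    coll: LocusCollection,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -4,
    gap_extend: float = -1,
    passthrough: bool = False,
) -> Alignment:
    """Progressive multiple alignment of one locus' sequences.

    A guide tree is built by neighbor joining on pairwise k-mer distances;
    profiles are merged in the guide tree's post-order. With
    ``passthrough=True``, already-gapped equal-length input is returned
    unchanged (for externally aligned FASTA).
    """
    records = list(coll.records)
    if not records:
        raise ValueError("empty collection")
    if passthrough and any("-" in r.residues for r in records):
        return Alignment(coll.locus, [r.sample_id for r in records],
                         [r.residues for r in records])
    seqs = [r.ungapped for r in records]
    ids = [r.sample_id for r in records]
    if len(records) == 1:
        return Alignment(coll.locus, ids, seqs)
    if len(records) == 2:
        ga, gb, _ = pairwise_align(seqs[0], seqs[1], match, mismatch,
                                   gap_open, gap_extend)
        return Alignment(coll.locus, ids, [ga, gb])

    from barcodekit.distance import DistanceMatrix
    from barcodekit.njtree import nj

    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_distance(seqs[i], seqs[j])
    guide = nj(DistanceMatrix(ids=list(range(n)), values=d))

    def build(node) -> _Profile:
        if node.is_leaf:
            i = node.name
            return _Profile([ids[i]], [seqs[i]])
        profiles = [build(child) for child, _bl, _sup in node.children]
        merged = profiles[0]
        for p in profiles[1:]:
            merged = _merge(merged, p, match, mismatch, gap_open, gap_extend)
        return merged

    prof = build(guide.root)
    order = {sid: i for i, sid in enumerate(ids)}
    pairs = sorted(zip(prof.ids, prof.rows), key=lambda t: order[t[0]])
    return Alignment(coll.locus, [p[0] for p in pairs], [p[1] for p in pairs])


def concatenate(alignments: Sequence[Alignment], mode: str = "intersect") -> Alignment:
    """Concatenate per-locus alignments over their shared samples.

    Only samples present in every input are kept (``mode="intersect"`` is
    the sole mode: a multi-locus barcode exists only where all loci were
    sequenced). Column boundaries per locus are recorded.
    """
    if mode != "intersect":
        raise ValueError(f"unsupported mode {mode!r}")
    if len(alignments) < 2:
        raise ValueError("need at least two alignments to concatenate")
    shared = [sid for sid in alignments[0].ids
              if all(sid in a.ids for a in alignments[1:])]
    if not shared:
        raise ValueError("no samples shared by all loci")
    rows = []
    for sid in shared:
        rows.append("".join(a.row(sid) for a in alignments))
    boundaries = []
    offset = 0
    for a in alignments:
        boundaries.append((a.label, offset, offset + a.length))
        offset += a.length
    label = "+".join(a.label for a in alignments)
    return Alignment(label, shared, rows, boundaries)


def write_partition_table(aln: Alignment, path: str | Path) -> None:
    """Write the (locus, start, end) table beside a concatenation."""
    with open(path, "w") as fh:
        fh.write("locus\tstart\tend\n")
        for locus, start, end in aln.boundaries:
            fh.write(f"{locus}\t{start}\t{end}\n")
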