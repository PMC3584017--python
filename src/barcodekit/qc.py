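"""Sequence quality screens applied before any barcode analysis.

Three screens, mirroring standard Sanger-trace post-processing:

1. **Windowed QV trimming** — successive terminal windows (default 20 bp)
   containing at least 4 bases below QV 20 are removed from each end; the
   read is accepted only if the kept span is at least 60% of the original
   length and its mean QV is at least 30.
2. **Forward/reverse overlap** — the two reads of a bidirectional pair must
   cover more than 70% of their consensus span (a relaxed 50% floor can be
   configured for the occasional short overlap).
3. **5.8S motif screen** — nuclear ITS amplicons from plants carry the
   conserved 5.8S motif GAATTGCAGAATCC; the single-base variant
   GAATTGCAGAATTC indicates an endophytic-fungus amplicon instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

PLANT_MOTIF = "GAATTGCAGAATCC"
FUNGAL_MOTIF = "GAATTGCAGAATTC"


@dataclass
class QualityRead:
    """A called read with per-base Phred quality values."""

    read_id: str
    residues: str
    qualities: list[int]
    direction: str = "forward"

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.residues):
            raise ValueError(
                f"{self.read_id}: {len(self.qualities)} QVs for "
                f"{len(self.residues)} bases"
            )
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"{self.read_id}: bad direction {self.direction!r}")


@dataclass
class QcVerdict:
    """Outcome of trimming one read.

    ``trimmed_span`` is the half-open 0-based interval kept; ``mean_qv`` is
    computed over kept bases only.
    """

    accepted: bool
    trimmed_span: tuple[int, int]
    mean_qv: float
    reasons: list[str] = field(default_factory=list)

    @property
    def kept_length(self) -> int:
        return self.trimmed_span[1] - self.trimmed_span[0]


def window_trim(
    read: QualityRead,
    window: int = 20,
    bad_per_window: int = 4,
    qv_floor: int = 20,
    min_keep_frac: float = 0.60,
    min_mean_qv: float = 30.0,
) -> QcVerdict:
    """Trim low-quality ends and decide acceptance.

    From each end inward, whole terminal windows (of ``window`` bases, or
    the entire remaining span if shorter) are removed while they contain at
    least ``bad_per_window`` bases with QV below ``qv_floor``. Interior
    segments are never excised.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read.residues)
    if n == 0:
        raise ValueError(f"{read.read_id}: empty read")
    qv = read.qualities

    def n_bad(lo: int, hi: int) -> int:
        return sum(1 for q in qv[lo:hi] if q < qv_floor)

    left, right = 0, n
    while left < right:
        w = min(window, right - left)
        if n_bad(left, left + w) >= bad_per_window:
            left += w
        else:
            break
    while left < right:
        w = min(window, right - left)
        if n_bad(right - w, right) >= bad_per_window:
            right -= w
        else:
            break

    reasons: list[str] = []
    if left >= right:
        return QcVerdict(False, (0, 0), 0.0, ["all_trimmed"])
    kept = right - left
    mean_qv = sum(qv[left:right]) / kept
    if kept < min_keep_frac * n:
        reasons.append("short_after_trim")
    if mean_qv < min_mean_qv:
        reasons.append("low_mean_qv")
    return QcVerdict(not reasons, (left, right), mean_qv, reasons)


def _local_aligner(match: int = 1, mismatch: int = -1, gap: int = -2) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def overlap_coverage(fwd: str, rev: str, match: int = 1, mismatch: int = -1,
                     gap: int = -2) -> float:
    """Fraction of the consensus span covered by the fwd/rev overlap.

    ``rev`` is supplied in its own read orientation and reverse-complemented
    internally. The overlap is the best local alignment between the two
    reads; coverage = overlap columns / consensus-span length, where the
    consensus span is the union len(fwd) + len(rev) - overlap.
    """
    if not fwd or not rev:
        raise ValueError("empty sequence in read pair")
    rc = str(Seq(rev).reverse_complement())
    aln = _local_aligner(match, mismatch, gap).align(fwd.upper(), rc.upper())
    if len(aln) == 0:
        return 0.0
    overlap = aln[0].length
    consensus = len(fwd) + len(rev) - overlap
    if consensus <= 0:
        return 1.0
    return min(1.0, overlap / consensus)


def pair_usable(coverage: float, min_overlap: float = 0.70) -> bool:
    """Strict-greater-than rule on overlap coverage (default 70% floor)."""
    return coverage > min_overlap


def motif_screen(seq: str) -> str:
    """Classify an ITS/ITS2 sequence by its 5.8S motif.

    Returns ``"plant"``, ``"fungal"`` or ``"absent"``. Exact match on the
    forward strand only; if both variants occur, the fungal call wins and a
    warning is logged.
    """
    s = seq.upper()
    has_plant = PLANT_MOTIF in s
    has_fungal = FUNGAL_MOTIF in s
    if has_plant and has_fungal:
        logger.warning("sequence contains both plant and fungal 5.8S motifs")
        return "fungal"
    if has_fungal:
        return "fungal"
    if has_plant:
        return "plant"
    return "absent"


def read_fastq(path: str | Path, direction: str = "forward") -> list[QualityRead]:
    """Read Sanger-encoded (Phred+33) FASTQ into QualityReads."""
    reads = []
    for entry in SeqIO.parse(str(path), "fastq"):
        reads.append(
            QualityRead(
                read_id=entry.id,
                residues=str(entry.seq).upper(),
                qualities=list(entry.letter_annotations["phred_quality"]),
                direction=direction,
            )
        )
    return reads


def write_qc_report(verdicts: dict[str, QcVerdict], path: str | Path) -> None:
    """QC report TSV: read_id, kept span, mean QV, verdict, reasons."""
    with open(path, "w") as fh:
        fh.write("read_id\tkept_start\tkept_end\tmean_qv\taccepted\treasons\n")
        for rid, v in verdicts.items():
            fh.write(
                f"{rid}\t{v.trimmed_span[0]}\t{v.trimmed_span[1]}\t"
                f"{v.mean_qv:.2f}\t{v.accepted}\t{','.join(v.reasons)}\n"
            )
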