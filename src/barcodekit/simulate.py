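"""Synthetic multi-locus barcode datasets with controlled divergence.

The generator builds, per locus, a random root sequence for each genus;
species ancestors diverge from their genus root, and accessions diverge
from their species ancestor at the intra-specific rate (star phylogenies
at both levels). Rates are parametrized by the divergence each lineage
accumulates relative to a comparison partner: two accessions of one
species differ at ~2x ``intra_divergence``, two accessions of congeneric
species at ~2x ``inter_divergence`` (the species-ancestor branch therefore
carries ``inter - intra``), and species of different genera are
essentially unrelated. Setting ``intra_divergence == inter_divergence``
collapses the within/between distance distributions onto each other and
destroys the barcoding gap.
Substitutions are Jukes-Cantor-style: each site mutates independently with
the branch's rate, to a uniformly chosen different base. Optional indels,
ambiguity codes (N), singleton species, and per-locus sample dropout
exercise the partitioning, alignment, and pairwise-deletion logic.

A :class:`TruthTable` accompanies every dataset: realized per-species
maximum intra- and minimum inter-specific p-distances computed on the
substitution-only sequences (before indels and ambiguities, where
p-distance needs no alignment), plus the implied gap-resolvability flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from barcodekit.io import LocusCollection, SequenceRecord
from barcodekit.qc import QualityRead

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``accessions_per_species`` may be a single int or a per-species list
    (length n_genera * species_per_genus); a count of 1 creates a
    singleton species. Rates are per-site probabilities on one branch.
    """

    n_genera: int = 5
    species_per_genus: int = 2
    accessions_per_species: int | Sequence[int] = 3
    locus_lengths: dict[str, int] = field(
        default_factory=lambda: {"ITS": 600, "trnH-psbA": 400}
    )
    inter_divergence: float = 0.05
    intra_divergence: float = 0.005
    indel_rate: float = 0.0
    ambiguity_rate: float = 0.0
    locus_dropout: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genera < 1:
            problems.append("n_genera must be >= 1")
        if self.species_per_genus < 1:
            problems.append("species_per_genus must be >= 1")
        n_species = self.n_genera * self.species_per_genus
        acc = self.accessions_per_species
        if isinstance(acc, int):
            if acc < 1:
                problems.append("accessions_per_species must be >= 1")
        elif len(acc) != n_species:
            problems.append(
                f"accessions_per_species list must have {n_species} entries"
            )
        if not self.locus_lengths:
            problems.append("locus_lengths must name at least one locus")
        for locus, L in self.locus_lengths.items():
            if L < 50:
                problems.append(f"locus {locus}: length must be >= 50")
        if not 0 <= self.intra_divergence <= self.inter_divergence <= 0.75:
            problems.append(
                "need 0 <= intra_divergence <= inter_divergence <= 0.75"
            )
        for name in ("indel_rate", "ambiguity_rate", "locus_dropout"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                problems.append(f"{name} must be in [0, 1)")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    @property
    def accession_counts(self) -> list[int]:
        n_species = self.n_genera * self.species_per_genus
        acc = self.accessions_per_species
        if isinstance(acc, int):
            return [acc] * n_species
        return list(acc)


@dataclass
class TruthTable:
    """Realized divergence structure of a generated dataset."""

    frame: pd.DataFrame  # locus, species, max_intra, min_inter, resolvable

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # shift by 1..3 in base space: uniform over the 3 alternatives
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    chars = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        chars.append(ch)
        if r >= rate / 2 and r < rate:  # insertion after this site
            chars.append(str(rng.choice(_BASES)))
    return "".join(chars) or seq[:1]


def _apply_ambiguity(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    chars = np.array(list(seq))
    mask = rng.random(chars.size) < rate
    chars[mask] = "N"
    return "".join(chars)


def _p_dist_codes(a: np.ndarray, b: np.ndarray) -> float:
    return float((a != b).mean())


def generate(spec: SyntheticSpec) -> tuple[dict[str, LocusCollection], TruthTable]:
    """Generate per-locus collections plus their realized truth table.

    Deterministic given ``spec.seed``; the same spec yields byte-identical
    FASTA on rewrite.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = spec.accession_counts

    # species labels: genus Gxx, species "Gxx spyy"
    species_names = []
    for g in range(spec.n_genera):
        genus = f"Genus{g + 1:02d}"
        for s in range(spec.species_per_genus):
            species_names.append(f"{genus} species{s + 1:02d}")

    collections: dict[str, LocusCollection] = {}
    truth_rows = []
    for locus, L in spec.locus_lengths.items():
        clean_seqs: dict[str, np.ndarray] = {}
        species_of: dict[str, str] = {}
        records = []
        sp_idx = 0
        for g in range(spec.n_genera):
            root = rng.integers(0, 4, size=L)
            for _s in range(spec.species_per_genus):
                sp = species_names[sp_idx]
                ancestor = _mutate(
                    root, spec.inter_divergence - spec.intra_divergence, rng)
                for a in range(counts[sp_idx]):
                    sid = f"G{g + 1:02d}S{_s + 1:02d}A{a + 1:02d}"
                    codes = _mutate(ancestor, spec.intra_divergence, rng)
                    clean_seqs[sid] = codes
                    species_of[sid] = sp
                    seq = "".join(_BASES[codes])
                    seq = _apply_indels(seq, spec.indel_rate, rng)
                    seq = _apply_ambiguity(seq, spec.ambiguity_rate, rng)
                    if spec.locus_dropout and rng.random() < spec.locus_dropout:
                        continue
                    records.append(SequenceRecord(
                        sample_id=sid, species=sp, locus=locus, residues=seq,
                    ))
                sp_idx += 1
        collections[locus] = LocusCollection(locus, records)

        # realized truth on substitution-only sequences
        ids = list(clean_seqs)
        for sp in species_names:
            own = [i for i in ids if species_of[i] == sp]
            others = [i for i in ids if species_of[i] != sp]
            intra = [_p_dist_codes(clean_seqs[a], clean_seqs[b])
                     for k, a in enumerate(own) for b in own[k + 1:]]
            inter = [_p_dist_codes(clean_seqs[a], clean_seqs[b])
                     for a in own for b in others]
            max_intra = max(intra) if intra else float("nan")
            min_inter = min(inter) if inter else float("nan")
            truth_rows.append({
                "locus": locus,
                "species": sp,
                "n_accessions": len(own),
                "max_intra": max_intra,
                "min_inter": min_inter,
                "resolvable": bool(intra and inter and min_inter > max_intra),
            })
    return collections, TruthTable(pd.DataFrame(truth_rows))


def generate_quality_reads(
    coll: LocusCollection,
    qv_profile: str = "clean",
    seed: int = 0,
    overlap_fraction: float = 0.8,
    noisy_tail: int = 25,
) -> list[tuple[QualityRead, QualityRead]]:
    """Forward/reverse read pairs over a collection's sequences.

    Each pair covers the template so the forward and reverse reads overlap
    by ``overlap_fraction`` of its length. ``qv_profile``:

    * ``"clean"`` — QV 40 everywhere (passes every screen);
    * ``"noisy_ends"`` — ``noisy_tail`` terminal bases at QV 10 on each
      read's far end (triggers window trimming).
    """
    if qv_profile not in ("clean", "noisy_ends"):
        raise ValueError(f"unknown qv_profile {qv_profile!r}")
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    comp = str.maketrans("ACGTN", "TGCAN")
    pairs = []
    for rec in coll:
        seq = rec.ungapped
        L = len(seq)
        read_len = int(round(L * (1 + overlap_fraction) / 2))
        fwd_seq = seq[:read_len]
        rev_templ = seq[L - read_len:]
        rev_seq = rev_templ.translate(comp)[::-1]
        if qv_profile == "clean":
            fq = [40] * len(fwd_seq)
            rq = [40] * len(rev_seq)
        else:
            t = min(noisy_tail, len(fwd_seq))
            fq = [40] * (len(fwd_seq) - t) + [10] * t
            rq = [40] * (len(rev_seq) - t) + [10] * t
        pairs.append((
            QualityRead(f"{rec.sample_id}_F", fwd_seq, fq, "forward"),
            QualityRead(f"{rec.sample_id}_R", rev_seq, rq, "reverse"),
        ))
    return pairs


def write_fastq(reads: Sequence[QualityRead], path: str | Path) -> None:
    """Write reads as Sanger Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.residues}\n+\n{quals}\n")
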