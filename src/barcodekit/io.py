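"""Sequence records, FASTA/metadata I/O, and the three analysis data sets.

Specimens are read from plain FASTA plus a tab-delimited metadata table
(``sample_id``, ``species``, ``locus``, ``source``); the FASTA header (first
whitespace-delimited token) must match a metadata ``sample_id``. Keeping
taxonomy out of the FASTA description line avoids fragile header parsing.

The three data sets used throughout barcode evaluation are:

* **set 1** — every sample,
* **set 2** — samples of species represented by at least two accessions,
* **set 3** — samples of congeneric species, each species itself with at
  least two accessions.

Set 2 is where intra-specific divergence is measurable; set 3 restricts to
the hardest case, closely related species in the same genus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

KNOWN_LOCI = ("ITS", "ITS2", "rbcL", "trnH-psbA", "matK")

#: IUPAC DNA codes plus gap; 'U' is canonicalised to 'T' on input.
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")


@dataclass(frozen=True)
class SequenceRecord:
    """One specimen's sequence at one locus, with its species label.

    ``genus`` is derived: the first whitespace-delimited token of the
    species binomial. ``source`` distinguishes newly generated sequences
    (``study``) from database supplements (``external``); both are pooled
    identically in every analysis.
    """

    sample_id: str
    species: str
    locus: str
    residues: str
    source: str = "study"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.sample_id}: empty sequence")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.sample_id}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.source not in ("study", "external"):
            raise ValueError(f"{self.sample_id}: bad source {self.source!r}")

    @property
    def genus(self) -> str:
        return self.species.split()[0]

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


class LocusCollection:
    """An ordered set of records for one locus, unique by sample id."""

    def __init__(self, locus: str, records: Iterable[SequenceRecord] = ()):
        self.locus = locus
        self.records: list[SequenceRecord] = []
        self._by_id: dict[str, SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.locus != self.locus:
            raise ValueError(
                f"record {rec.sample_id} has locus {rec.locus!r}, "
                f"collection is {self.locus!r}"
            )
        if rec.sample_id in self._by_id:
            raise ValueError(f"duplicate sample_id {rec.sample_id!r}")
        self.records.append(rec)
        self._by_id[rec.sample_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SequenceRecord:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def species_of(self) -> dict[str, str]:
        return {r.sample_id: r.species for r in self.records}

    def species_counts(self) -> Counter:
        return Counter(r.species for r in self.records)

    def subset(self, sample_ids: Iterable[str]) -> "LocusCollection":
        keep = set(sample_ids)
        return LocusCollection(
            self.locus, (r for r in self.records if r.sample_id in keep)
        )


@dataclass
class DatasetPartition:
    """The three nested analysis data sets (set3 ⊆ set2 ⊆ set1)."""

    set1: LocusCollection
    set2: LocusCollection
    set3: LocusCollection

    def __getitem__(self, name: str) -> LocusCollection:
        try:
            return {"set1": self.set1, "set2": self.set2, "set3": self.set3}[name]
        except KeyError:
            raise KeyError(f"unknown data set {name!r}") from None

    def items(self):
        return [("set1", self.set1), ("set2", self.set2), ("set3", self.set3)]


def _canonical(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read the tab-delimited metadata table, keyed by sample_id."""
    rows: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "species", "locus"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or ())
            raise ValueError(f"metadata {path}: missing columns {sorted(missing)}")
        for row in reader:
            sid = row["sample_id"]
            if sid in rows:
                raise ValueError(f"metadata {path}: duplicate sample_id {sid!r}")
            rows[sid] = row
    return rows


def read_fasta(path: str | Path, metadata: str | Path) -> LocusCollection:
    """Read one locus' FASTA plus its metadata table into a collection.

    Residues are upper-cased and 'U' mapped to 'T'. A FASTA header with no
    metadata row, or a duplicated header, is a hard error naming the id.
    """
    meta = read_metadata(metadata)
    records = []
    loci = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        sid = entry.id
        if sid not in meta:
            raise ValueError(f"FASTA header {sid!r} has no metadata row in {metadata}")
        row = meta[sid]
        loci.add(row["locus"])
        records.append(
            SequenceRecord(
                sample_id=sid,
                species=row["species"],
                locus=row["locus"],
                residues=_canonical(str(entry.seq)),
                source=row.get("source", "study") or "study",
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    if len(loci) > 1:
        raise ValueError(f"{path}: mixed loci {sorted(loci)} in one FASTA")
    return LocusCollection(loci.pop(), records)


def write_fasta(coll: LocusCollection, fasta_path: str | Path,
                metadata_path: str | Path | None = None, width: int = 70) -> None:
    """Write a collection as FASTA (+ optional metadata TSV)."""
    with open(fasta_path, "w") as fh:
        for rec in coll:
            fh.write(f">{rec.sample_id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
    if metadata_path is not None:
        write_metadata(coll, metadata_path)


def write_metadata(coll: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "species", "locus", "source"])
        for rec in coll:
            writer.writerow([rec.sample_id, rec.species, rec.locus, rec.source])


def partition_datasets(
    coll: LocusCollection, congener_rule: str = "multi_accession"
) -> DatasetPartition:
    """Split a collection into the three nested analysis data sets.

    Parameters
    ----------
    coll
        All records for one locus.
    congener_rule
        How set 3 decides that a multi-accession species has a usable
        congener: ``"multi_accession"`` (default) requires the congener
        itself to have >= 2 accessions; ``"any"`` accepts any species in
        the same genus, singleton or not.
    """
    if congener_rule not in ("multi_accession", "any"):
        raise ValueError(f"unknown congener_rule {congener_rule!r}")
    counts = coll.species_counts()
    multi = {sp for sp, n in counts.items() if n >= 2}

    genus_of = {sp: sp.split()[0] for sp in counts}
    if congener_rule == "multi_accession":
        candidate_congeners = multi
    else:
        candidate_congeners = set(counts)
    genus_pool = Counter(genus_of[sp] for sp in candidate_congeners)

    def in_set3(sp: str) -> bool:
        if sp not in multi:
            return False
        g = genus_of[sp]
        # at least one OTHER species of the same genus in the congener pool
        others = genus_pool[g] - (1 if sp in candidate_congeners else 0)
        return others >= 1

    set3_species = {sp for sp in counts if in_set3(sp)}
    set2 = LocusCollection(coll.locus, (r for r in coll if r.species in multi))
    set3 = LocusCollection(coll.locus, (r for r in coll if r.species in set3_species))
    set1 = LocusCollection(coll.locus, coll.records)
    return DatasetPartition(set1=set1, set2=set2, set3=set3)
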