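"""Uncorrected p-distances under pairwise deletion, and alignment summaries.

The p-distance between two aligned rows is the fraction of differing sites
among the sites compared; under pairwise deletion a column contributes only
if BOTH rows carry an unambiguous base (A/C/G/T). Ambiguity codes are, by
default, treated like gaps (excluded); the ``partial_match`` policy instead
counts a column where one row's IUPAC code includes the other row's base as
a match. A pair sharing zero comparable columns has no defined distance and
is reported as missing (NaN).

Summary statistics follow the usual barcode-literature conventions: percentage
of variable columns (>= 2 distinct unambiguous bases present), percentage
of parsimony-informative columns (>= 2 distinct bases each in >= 2 rows),
mean ungapped sequence length, and mean inter-/intra-specific divergence.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np

from barcodekit.align import Alignment
from barcodekit.io import LocusCollection

logger = logging.getLogger(__name__)

_CODE = {b: i for i, b in enumerate("ACGT")}

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distances; missing entries are NaN."""

    ids: list[Hashable]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} for {n} ids")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix not symmetric")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: Hashable, b: Hashable) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    @property
    def n_missing(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(
                    "NA" if np.isnan(v) else f"{v:.6f}" for v in self.values[i]
                )
                fh.write(f"{sid}\t{row}\n")

    def to_long_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\tp_distance\n")
            for i, j in itertools.combinations(range(len(self.ids)), 2):
                v = self.values[i, j]
                fh.write(f"{self.ids[i]}\t{self.ids[j]}\t"
                         f"{'NA' if np.isnan(v) else f'{v:.6f}'}\n")


def encode_rows(rows: Sequence[str], ambiguity: str = "missing") -> np.ndarray:
    """Encode aligned rows as int8: A/C/G/T -> 0..3, everything else -> -1.

    Only the ``missing`` policy is vectorisable this way; ``partial_match``
    pairs are handled column-wise in :func:`p_distance`.
    """
    if ambiguity != "missing":
        raise ValueError("encode_rows supports the 'missing' policy only")
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    arr = arr.reshape(len(rows), -1)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def p_distance(row_a: str, row_b: str, ambiguity: str = "missing") -> float:
    """p-distance between two gapped rows under pairwise deletion.

    Returns NaN when no column is comparable. Unequal lengths are a hard
    error: the rows must come from one alignment.
    """
    if len(row_a) != len(row_b):
        raise ValueError(
            f"rows of unequal length ({len(row_a)} vs {len(row_b)})"
        )
    if ambiguity == "missing":
        compared = mismatches = 0
        for x, y in zip(row_a.upper(), row_b.upper()):
            if x in _CODE and y in _CODE:
                compared += 1
                if x != y:
                    mismatches += 1
    elif ambiguity == "partial_match":
        compared = mismatches = 0
        for x, y in zip(row_a.upper(), row_b.upper()):
            sx, sy = _IUPAC_SETS.get(x), _IUPAC_SETS.get(y)
            if sx is None or sy is None or (len(sx) == 4 and len(sy) == 4):
                continue
            compared += 1
            if not set(sx) & set(sy):
                mismatches += 1
    else:
        raise ValueError(f"unknown ambiguity policy {ambiguity!r}")
    if compared == 0:
        return float("nan")
    return mismatches / compared


def distance_matrix(aln: Alignment, ambiguity: str = "missing") -> DistanceMatrix:
    """All-pairs p-distance matrix for an alignment (missing -> NaN)."""
    if len(aln) < 2:
        raise ValueError("need >= 2 rows")
    if ambiguity == "missing":
        X = encode_rows(aln.rows)
        valid = X >= 0
        # pairwise comparable-site and mismatch counts by broadcasting
        comp = (valid[:, None, :] & valid[None, :, :]).sum(axis=2)
        diff = ((X[:, None, :] != X[None, :, :])
                & valid[:, None, :] & valid[None, :, :]).sum(axis=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = np.where(comp > 0, diff / np.maximum(comp, 1), np.nan)
        np.fill_diagonal(d, 0.0)
    else:
        n = len(aln)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = p_distance(aln.rows[i], aln.rows[j], ambiguity)
    dm = DistanceMatrix(ids=list(aln.ids), values=d)
    if dm.n_missing:
        logger.warning("%s: %d pair(s) share no comparable sites",
                       aln.label, dm.n_missing)
    return dm


def site_classes(aln: Alignment) -> tuple[float, float]:
    """(% variable columns, % parsimony-informative columns).

    A column is variable when >= 2 distinct unambiguous bases occur;
    parsimony-informative when >= 2 distinct bases each occur in >= 2 rows.
    Gaps and ambiguity codes are ignored within a column.
    """
    if len(aln) == 0 or aln.length == 0:
        return 0.0, 0.0
    X = encode_rows(aln.rows)
    counts = np.stack([(X == c).sum(axis=0) for c in range(4)])  # 4 x L
    n_distinct = (counts > 0).sum(axis=0)
    n_common = (counts >= 2).sum(axis=0)
    variable = n_distinct >= 2
    pic = n_common >= 2
    L = aln.length
    return 100.0 * variable.sum() / L, 100.0 * pic.sum() / L


@dataclass
class DivergenceSummary:
    """Mean inter- and intra-specific p-distance with per-species detail."""

    mean_interspecific: float
    mean_intraspecific: float
    intra_by_species: dict[str, list[float]]
    inter_by_species: dict[str, list[float]]

    @property
    def intra_distances(self) -> list[float]:
        return [d for v in self.intra_by_species.values() for d in v]


def divergence_summary(
    dm: DistanceMatrix,
    species_of: Mapping[Hashable, str],
    weighting: str = "pairs",
) -> DivergenceSummary:
    """Mean inter/intra-specific divergence over a distance matrix.

    ``weighting="pairs"`` (default) averages over all pairs; ``"species"``
    averages each species' mean first, then averages species. Pairs with
    missing distance are skipped. With no multi-accession species the
    intra-specific mean is NaN.
    """
    if weighting not in ("pairs", "species"):
        raise ValueError(f"unknown weighting {weighting!r}")
    species = [species_of[sid] for sid in dm.ids]
    if len(set(species)) < 2:
        raise ValueError("need >= 2 species")
    intra: dict[str, list[float]] = {}
    inter: dict[str, list[float]] = {}
    for i, j in itertools.combinations(range(len(dm.ids)), 2):
        d = dm.values[i, j]
        if np.isnan(d):
            continue
        if species[i] == species[j]:
            intra.setdefault(species[i], []).append(float(d))
        else:
            inter.setdefault(species[i], []).append(float(d))
            inter.setdefault(species[j], []).append(float(d))

    def _mean(groups: dict[str, list[float]]) -> float:
        # inter pairs appear under both species; duplication leaves the
        # pair-weighted mean unchanged
        if not groups:
            return float("nan")
        if weighting == "species":
            return float(np.mean([np.mean(v) for v in groups.values()]))
        return float(np.mean([d for v in groups.values() for d in v]))

    return DivergenceSummary(
        mean_interspecific=_mean(inter),
        mean_intraspecific=_mean(intra),
        intra_by_species=intra,
        inter_by_species=inter,
    )


@dataclass
class LocusSummary:
    """Per-locus per-dataset table-style statistics."""

    locus: str
    n_sequences: int
    n_species: int
    mean_length: float
    sd_length: float
    pct_variable: float
    pct_pic: float


def locus_summary(coll: LocusCollection, aln: Alignment) -> LocusSummary:
    """Summary statistics for one locus/data set.

    Mean length is over ungapped input sequences (per-sequence semantics);
    site classes are over alignment columns.
    """
    lengths = [len(r.ungapped) for r in coll]
    pct_var, pct_pic = site_classes(aln)
    return LocusSummary(
        locus=coll.locus,
        n_sequences=len(coll),
        n_species=len(coll.species_counts()),
        mean_length=float(np.mean(lengths)),
        sd_length=float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0,
        pct_variable=pct_var,
        pct_pic=pct_pic,
    )
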