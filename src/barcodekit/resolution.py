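"""Non-tree species-discrimination methods and report assembly.

**Barcoding gap** — a multi-accession species is resolved when its minimum
inter-specific p-distance (to any sample of any other species) strictly
exceeds its maximum intra-specific p-distance.

**Best-match identification** — emulates querying each sequence against a
self database (leave-one-out): every query is scored against all reference
records except itself; identification is correct when all top-scoring hits
belong to the query's species, ambiguous when the top ties span species. A
species counts as identified only when all of its queries are correct
(configurable to any-query or majority rules).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align as _bioalign

from barcodekit.distance import DistanceMatrix, p_distance
from barcodekit.io import LocusCollection

logger = logging.getLogger(__name__)


@dataclass
class SpeciesGapSummary:
    """Per-species barcoding-gap verdict."""

    species: str
    n_accessions: int
    max_intra: float
    min_inter: float
    resolved: bool


def gap_resolution(
    dm: DistanceMatrix, species_of: Mapping[Hashable, str]
) -> tuple[list[SpeciesGapSummary], float]:
    """Barcoding-gap resolution over all multi-accession species.

    Returns the per-species summaries and the percentage resolved
    (strict ``min_inter > max_intra``), computed over multi-accession
    species only. Pairs with missing distances are skipped.
    """
    species = [species_of[sid] for sid in dm.ids]
    by_sp: dict[str, list[int]] = {}
    for idx, sp in enumerate(species):
        by_sp.setdefault(sp, []).append(idx)
    multi = {sp: idxs for sp, idxs in by_sp.items() if len(idxs) >= 2}
    if not multi:
        raise ValueError("no multi-accession species")

    summaries = []
    for sp in sorted(multi):
        idxs = multi[sp]
        intra = [dm.values[i, j] for i, j in itertools.combinations(idxs, 2)]
        others = [k for k, s in enumerate(species) if s != sp]
        inter = [dm.values[i, k] for i in idxs for k in others]
        intra = [d for d in intra if not np.isnan(d)]
        inter = [d for d in inter if not np.isnan(d)]
        max_intra = max(intra) if intra else float("nan")
        min_inter = min(inter) if inter else float("nan")
        resolved = bool(
            not np.isnan(max_intra) and not np.isnan(min_inter)
            and min_inter > max_intra
        )
        summaries.append(SpeciesGapSummary(
            species=sp, n_accessions=len(idxs),
            max_intra=float(max_intra), min_inter=float(min_inter),
            resolved=resolved,
        ))
    pct = 100.0 * sum(s.resolved for s in summaries) / len(summaries)
    return summaries, pct


def gap_scatter(summaries: Sequence[SpeciesGapSummary]) -> pd.DataFrame:
    """Scatter table (one point per species) for barcode-gap plots.

    The frame carries ``gap_exists`` in ``.attrs``: True only when every
    point lies strictly above the y = x diagonal (min_inter > max_intra),
    plus ``n_above``, the count of points above the diagonal.
    """
    if not summaries:
        raise ValueError("no gap summaries")
    df = pd.DataFrame(
        {
            "species": [s.species for s in summaries],
            "max_intra": [s.max_intra for s in summaries],
            "min_inter": [s.min_inter for s in summaries],
        }
    )
    above = df["min_inter"] > df["max_intra"]
    df["above_diagonal"] = above
    df.attrs["gap_exists"] = bool(above.all())
    df.attrs["n_above"] = int(above.sum())
    return df


@dataclass
class IdentificationResult:
    """Outcome of one leave-one-out query against the self database."""

    query_id: str
    species: str
    best_hits: list[str]
    best_score: float
    status: str  # correct | incorrect | ambiguous


def _local_score_matrix(queries: Sequence[str], refs: Sequence[str],
                        match: float = 1, mismatch: float = -1,
                        gap_open: float = -2, gap_extend: float = -2) -> np.ndarray:
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    out = np.empty((len(queries), len(refs)))
    for i, q in enumerate(queries):
        for j, r in enumerate(refs):
            out[i, j] = aligner.score(q, r)
    return out


def best_match_identify(
    queries: LocusCollection,
    reference: LocusCollection,
    scorer: str = "local_align",
    species_rule: str = "all",
) -> tuple[list[IdentificationResult], float]:
    """Leave-one-out best-match identification against a self database.

    Every query (normally data set 2 or 3) must itself be present in the
    reference (data set 1); its own record is excluded by sample id, so
    identical sequences from different specimens remain legitimate hits.

    ``scorer``: ``"local_align"`` (BLAST-like local alignment score, ties at
    the maximum) or ``"p_distance"`` (p-distance over a pairwise global
    alignment, ties at the minimum).
    ``species_rule``: a species is identified when ``"all"`` (default),
    ``"any"`` or a ``"majority"`` of its queries are correct.
    """
    if scorer not in ("local_align", "p_distance"):
        raise ValueError(f"unknown scorer {scorer!r}")
    if species_rule not in ("all", "any", "majority"):
        raise ValueError(f"unknown species_rule {species_rule!r}")
    if len(reference) < 2:
        raise ValueError("reference needs >= 2 records")
    for q in queries:
        if q.sample_id not in reference:
            raise ValueError(f"query {q.sample_id!r} not in the self database")

    ref_ids = reference.sample_ids
    ref_species = [r.species for r in reference]
    q_seqs = [q.ungapped for q in queries]
    r_seqs = [r.ungapped for r in reference]

    if scorer == "local_align":
        scores = _local_score_matrix(q_seqs, r_seqs)
        better = np.greater
    else:
        from barcodekit.align import pairwise_align

        scores = np.empty((len(q_seqs), len(r_seqs)))
        for i, q in enumerate(q_seqs):
            for j, r in enumerate(r_seqs):
                ga, gb, _ = pairwise_align(q, r)
                scores[i, j] = p_distance(ga, gb)
        better = np.less

    results = []
    correct_by_sp: dict[str, list[bool]] = {}
    for i, q in enumerate(queries):
        row = scores[i].copy()
        self_j = ref_ids.index(q.sample_id)
        row[self_j] = np.nan
        valid = ~np.isnan(row)
        best = row[valid].max() if better is np.greater else row[valid].min()
        hit_js = [j for j in range(len(ref_ids))
                  if valid[j] and row[j] == best]
        hit_species = {ref_species[j] for j in hit_js}
        if hit_species == {q.species}:
            status = "correct"
        elif q.species in hit_species:
            status = "ambiguous"
        else:
            status = "incorrect"
        if not any(sp == q.species and j != self_j
                   for j, sp in enumerate(ref_species)):
            logger.warning("query %s: no same-species reference after "
                           "self-exclusion", q.sample_id)
        results.append(IdentificationResult(
            query_id=q.sample_id, species=q.species,
            best_hits=[ref_ids[j] for j in hit_js],
            best_score=float(best), status=status,
        ))
        correct_by_sp.setdefault(q.species, []).append(status == "correct")

    def identified(flags: list[bool]) -> bool:
        if species_rule == "all":
            return all(flags)
        if species_rule == "any":
            return any(flags)
        return sum(flags) > len(flags) / 2

    n_sp = len(correct_by_sp)
    pct = 100.0 * sum(identified(v) for v in correct_by_sp.values()) / n_sp
    return results, pct


@dataclass
class ResolutionReport:
    """Per (locus/combination, data set, method) discrimination percentages."""

    rows: list[dict] = field(default_factory=list)

    def add(self, locus_or_combo: str, dataset: str, method: str,
            pct_resolved: float, n_species: int, detail=None) -> None:
        if not 0.0 <= pct_resolved <= 100.0:
            raise ValueError(f"percentage out of range: {pct_resolved}")
        self.rows.append({
            "locus_or_combo": locus_or_combo,
            "dataset": dataset,
            "method": method,
            "pct_resolved": pct_resolved,
            "n_species": n_species,
            "detail": detail,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: v for k, v in row.items() if k != "detail"}
             for row in self.rows]
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df["pct_resolved"] = df["pct_resolved"].map(lambda p: f"{p:.1f}")
        df.to_csv(path, sep="\t", index=False)
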