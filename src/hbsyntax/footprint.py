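"""Phylogenetic footprinting of motif pairs in orthologue alignments.

Each orthologous element comes as a multiple alignment of 2-30 vertebrate
sequences.  Every row is scanned in its own ungapped coordinates, hits are
projected onto alignment columns, and hits from different species whose
column intervals overlap are clustered into a single putative occurrence.
An occurrence is "positionally conserved" when the fraction of species
supporting it reaches ``min_fraction`` (1.0 = present in every aligned
species).

A candidate enhancer verdict combines three criteria: (a) significant
matches to both motifs, (b) the two motifs within ``max_dist`` bases of one
another in the reference species, and (c) positional conservation across
the aligned species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .motifs import IupacMotif, MotifHit, PositionWeightMatrix, scan_consensus, scan_pwm

logger = logging.getLogger(__name__)

GAP_CHARS = "-."


@dataclass
class AlignmentBlock:
    """One orthologous element: species -> aligned row (with gap characters)."""

    element_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows of {self.element_id} have unequal aligned lengths")
        if not self.rows:
            raise ValueError("alignment needs at least one row")

    @property
    def n_species(self) -> int:
        return len(self.rows)

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, species: str) -> str:
        row = self.rows[species]
        return "".join(c for c in row if c not in GAP_CHARS)


def build_column_maps(aligned_row: str) -> tuple[np.ndarray, np.ndarray]:
    """Bidirectional map between non-gap alignment columns and ungapped positions.

    Returns ``(col_of_pos, pos_of_col)``: ``col_of_pos[p]`` is the column
    holding ungapped position ``p``; ``pos_of_col[c]`` is the ungapped
    position at column ``c`` or -1 at a gap.
    """
    pos_of_col = np.full(len(aligned_row), -1, dtype=np.int64)
    col_of_pos = []
    p = 0
    for c, ch in enumerate(aligned_row):
        if ch not in GAP_CHARS:
            pos_of_col[c] = p
            col_of_pos.append(c)
            p += 1
    return np.asarray(col_of_pos, dtype=np.int64), pos_of_col


@dataclass
class ConservedMotifOccurrence:
    """Hits of one motif, clustered across species by alignment-column overlap."""

    motif_name: str
    col_start: int
    col_end: int  # half-open in alignment columns
    per_species_hits: dict[str, MotifHit]
    n_species: int

    @property
    def n_supporting(self) -> int:
        return len(self.per_species_hits)

    def is_conserved(self, min_fraction: float = 1.0) -> bool:
        return self.n_supporting / self.n_species >= min_fraction


def _scan_row(seq: str, motif, *, seq_id: str, p_threshold: float) -> list[MotifHit]:
    if isinstance(motif, PositionWeightMatrix):
        return scan_pwm(seq, motif, p_threshold=p_threshold, seq_id=seq_id)
    if isinstance(motif, IupacMotif):
        return scan_consensus(seq, motif, seq_id=seq_id)
    raise TypeError(f"motif must be IupacMotif or PositionWeightMatrix, got {type(motif)}")


def conserved_occurrences(block: AlignmentBlock, motif, *,
                          p_threshold: float = 0.001,
                          min_fraction: float | None = None
                          ) -> list[ConservedMotifOccurrence]:
    """Scan every species row ungapped, project to columns and cluster.

    Returns all clustered occurrences sorted by column; filter with
    ``min_fraction`` (keep those with support fraction >= it) when given.
    A motif longer than the shortest ungapped row simply finds nothing
    there (logged at debug level).
    """
    projected: list[tuple[int, int, str, MotifHit]] = []
    for species, row in block.rows.items():
        seq = block.ungapped(species)
        if len(seq) < _motif_len(motif):
            logger.debug("%s: row %s shorter than motif", block.element_id, species)
            continue
        col_of_pos, _ = build_column_maps(row)
        for h in _scan_row(seq.upper(), motif, seq_id=species, p_threshold=p_threshold):
            cs = int(col_of_pos[h.start])
            ce = int(col_of_pos[h.end - 1]) + 1
            projected.append((cs, ce, species, h))
    projected.sort(key=lambda t: (t[0], t[1]))
    occurrences: list[ConservedMotifOccurrence] = []
    cur: ConservedMotifOccurrence | None = None
    for cs, ce, species, h in projected:
        if cur is not None and cs < cur.col_end:  # overlaps current cluster
            cur.col_end = max(cur.col_end, ce)
            cur.per_species_hits.setdefault(species, h)
        else:
            cur = ConservedMotifOccurrence(_motif_name(motif), cs, ce,
                                           {species: h}, block.n_species)
            occurrences.append(cur)
    if min_fraction is not None:
        occurrences = [o for o in occurrences if o.is_conserved(min_fraction)]
    return occurrences


def _motif_len(motif) -> int:
    return len(motif)


def _motif_name(motif) -> str:
    return motif.name


def _ungapped_gap(a: MotifHit, b: MotifHit) -> int:
    """Intervening bases between two hits in one species; 0 if they touch/overlap."""
    if b.start >= a.end:
        return b.start - a.end
    if a.start >= b.end:
        return a.start - b.end
    return 0


def pairwise_distances(block: AlignmentBlock, occ_a: ConservedMotifOccurrence,
                       occ_b: ConservedMotifOccurrence
                       ) -> tuple[dict[str, int], int | None]:
    """Per-species ungapped distance between two occurrences, and the maximum.

    Only species carrying both hits contribute; the distance is measured in
    each species' own ungapped coordinates.
    """
    per_species: dict[str, int] = {}
    for sp in block.rows:
        ha = occ_a.per_species_hits.get(sp)
        hb = occ_b.per_species_hits.get(sp)
        if ha is not None and hb is not None:
            per_species[sp] = _ungapped_gap(ha, hb)
    max_dist = max(per_species.values()) if per_species else None
    return per_species, max_dist


def bin_distance_profile(distances: Sequence[float]) -> dict[str, int]:
    """Cumulative distance bins: < 25, < 50, < 100 bp, and >= 100 bp."""
    d = np.asarray(distances, dtype=float)
    return {
        "lt25": int((d < 25).sum()),
        "lt50": int((d < 50).sum()),
        "lt100": int((d < 100).sum()),
        "ge100": int((d >= 100).sum()),
    }


@dataclass(frozen=True)
class CandidateVerdict:
    """Three-criterion classification of one aligned element."""

    element_id: str
    has_pbxhox: bool
    has_meis: bool
    within_100bp: bool
    conserved_all: bool
    reference_distance: int | None = None
    max_distance: int | None = None

    @property
    def verdict(self) -> bool:
        return (self.has_pbxhox and self.has_meis
                and self.within_100bp and self.conserved_all)


def classify_candidate(block: AlignmentBlock, pbxhox_motif, meis_motif, *,
                       p_threshold: float = 0.001, max_dist: int = 100,
                       min_fraction: float = 1.0,
                       reference: str | None = None) -> CandidateVerdict:
    """Apply the candidate criteria to one aligned element.

    (a) both motifs present (significant matches at ``p_threshold`` in PWM
    mode) in the reference species; (b) a pair of them within ``max_dist``
    ungapped bases in the reference species; (c) both motifs positionally
    conserved across species at ``min_fraction``.  ``reference`` defaults
    to the first row.
    """
    if reference is None:
        reference = next(iter(block.rows))
    occs_p = conserved_occurrences(block, pbxhox_motif, p_threshold=p_threshold)
    occs_m = conserved_occurrences(block, meis_motif, p_threshold=p_threshold)
    ref_p = [o.per_species_hits[reference] for o in occs_p
             if reference in o.per_species_hits]
    ref_m = [o.per_species_hits[reference] for o in occs_m
             if reference in o.per_species_hits]
    has_p, has_m = bool(ref_p), bool(ref_m)
    ref_dist = None
    for hp in ref_p:
        for hm in ref_m:
            if hp.overlaps(hm):
                continue
            d = _ungapped_gap(hp, hm)
            if ref_dist is None or d < ref_dist:
                ref_dist = d
    within = ref_dist is not None and ref_dist <= max_dist
    cons_p = [o for o in occs_p if o.is_conserved(min_fraction)]
    cons_m = [o for o in occs_m if o.is_conserved(min_fraction)]
    conserved_all = bool(cons_p) and bool(cons_m)
    max_distance = None
    if cons_p and cons_m:
        # closest conserved pair by column distance; report its per-species max
        best = min(((op, om) for op in cons_p for om in cons_m),
                   key=lambda pm: abs(pm[0].col_start - pm[1].col_start))
        _, max_distance = pairwise_distances(block, *best)
    return CandidateVerdict(block.element_id, has_p, has_m, within, conserved_all,
                            reference_distance=ref_dist, max_distance=max_distance)
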