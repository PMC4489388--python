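"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: i.i.d. background
genomes with soft-masked stretches, non-overlapping conserved-region sets
with the 4-2000 bp size range of a GERP-style element call, genomes with
planted gap-constrained motif pairs, labelled positive/negative sequence
sets with controllable co-occurrence rates, and star-topology orthologue
alignments with positionally conserved motif pairs.  Every generator is
deterministic given its RNG/seed and returns an explicit truth record, so
recovery tests can assert recall and (with background scrubbing) precision
of exactly 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .footprint import AlignmentBlock
from .motifs import IupacMotif, reverse_complement, scan_consensus
from .syntax import GenomicInterval, RegionSet

BASES = np.array(list("ACGT"))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_iupac_word(motif: IupacMotif, rng) -> str:
    """Draw one unambiguous word uniformly among those the consensus accepts."""
    rng = _rng(rng)
    return "".join(sorted(s)[rng.integers(len(s))] for s in motif.position_sets)


def random_sequence(length: int, rng, gc_content: float = 0.5) -> str:
    rng = _rng(rng)
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2,
                  (1 - gc_content) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def gen_background_genome(length: int, *, gc_content: float = 0.41,
                          mask_fraction: float = 0.0,
                          mask_len_range: tuple[int, int] = (100, 500),
                          seed=None) -> tuple[str, list[GenomicInterval]]:
    """I.i.d. genome with lowercase (soft-masked) runs covering ~mask_fraction.

    Returns the sequence and the mask intervals actually applied.
    """
    if not 0.0 <= mask_fraction < 1.0:
        raise ValueError("mask_fraction must be in [0, 1)")
    rng = _rng(seed)
    seq = list(random_sequence(length, rng, gc_content))
    masks: list[GenomicInterval] = []
    target = int(mask_fraction * length)
    covered = 0
    attempts = 0
    occupied = np.zeros(length, dtype=bool)
    while covered < target and attempts < 50 * max(1, target):
        attempts += 1
        mlen = int(rng.integers(mask_len_range[0], mask_len_range[1] + 1))
        if mlen >= length:
            continue
        start = int(rng.integers(0, length - mlen))
        if occupied[start:start + mlen].any():
            continue
        occupied[start:start + mlen] = True
        for i in range(start, start + mlen):
            seq[i] = seq[i].lower()
        masks.append(GenomicInterval("synth", start, start + mlen))
        covered += mlen
    masks.sort(key=lambda iv: iv.start)
    return "".join(seq), masks


def gen_conserved_regions(genome_length: int, n_regions: int, *,
                          size_range: tuple[int, int] = (4, 2000),
                          chrom: str = "synth", seed=None) -> list[GenomicInterval]:
    """Non-overlapping intervals with sizes uniform over ``size_range``.

    Regions are separated by at least one base; placement distributes the
    leftover length as random gaps, so the layout is exchangeable.
    """
    if n_regions == 0:
        return []
    rng = _rng(seed)
    lo, hi = size_range
    sizes = rng.integers(lo, hi + 1, size=n_regions)
    needed = int(sizes.sum()) + n_regions  # 1 bp minimum spacing
    if needed > genome_length:
        raise ValueError(
            f"cannot fit {n_regions} regions of total {int(sizes.sum())} bp "
            f"(+spacers) in {genome_length} bp")
    slack = genome_length - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=n_regions))
    regions = []
    pos = 0
    for k in range(n_regions):
        extra = int(cuts[k]) - (int(cuts[k - 1]) if k else 0)
        start = pos + extra + 1
        regions.append(GenomicInterval(chrom, start, start + int(sizes[k])))
        pos = start + int(sizes[k])
    return regions


@dataclass(frozen=True)
class PlantSpec:
    """How many elements to plant and with what gap/orientation structure."""

    n_elements: int
    gap_distribution: tuple = ("uniform", 0, 40)  # ("fixed", g) | ("uniform", lo, hi) | ("empirical", values)
    orientation_policy: str = "random"  # or "fixed" (both motifs forward, PBX-HOX first)
    fraction_in_conserved: float = 1.0
    seed: int | None = None

    def sample_gap(self, rng) -> int:
        kind = self.gap_distribution[0]
        if kind == "fixed":
            return int(self.gap_distribution[1])
        if kind == "uniform":
            return int(rng.integers(self.gap_distribution[1], self.gap_distribution[2] + 1))
        if kind == "empirical":
            values = self.gap_distribution[1]
            return int(values[rng.integers(len(values))])
        raise ValueError(f"unknown gap distribution {kind!r}")


@dataclass(frozen=True)
class PlantedElement:
    """Ground truth for one planted pair (forward-strand coordinates)."""

    chrom: str
    pbx_start: int
    pbx_end: int
    pbx_strand: str
    meis_start: int
    meis_end: int
    meis_strand: str
    gap: int
    conserved: bool

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.pbx_start, self.meis_start),
                max(self.pbx_end, self.meis_end))


def _break_hit(seq: list[str], hit, motif: IupacMotif, protected: np.ndarray, rng) -> bool:
    """Mutate one unprotected base so the window no longer matches ``motif``."""
    sets = motif.position_sets if hit.strand == "+" else motif.rc_position_sets
    for off in rng.permutation(len(motif)):
        pos = hit.start + int(off)
        if protected[pos]:
            continue
        allowed = sets[int(off)]
        others = [b for b in "ACGT" if b not in allowed]
        if others:
            seq[pos] = others[int(rng.integers(len(others)))]
            return True
    return False


def plant_elements(genome: str, spec: PlantSpec, pbxhox: IupacMotif, meis: IupacMotif,
                   conserved: Sequence[GenomicInterval] | RegionSet, *,
                   chrom: str = "synth", scrub_background: bool = False,
                   seed=None) -> tuple[str, list[PlantedElement]]:
    """Write motif-pair words into a genome at known loci.

    Each element is a PBX-HOX word and a MEIS/PREP word at the sampled gap
    and orientation; with probability ``fraction_in_conserved`` it is placed
    fully inside a conserved interval, otherwise fully outside all of them.
    Planted spans keep a 100+ bp exclusion zone from one another so no
    cross-element pair can arise.  With ``scrub_background`` every chance
    occurrence of either motif elsewhere in the genome is destroyed by a
    single-base substitution, enabling precision-1.0 recovery tests.
    """
    rng = _rng(seed if seed is not None else spec.seed)
    conserved_list = list(conserved)
    seq = list(genome)
    n = len(seq)
    pad = 100 + len(pbxhox) + len(meis)  # no cross-element pairing possible
    blocked = np.zeros(n, dtype=bool)
    protected = np.zeros(n, dtype=bool)
    cons_mask = np.zeros(n, dtype=bool)
    for iv in conserved_list:
        cons_mask[iv.start:iv.end] = True
    truth: list[PlantedElement] = []
    hosts = [iv for iv in conserved_list]
    for _ in range(spec.n_elements):
        gap = spec.sample_gap(rng)
        span_len = len(pbxhox) + len(meis) + gap
        in_cons = bool(rng.random() < spec.fraction_in_conserved)
        placed = None
        for _attempt in range(2000):
            if in_cons:
                if not hosts:
                    break
                iv = hosts[int(rng.integers(len(hosts)))]
                if len(iv) < span_len:
                    continue
                start = iv.start + int(rng.integers(0, len(iv) - span_len + 1))
            else:
                start = int(rng.integers(0, n - span_len + 1))
                if cons_mask[start:start + span_len].any():
                    continue
            s0, s1 = max(0, start - pad), min(n, start + span_len + pad)
            if blocked[s0:s1].any():
                continue
            window = genome[start:start + span_len]
            if not all(c in "ACGT" for c in window.upper()) or window != window.upper():
                continue  # keep out of masked sequence
            placed = start
            break
        if placed is None:
            raise ValueError("genome too small (or too masked) for requested planting")
        pbx_word = sample_iupac_word(pbxhox, rng)
        meis_word = sample_iupac_word(meis, rng)
        if spec.orientation_policy == "random":
            pbx_strand = "+" if rng.random() < 0.5 else "-"
            meis_strand = "+" if rng.random() < 0.5 else "-"
            pbx_first = bool(rng.random() < 0.5)
        else:
            pbx_strand = meis_strand = "+"
            pbx_first = True
        pw = pbx_word if pbx_strand == "+" else reverse_complement(pbx_word)
        mw = meis_word if meis_strand == "+" else reverse_complement(meis_word)
        if pbx_first:
            pbx_start = placed
            meis_start = placed + len(pbxhox) + gap
        else:
            meis_start = placed
            pbx_start = placed + len(meis) + gap
        seq[pbx_start:pbx_start + len(pbxhox)] = pw
        seq[meis_start:meis_start + len(meis)] = mw
        blocked[max(0, placed - pad):min(n, placed + span_len + pad)] = True
        protected[pbx_start:pbx_start + len(pbxhox)] = True
        protected[meis_start:meis_start + len(meis)] = True
        truth.append(PlantedElement(chrom, pbx_start, pbx_start + len(pbxhox),
                                    pbx_strand, meis_start, meis_start + len(meis),
                                    meis_strand, gap,
                                    conserved=bool(cons_mask[placed])))
    if scrub_background:
        truth_keys = {(t.pbx_start, t.pbx_end, t.pbx_strand) for t in truth} | \
                     {(t.meis_start, t.meis_end, t.meis_strand) for t in truth}
        for _round in range(10):
            stray = []
            current = "".join(seq)
            for motif in (pbxhox, meis):
                for h in scan_consensus(current, motif, seq_id=chrom):
                    if (h.start, h.end, h.strand) not in truth_keys:
                        stray.append((h, motif))
            if not stray:
                break
            for h, motif in stray:
                _break_hit(seq, h, motif, protected, rng)
    return "".join(seq), truth


@dataclass(frozen=True)
class LabelledSequence:
    seq_id: str
    sequence: str
    label: str  # "pos" | "neg"
    has_pair: bool
    gap: int | None = None


def gen_labelled_sets(n_pos: int, n_neg: int, co_rate_pos: float, co_rate_neg: float,
                      pbxhox: IupacMotif, meis: IupacMotif, *,
                      seq_len_range: tuple[int, int] = (300, 800),
                      gap_range: tuple[int, int] = (0, 40),
                      gc_content: float = 0.41,
                      seed=None) -> list[LabelledSequence]:
    """Positive/negative sequence sets with controlled pair co-occurrence rates.

    A sequence carries a planted PBX-HOX + MEIS/PREP pair (gap uniform over
    ``gap_range``) with probability ``co_rate_pos`` (positives) or
    ``co_rate_neg`` (negatives); otherwise any chance co-occurrence of the
    exact motif words is scrubbed out.
    """
    rng = _rng(seed)
    out: list[LabelledSequence] = []
    for label, count, rate in (("pos", n_pos, co_rate_pos), ("neg", n_neg, co_rate_neg)):
        for k in range(count):
            L = int(rng.integers(seq_len_range[0], seq_len_range[1] + 1))
            sid = f"{label}_{k:04d}"
            has_pair = bool(rng.random() < rate)
            if has_pair:
                gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
                spec = PlantSpec(1, gap_distribution=("fixed", gap),
                                 fraction_in_conserved=0.0)
                genome = random_sequence(L, rng, gc_content)
                planted, truth = plant_elements(genome, spec, pbxhox, meis, [],
                                                chrom=sid, scrub_background=True,
                                                seed=rng)
                out.append(LabelledSequence(sid, planted, label, True, truth[0].gap))
            else:
                genome = random_sequence(L, rng, gc_content)
                cleaned, _ = plant_elements(genome, PlantSpec(0), pbxhox, meis, [],
                                            chrom=sid, scrub_background=True, seed=rng)
                out.append(LabelledSequence(sid, cleaned, label, False))
    return out


@dataclass(frozen=True)
class AlignmentTruth:
    """Planted motif geometry for one synthetic orthologue alignment."""

    element_id: str
    species: tuple[str, ...]
    conserved_species: tuple[str, ...]
    gap: int
    per_species_distance: dict  # species -> ungapped inter-motif distance
    pbx_word: str
    meis_word: str


def gen_alignment(element_id: str, n_species: int, element_len: int,
                  pbxhox: IupacMotif, meis: IupacMotif, *,
                  gap: int = 20, substitution_rate: float = 0.05,
                  indel_rate: float = 0.0, conserved_species: Sequence[str] | None = None,
                  extra_insertions: dict | None = None,
                  seed=None) -> tuple[AlignmentBlock, AlignmentTruth]:
    """Star-topology orthologue alignment with a planted motif pair.

    An ancestral element carries a PBX-HOX word and a MEIS/PREP word
    separated by ``gap`` bases.  Each species row substitutes non-motif
    bases at ``substitution_rate`` and acquires species-specific insertions
    at ``indel_rate`` per eligible position (never inside motif words).
    Species not listed in ``conserved_species`` (default: all conserved)
    have their MEIS/PREP word ablated by a substitution that violates the
    consensus.  ``extra_insertions`` maps species -> (ancestral_position,
    length) for deterministic lineage-specific insertions.
    """
    if not 2 <= n_species <= 30:
        raise ValueError("n_species must be in [2, 30]")
    rng = _rng(seed)
    species = tuple(f"sp{i:02d}" for i in range(n_species))
    conserved_set = set(species if conserved_species is None else conserved_species)
    pbx_word = sample_iupac_word(pbxhox, rng)
    meis_word = sample_iupac_word(meis, rng)
    Lp, Lm = len(pbx_word), len(meis_word)
    core = Lp + gap + Lm
    if element_len < core + 20:
        raise ValueError("element_len too small for the planted pair plus flanks")
    p0 = (element_len - core) // 2
    ancestral = list(random_sequence(element_len, rng, 0.41))
    ancestral[p0:p0 + Lp] = pbx_word
    m0 = p0 + Lp + gap
    ancestral[m0:m0 + Lm] = meis_word
    motif_pos = set(range(p0, p0 + Lp)) | set(range(m0, m0 + Lm))
    # scrub chance ancestral occurrences so the planted pair is the only truth
    protected = np.zeros(element_len, dtype=bool)
    protected[list(motif_pos)] = True
    for _round in range(10):
        stray = [(h, m) for m in (pbxhox, meis)
                 for h in scan_consensus("".join(ancestral), m)
                 if not (h.start in motif_pos and (h.end - 1) in motif_pos)]
        if not stray:
            break
        for h, m in stray:
            _break_hit(ancestral, h, m, protected, rng)
    # per-species edited base at each ancestral position, plus insertions after i
    rows_base: dict[str, list[str]] = {}
    insertions: dict[str, dict[int, str]] = {sp: {} for sp in species}
    distances: dict[str, int] = {}
    for sp in species:
        chars = list(ancestral)
        for i in range(element_len):
            if i in motif_pos:
                continue
            if rng.random() < substitution_rate:
                cur = chars[i]
                alts = [b for b in "ACGT" if b != cur]
                chars[i] = alts[int(rng.integers(3))]
        if sp not in conserved_set:
            # ablate the MEIS/PREP word at a non-degenerate consensus position
            for off, s in enumerate(meis.position_sets):
                if len(s) < 4:
                    bad = [b for b in "ACGT" if b not in s]
                    chars[m0 + off] = bad[int(rng.integers(len(bad)))]
                    break
        inserted_between = 0
        if indel_rate > 0:
            for i in range(element_len - 1):
                if i in motif_pos and (i + 1) in motif_pos:
                    continue
                if rng.random() < indel_rate:
                    ilen = int(rng.integers(1, 11))
                    insertions[sp][i] = random_sequence(ilen, rng, 0.41)
        if extra_insertions and sp in extra_insertions:
            pos, ilen = extra_insertions[sp]
            if pos is None:  # midway between the two motif words
                pos = p0 + Lp + gap // 2
            insertions[sp][pos] = insertions[sp].get(pos, "") + random_sequence(ilen, rng, 0.41)
        for i, ins in insertions[sp].items():
            if p0 + Lp - 1 <= i < m0:
                inserted_between += len(ins)
        # substitutions and inserted sequence must not mint new motif matches:
        # scan the assembled ungapped row and break any unplanned hit
        for _round in range(10):
            idx: list[tuple[int, str, int]] = []  # (ancestral pos, container, offset)
            ungapped = []
            for i in range(element_len):
                idx.append((i, "base", 0))
                ungapped.append(chars[i])
                for k, ch in enumerate(insertions[sp].get(i, "")):
                    idx.append((i, "ins", k))
                    ungapped.append(ch)
            row = "".join(ungapped)
            planted_ungapped = {j for j, (i, kind, _) in enumerate(idx)
                                if kind == "base" and i in motif_pos}
            stray = []
            for m in (pbxhox, meis):
                for h in scan_consensus(row, m):
                    if not set(range(h.start, h.end)) <= planted_ungapped:
                        stray.append((h, m))
            if not stray:
                break
            for h, m in stray:
                sets = m.position_sets if h.strand == "+" else m.rc_position_sets
                for off in rng.permutation(len(m)):
                    j = h.start + int(off)
                    if j in planted_ungapped:
                        continue
                    allowed = sets[int(off)]
                    others = [b for b in "ACGT" if b not in allowed]
                    if not others:
                        continue
                    new_b = others[int(rng.integers(len(others)))]
                    i, kind, k = idx[j]
                    if kind == "base":
                        chars[i] = new_b
                    else:
                        s = insertions[sp][i]
                        insertions[sp][i] = s[:k] + new_b + s[k + 1:]
                    break
        rows_base[sp] = chars
        distances[sp] = gap + inserted_between
    # assemble aligned rows column-block by column-block
    aligned = {sp: [] for sp in species}
    for i in range(element_len):
        for sp in species:
            aligned[sp].append(rows_base[sp][i])
        for sp in species:
            ins = insertions[sp].get(i)
            if ins:
                for osp in species:
                    aligned[osp].append(ins if osp == sp else "-" * len(ins))
    block = AlignmentBlock(element_id, {sp: "".join(aligned[sp]) for sp in species})
    truth = AlignmentTruth(element_id, species, tuple(sorted(conserved_set)), gap,
                           distances, pbx_word, meis_word)
    return block, truth
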