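"""Binding-site models and strand-aware motif scanning.

Two motif representations are supported:

* :class:`IupacMotif` — a degenerate consensus over the IUPAC nucleotide
  alphabet (e.g. the PBX-HOX heterodimer consensus ``TGATNNATKR`` or the
  MEIS/PREP consensus ``CTGTCA``).  A window matches iff every base is a
  member of the corresponding code's base set.
* :class:`PositionWeightMatrix` — a 4xL frequency matrix scored as log2
  odds against a background composition, with an exact match p-value
  obtained by dynamic programming over the discretised per-column score
  distribution (the same quantity FIMO reports).

Scanning is soft-mask aware: a window that overlaps ANY lowercase or ``N``
base is discarded, the strictest reading of "masked matches are not
counted".  Both strands are scanned by default; minus-strand hits are
reported in forward-strand coordinates with ``matched_word`` being the
forward-strand substring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def reverse_complement(seq: str) -> str:
    """Reverse complement, defined for IUPAC codes and case-preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate consensus motif over IUPAC nucleotide codes."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty IUPAC pattern")
        for i, c in enumerate(self.pattern):
            if c.upper() not in IUPAC_CODES:
                raise ValueError(
                    f"invalid IUPAC code {c!r} at position {i} in pattern {self.pattern!r}"
                )
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    @cached_property
    def position_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC_CODES[c] for c in self.pattern)

    @cached_property
    def rc_position_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC_CODES[c] for c in reverse_complement(self.pattern))

    def degeneracy(self) -> int:
        """Number of distinct unambiguous words the pattern accepts."""
        n = 1
        for s in self.position_sets:
            n *= len(s)
        return n

    def matches(self, word: str) -> bool:
        """True iff ``word`` (unambiguous, uppercase) is accepted forward-strand."""
        if len(word) != len(self.pattern):
            return False
        return all(c in s for c, s in zip(word, self.position_sets))

    def words(self) -> Iterable[str]:
        """Enumerate every accepted word (use only for small degeneracy)."""
        from itertools import product

        for combo in product(*(sorted(s) for s in self.position_sets)):
            yield "".join(combo)


def compile_iupac(pattern: str, name: str | None = None) -> IupacMotif:
    """Validate and compile an IUPAC consensus string."""
    return IupacMotif(name=name or pattern, pattern=pattern)


@dataclass(frozen=True)
class MotifHit:
    """One strand-aware motif occurrence in forward-strand coordinates.

    ``start``/``end`` are 0-based half-open on the forward strand;
    ``matched_word`` is the forward-strand substring, so for a minus-strand
    hit its reverse complement is what matches the motif.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    motif_name: str
    matched_word: str
    score: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    def overlaps(self, other: "MotifHit") -> bool:
        return (self.seq_id == other.seq_id
                and self.start < other.end and other.start < self.end)


def _window_ok(window: str) -> bool:
    # masked policy: reject if any base is lowercase or not a concrete ACGT
    return all(c in "ACGT" for c in window)


def scan_consensus(sequence: str, motif: IupacMotif, *, seq_id: str = "seq",
                   strands: str = "both") -> list[MotifHit]:
    """Find all unmasked occurrences of a consensus motif.

    Parameters
    ----------
    sequence : str
        Nucleotide sequence; lowercase runs and ``N`` are treated as masked.
    strands : ``"both"`` or ``"forward"``

    Returns hits sorted by (start, strand).  A sequence shorter than the
    motif yields an empty list.
    """
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    L = len(motif)
    hits: list[MotifHit] = []
    fwd = motif.position_sets
    rev = motif.rc_position_sets
    for i in range(len(sequence) - L + 1):
        window = sequence[i:i + L]
        if not _window_ok(window):
            continue
        if all(c in s for c, s in zip(window, fwd)):
            hits.append(MotifHit(seq_id, i, i + L, "+", motif.name, window))
        if strands == "both" and all(c in s for c, s in zip(window, rev)):
            hits.append(MotifHit(seq_id, i, i + L, "-", motif.name, window))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


class PositionWeightMatrix:
    """A 4xL base-frequency matrix scored as log2-odds vs background.

    Parameters
    ----------
    matrix : array-like, shape (4, L) or (L, 4)
        Per-position base counts or frequencies, rows in A,C,G,T order
        (an (L, 4) matrix is transposed automatically when unambiguous).
    background : 4-vector of base probabilities, default uniform.
    pseudocount : added to every cell before column normalisation.
    """

    def __init__(self, name: str, matrix, *, background: Sequence[float] | None = None,
                 pseudocount: float = 0.0) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if m.shape[0] != 4 and m.shape[1] == 4:
            m = m.T
        if m.shape[0] != 4:
            raise ValueError(f"matrix must be 4xL, got {m.shape}")
        if m.shape[1] < 1:
            raise ValueError("matrix must have at least one column")
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if np.any(m < 0):
            raise ValueError("matrix entries must be non-negative")
        self.name = name
        self.pseudocount = float(pseudocount)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("background must be 4 probabilities summing to 1")
        if np.any(bg <= 0):
            raise ValueError("background probabilities must be positive")
        self.background = bg
        m = m + self.pseudocount
        colsums = m.sum(axis=0)
        if np.any(colsums <= 0):
            raise ValueError("each column needs positive total weight (use a pseudocount)")
        self.freqs = m / colsums
        # zero frequencies give -inf log-odds: legal, a word using such a
        # base can simply never exceed any finite score threshold
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.freqs / bg[:, None])
        self._sf_cache: tuple[float, np.ndarray, int, int] | None = None

    @property
    def length(self) -> int:
        return self.freqs.shape[1]

    def __len__(self) -> int:
        return self.length

    @classmethod
    def from_iupac(cls, motif: IupacMotif, *, name: str | None = None,
                   pseudocount: float = 0.0,
                   background: Sequence[float] | None = None) -> "PositionWeightMatrix":
        """0/1 matrix admitting exactly the words the consensus accepts."""
        m = np.zeros((4, len(motif)))
        for j, s in enumerate(motif.position_sets):
            for b in s:
                m[_BASE_INDEX[b], j] = 1.0 / len(s)
        return cls(name or motif.name, m, pseudocount=pseudocount, background=background)

    def score(self, word: str) -> float:
        """Log2-odds score of an unambiguous word of matching length (bits)."""
        if len(word) != self.length:
            raise ValueError(f"word length {len(word)} != PWM length {self.length}")
        total = 0.0
        for j, c in enumerate(word):
            i = _BASE_INDEX.get(c)
            if i is None:
                raise ValueError(f"ambiguous or invalid base {c!r} in word")
            total += self.log_odds[i, j]
        return total

    # -- exact p-value by DP over the discretised score distribution --------

    def _score_sf(self, granularity: float) -> tuple[np.ndarray, int]:
        """Survival function of the null score distribution.

        Scores are discretised to integer multiples of ``granularity`` bits.
        Returns (sf, offset): sf[k] = P(score >= (k + offset) * granularity)
        under the background model.
        """
        if self._sf_cache is not None and self._sf_cache[0] == granularity:
            _, sf, offset, _ = self._sf_cache
            return sf, offset
        finite = np.isfinite(self.log_odds)
        scaled = np.where(finite, np.rint(np.where(finite, self.log_odds, 0.0)
                                          / granularity), 0).astype(np.int64)
        # DP over finite-score paths only; -inf mass can never reach a finite
        # threshold, so it simply drops out of the survival function
        dist = np.array([1.0])
        cur_lo = 0
        for j in range(self.length):
            col_fin = finite[:, j]
            col = scaled[:, j]
            vals = col[col_fin]
            new_lo = cur_lo + int(vals.min())
            new_hi = cur_lo + len(dist) - 1 + int(vals.max())
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                if not col_fin[b]:
                    continue
                off = cur_lo + int(col[b]) - new_lo
                new[off:off + len(dist)] += self.background[b] * dist
            dist, cur_lo = new, new_lo
        hi = cur_lo + len(dist) - 1
        sf = np.cumsum(dist[::-1])[::-1]
        self._sf_cache = (granularity, sf, cur_lo, hi)
        return sf, cur_lo

    def score_pvalue(self, score: float, *, granularity: float = 0.001) -> float:
        """P(random background word scores >= ``score``), exact up to discretisation."""
        sf, lo = self._score_sf(granularity)
        k = int(round(score / granularity)) - lo
        if k < 0:
            return 1.0
        if k >= len(sf):
            return 0.0
        return float(min(1.0, sf[k]))


def pwm_log_odds(pwm: PositionWeightMatrix, word: str) -> float:
    """Functional alias for :meth:`PositionWeightMatrix.score`."""
    return pwm.score(word)


def pwm_score_pvalue(pwm: PositionWeightMatrix, score: float, *,
                     granularity: float = 0.001) -> float:
    """Functional alias for :meth:`PositionWeightMatrix.score_pvalue`."""
    return pwm.score_pvalue(score, granularity=granularity)


def scan_pwm(sequence: str, pwm: PositionWeightMatrix, *, p_threshold: float = 0.001,
             seq_id: str = "seq", strands: str = "both",
             granularity: float = 0.001) -> list[MotifHit]:
    """Find all unmasked windows whose match p-value is <= ``p_threshold``.

    The p-value is the exact probability that a background-distributed word
    scores at least as high as the window (per strand).  Masking follows
    :func:`scan_consensus`.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    L = pwm.length
    hits: list[MotifHit] = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i:i + L]
        if not _window_ok(window):
            continue
        s = pwm.score(window)
        p = pwm.score_pvalue(s, granularity=granularity)
        if p <= p_threshold:
            hits.append(MotifHit(seq_id, i, i + L, "+", pwm.name, window, score=s, p_value=p))
        if strands == "both":
            s = pwm.score(reverse_complement(window))
            p = pwm.score_pvalue(s, granularity=granularity)
            if p <= p_threshold:
                hits.append(MotifHit(seq_id, i, i + L, "-", pwm.name, window,
                                     score=s, p_value=p))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
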