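"""Readers/writers for the standard formats and the pipeline orchestrator.

FASTA (case-preserving, so soft-masking survives round-trips) and
alignments go through Biopython; MEME-minimal motif files through
``Bio.motifs``; BED is read/written natively as 0-based half-open BED4/6.
``run_pipeline`` binds the stages together from a single config with one
seed, writing every stage output plus a provenance header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import AlignIO, SeqIO, motifs as bio_motifs

from .footprint import AlignmentBlock
from .motifs import IupacMotif, MotifHit, PositionWeightMatrix, compile_iupac, scan_consensus
from .syntax import (GenomicInterval, RegionSet, SyntaxElement, filter_conserved,
                     gap_histogram, pair_hits, select_hb)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA as {id: sequence}, case preserved."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, label: str | None = None) -> RegionSet:
    """BED3-6 as a RegionSet (0-based half-open, as BED natively is)."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            intervals.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    return RegionSet(intervals, label=label or Path(path).stem)


def _bed_row(item) -> tuple:
    if isinstance(item, MotifHit):
        if item.p_value is not None and item.p_value > 0:
            score = round(1000 * min(1.0, -math.log10(item.p_value)))
        elif item.p_value == 0:
            score = 1000
        else:
            score = 0
        return (item.seq_id, item.start, item.end, item.motif_name, score, item.strand)
    if isinstance(item, SyntaxElement):
        # score column carries the gap size for quick inspection
        return (item.seq_id, item.start, item.end, "syntax", item.gap, "+")
    if isinstance(item, GenomicInterval):
        return (item.chrom, item.start, item.end, item.name or ".", 0,
                item.strand or ".")
    raise TypeError(f"cannot write {type(item)} as BED")


def write_bed(path, items: Iterable, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for item in items:
            fh.write("\t".join(str(x) for x in _bed_row(item)) + "\n")


def elements_to_tsv(path, elements: Sequence[SyntaxElement],
                    categories: Sequence[str] | None = None) -> None:
    cols = ["seq", "pbx_start", "pbx_end", "pbx_strand",
            "meis_start", "meis_end", "meis_strand", "gap", "conserved"]
    if categories is not None:
        cols.append("category")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, e in enumerate(elements):
            row = [e.seq_id, e.pbxhox_hit.start, e.pbxhox_hit.end,
                   e.pbxhox_hit.strand, e.meis_hit.start, e.meis_hit.end,
                   e.meis_hit.strand, e.gap, int(e.conserved)]
            if categories is not None:
                row.append(categories[i])
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_elements_tsv(path) -> list[SyntaxElement]:
    """Round-trip reader for :func:`elements_to_tsv` (matched words not kept)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            try:
                ps, pe = int(p[idx["pbx_start"]]), int(p[idx["pbx_end"]])
                ms, me = int(p[idx["meis_start"]]), int(p[idx["meis_end"]])
                pbx = MotifHit(p[idx["seq"]], ps, pe, p[idx["pbx_strand"]],
                               "PBX-HOX", "N" * (pe - ps))
                meis = MotifHit(p[idx["seq"]], ms, me, p[idx["meis_strand"]],
                                "MEIS-PREP", "N" * (me - ms))
                out.append(SyntaxElement(pbx, meis, int(p[idx["gap"]]),
                                         conserved=bool(int(p[idx["conserved"]])),
                                         category=p[idx["category"]]
                                         if "category" in idx else None))
            except (KeyError, ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: malformed element row") from exc
    return out


# ---------------------------------------------------------------------------
# motifs and alignments
# ---------------------------------------------------------------------------

def read_iupac_motifs(path) -> list[IupacMotif]:
    """Plain-text motif list: one ``name<TAB>pattern`` per line, # comments."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'name pattern'")
            out.append(compile_iupac(parts[1], name=parts[0]))
    return out


def read_meme_minimal(path, *, pseudocount: float = 0.01) -> list[PositionWeightMatrix]:
    """MEME-minimal letter-probability matrices as PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
        bg = None
        if getattr(parsed, "background", None):
            b = parsed.background
            bg = [b["A"], b["C"], b["G"], b["T"]]
        out = []
        for m in parsed:
            mat = [[m.counts[base][i] for i in range(m.length)] for base in "ACGT"]
            out.append(PositionWeightMatrix(m.name or "motif", mat,
                                            background=bg, pseudocount=pseudocount))
    return out


def read_alignment(path, element_id: str | None = None,
                   fmt: str | None = None) -> AlignmentBlock:
    """Aligned multi-FASTA or Clustal file as one AlignmentBlock."""
    if fmt is None:
        fmt = "clustal" if str(path).endswith((".aln", ".clustal", ".clw")) else "fasta"
    aln = AlignIO.read(str(path), fmt)
    rows = {rec.id: str(rec.seq) for rec in aln}
    return AlignmentBlock(element_id or Path(path).stem, rows)


# ---------------------------------------------------------------------------
# pipeline config and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one end-to-end run needs; CLI flags override file values."""

    genome_fasta: str
    pbxhox_pattern: str = "TGATNNATKR"
    meis_pattern: str = "CTGTCA"
    scan_mode: str = "consensus"  # or "pwm"
    meme_file: str | None = None
    p_threshold: float = 0.001
    max_gap: int = 100
    min_gap: int = 0
    hb_gap: int = 40
    strands: str = "both"
    conserved_bed: str | None = None
    seed: int = 0
    outdir: str = "hbsyntax_out"

    def validate(self) -> None:
        for label, p in (("genome_fasta", self.genome_fasta),
                         ("conserved_bed", self.conserved_bed),
                         ("meme_file", self.meme_file)):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{label}: {p} does not exist")
        if self.scan_mode not in ("consensus", "pwm"):
            raise ValueError(f"unknown scan_mode {self.scan_mode!r}")
        if self.scan_mode == "pwm" and not self.meme_file:
            raise ValueError("pwm mode needs a meme_file")
        if not 0 <= self.min_gap <= self.max_gap:
            raise ValueError("require 0 <= min_gap <= max_gap")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """scan -> pair -> conservation filter -> hb selection, with files written.

    Outputs under ``config.outdir``: per-motif hit BEDs, element BED + TSV,
    a gap histogram TSV and a JSON summary; every file carries a provenance
    header (config hash + seed).  Re-running the same config is
    bitwise-identical.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = f"hbsyntax config={config.digest()} seed={config.seed}"
    genome = read_fasta(config.genome_fasta)

    from .motifs import scan_pwm  # local to avoid cycle at import time

    if config.scan_mode == "pwm":
        pwms = read_meme_minimal(config.meme_file)
        if len(pwms) < 2:
            raise ValueError("pwm mode needs two matrices (PBX-HOX, MEIS/PREP)")
        pbx_scan = lambda seq, sid: scan_pwm(seq, pwms[0], p_threshold=config.p_threshold,
                                             seq_id=sid, strands=config.strands)
        meis_scan = lambda seq, sid: scan_pwm(seq, pwms[1], p_threshold=config.p_threshold,
                                              seq_id=sid, strands=config.strands)
    else:
        pbx = compile_iupac(config.pbxhox_pattern, name="PBX-HOX")
        meis = compile_iupac(config.meis_pattern, name="MEIS-PREP")
        pbx_scan = lambda seq, sid: scan_consensus(seq, pbx, seq_id=sid,
                                                   strands=config.strands)
        meis_scan = lambda seq, sid: scan_consensus(seq, meis, seq_id=sid,
                                                    strands=config.strands)

    pbx_hits: list[MotifHit] = []
    meis_hits: list[MotifHit] = []
    for sid in sorted(genome):
        pbx_hits.extend(pbx_scan(genome[sid], sid))
        meis_hits.extend(meis_scan(genome[sid], sid))

    elements = pair_hits(pbx_hits, meis_hits, max_gap=config.max_gap,
                         min_gap=config.min_gap)
    conserved_elements = None
    if config.conserved_bed:
        regions = read_bed(config.conserved_bed, label="conserved")
        conserved_elements = filter_conserved(elements, regions)
    final = conserved_elements if conserved_elements is not None else elements
    hb = select_hb(final, max_gap=config.hb_gap)

    write_bed(outdir / "hits_pbxhox.bed", pbx_hits, header=prov)
    write_bed(outdir / "hits_meis.bed", meis_hits, header=prov)
    write_bed(outdir / "elements.bed", final, header=prov)
    elements_to_tsv(outdir / "elements.tsv", final)
    hist = gap_histogram(hb)
    with open(outdir / "gap_histogram.tsv", "w") as fh:
        fh.write(f"#{prov}\ngap\tcount\n")
        for g in sorted(hist):
            fh.write(f"{g}\t{hist[g]}\n")
    summary = {
        "provenance": prov,
        "n_sequences": len(genome),
        "n_pbxhox_hits": len(pbx_hits),
        "n_meis_hits": len(meis_hits),
        "n_pairs": len(elements),
        "n_conserved_pairs": (len(conserved_elements)
                              if conserved_elements is not None else None),
        "n_hb": len(hb),
        "hb_gap": config.hb_gap,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    summary["elements"] = final
    summary["hb_elements"] = hb
    summary["pbx_hits"] = pbx_hits
    summary["meis_hits"] = meis_hits
    return summary
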