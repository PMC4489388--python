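# Methods

## The model

The package operationalises a two-motif enhancer grammar. A *syntax
element* is an ordered pair of one PBX-HOX hit (consensus `TGATNNATKR`,
the inseparable heterodimer half-sites bound jointly by PBX and HOX
homeodomain proteins) and one MEIS/PREP hit (consensus `CTGTCA`, the
TALE-class cofactor site), on the same sequence, not overlapping, with at
most `max_gap` intervening bases. The gap is the number of bases strictly
between the two hit spans (half-open coordinates), so adjacent motifs have
gap 0 and "gap ≤ 100" means `downstream.start − upstream.end ≤ 100`.
Either motif may lie upstream and either may be on either strand:
orientation is recorded on every hit but never filtered by default,
because functional examples occur gapped and inverted. Elements are never
merged or deduplicated beyond exact duplicates — overlapping elements are
real (several motifs within one neighbourhood each pair) and are counted
as such.

An element is *conserved* when **each** of its two hits lies fully inside
some conserved interval (the two hits may sit in different intervals; a
hit straddling an interval boundary disqualifies the element). The
conservation universe is a GERP-style conserved-element set: many short
intervals (4–2000 bp) covering a minority of the genome. hb_40 elements
are the conserved pairs with gap ≤ 40.

## Scanning

* **Consensus mode.** A window matches iff every base is a member of the
  IUPAC code's base set at that position. Both strands are scanned by
  default; `CTGTCA` is non-palindromic, so forward-only scanning would
  miss half the sites. Minus-strand hits are reported in forward-strand
  coordinates with the forward-strand word.
* **Masking.** A window overlapping *any* lowercase or `N` base is
  discarded — the strictest reading of "masked matches are not counted".
* **PWM mode.** Windows are scored as Σᵢ log2(fᵢ(base)/bg(base)) in bits.
  The match p-value P(score of a background word ≥ s) is computed exactly
  by dynamic programming over the per-column score distribution,
  discretised to a configurable granularity (default 1/1000 bit; tests
  compare against exhaustive 4^L enumeration at thresholds separated by
  more than the accumulated rounding error). Zero frequencies are legal:
  they score −∞ and simply drop out of the upper tail. The default
  significance threshold is p ≤ 0.001, the conventional single-motif
  cutoff for candidate calling. Background defaults to uniform 0.25 and
  can be supplied (the MEME-minimal reader picks up the file's background
  line).

## Statistics

* **Fisher's exact test** (scipy) on 2×2 sequence-set tables. The default
  is two-sided (sum of all tables with point probability ≤ the observed
  table's); sidedness is an explicit flag, and tests pin the convention
  against a rational-arithmetic enumeration oracle. One-sided "greater"
  coincides with the hypergeometric upper tail, which is asserted as a
  cross-check property.
* **Hypergeometric enrichment** on region counts: expected = nK/N, p =
  P(X ≥ x) (inclusive upper tail, scipy's log-space survival function).
* **Rates and folds.** rate = count/Mb; fold is the ratio of two per-Mb
  rates, algebraically identical to observed/expected with expected =
  bg_count·(obs_bp/bg_bp), so both published phrasings are the same
  function.
* **Placement null.** Each simulation draws the observed numbers of
  6-mer and 10-mer site locations uniformly (with replacement) from all
  positions where the site fits entirely inside a single conserved
  interval — an interval shorter than the site contributes nothing — and
  recounts gap-constrained pairs. Simulated sites may overlap one another,
  as real motif matches may. Chromosomes are laid out with spacers wider
  than any admissible gap so no cross-chromosome pair can arise. The
  z-score, one-sided normal tail and the add-one empirical tail
  (1 + #{count ≥ obs})/(n_sims + 1) are reported together; a single seeded
  generator drives each run and the seed is written into the output.
* **Quantiles** use numpy's linear-interpolation convention (q = 0.1 of
  {1..10} is 1.9); **Mann-Whitney** uses the exact distribution for small
  tie-free samples and the tie-corrected normal approximation otherwise.

## Phylogenetic footprinting

Each orthologous element is a multiple alignment (2–30 species; the
empirically relevant range is 16–25). Every row is scanned in its own
ungapped coordinates; hits are projected to alignment columns through a
per-row bidirectional column↔position map; hits from different species
whose column intervals overlap by ≥ 1 column are clustered into one
occurrence. "Positionally conserved" means the supporting fraction
reaches `min_fraction` — default 1.0 (all aligned species), configurable
because real alignments wobble and rows go missing. The candidate verdict
is the conjunction of three criteria: (a) both motifs present
(significant at the PWM threshold in PWM mode) in the reference species
(default: the first row); (b) a non-overlapping pair within 100 bp in the
reference species, measured in its ungapped coordinates; (c) both motifs
positionally conserved. Per-species inter-motif distances and their
maximum over species are also reported, since lineage-specific indels
stretch the spacing in individual genomes.

## Synthetic data: what it emulates and what it does not

The generators emulate the statistical structure the analysis assumes:
i.i.d. background at a chosen GC content (default 0.41, the human
genome-wide value) with soft-masked runs; non-overlapping conserved
intervals with sizes uniform over 4–2000 bp; planted motif pairs with a
chosen gap law (default uniform on [0, 40]), random orientation and a
chosen fraction inside conserved DNA; labelled sequence sets whose
positive/negative co-occurrence rates default to the empirical 25/38 and
49/150; star-topology orthologue alignments with per-species
substitutions and insertions that never touch planted motif words, and
with motif ablation in species flagged non-conserved.

Planted spans keep a >100 bp exclusion zone from each other so no
cross-element pair can arise, and the generators post-scan their own
output and destroy any *unplanned* motif occurrence (in `plant_elements`
this scrubbing is an explicit flag, default off, because it perturbs
base composition: precision-1 recovery tests enable it, calibration tests
do not; the alignment generator always enforces it so the planted
geometry is the whole truth). Every generator is deterministic given its
seed.

What passing recovery tests on these fixtures shows is that the
*machinery* — scanning, masking, pairing, conservation filtering,
projection — is exact. They do not show anything about real genomes:
real background is not i.i.d. (CpG depletion, repeats, compositional
domains), real conserved elements cluster near developmental genes, and
real alignments contain alignment error, none of which the generators
model. The published genome-scale counts therefore enter the acceptance
surface only through statistics computed exactly from the printed count
tables; the synthetic emulations are run at desk scale (100 kb genomes,
tens of planted elements, hundreds of simulations), which is sufficient
because the quantities checked there — recall, precision, calibration —
are scale-free.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere internally; BED is written
  natively, conversion happens only at I/O.
* The promoter window for element classification is ±1 kb around the most
  5′ TSS, symmetric because sidedness is not dictated by the biology of
  the call; priority order is promoter > exonic > intronic > intergenic,
  making categories exhaustive and mutually exclusive.
* Midpoint-to-midpoint distance is used for nearest-feature profiles;
  elements on sequences carrying no feature are skipped and logged.
* The pair-count fold over a background per-Mb rate depends on the chosen
  denominator (total conserved bp vs effective unmasked genome); the
  denominator is an argument, never hard-coded.
* `n_sims < 2` is rejected (sd undefined); a zero-margin 2×2 table
  returns p = 1 with a warning rather than raising mid-pipeline.
* Pipeline runs are bitwise reproducible from the config (hash + seed
  stamped into every output file header).

## Known limitations

* Consensus scanning is pure-Python O(nL); it is comfortable up to a few
  hundred kb per call, which covers the intended fixture scale. Genome-
  scale scans would want a vectorised or automaton-based matcher.
* The placement null draws sites with replacement and ignores site
  self-overlap exclusion; at realistic densities (sites ≪ positions) the
  effect on the pair-count distribution is negligible.
* The footprint clusterer merges occurrences across species by column
  overlap only; a misaligned motif shifted by more than its own length
  into non-overlapping columns would be split into two occurrences rather
  than recognised as wobble.
* MEME-minimal is the only PWM exchange format read; alignments are
  consumed as aligned FASTA or Clustal, never built.
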