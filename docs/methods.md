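# Methods

This note documents the models, conventions and numerical choices behind
`zfrec`, and what the synthetic-data tests do and do not establish.

## Design grammar

A **lox site** is modeled as `left_half + spacer + right_half`
(default 13 + 8 + 13 = 34 nt); a **ZF motif** is any sequence with length
divisible by 3 (one finger per 3 nt; 9 nt for three fingers, 12 for
four). A composite target site places the motif on both outer flanks of
the lox site, mirror-symmetrically, separated by a pad of `spacing_bp`
(0–10) deterministic filler bases. Only the pad *length* matters to the
screen, so the filler cycles a fixed 4-mer rather than being random; this
keeps site construction reproducible byte-for-byte.

**Orientation** is defined graphically in screen designs, so the package
fixes an internal convention: orientation A puts the motif's given
sequence on the top strand reading toward the lox site (given sequence on
the left flank, reverse complement on the right); orientation B is the
mirror. Both are enumerated; nothing downstream depends on which label is
which. Single-sided placement (`flanked_sides = left/right`) supports
asymmetric controls.

**Fusions.** GGS linkers use the fixed codons `GGT GGT AGC` per repeat.
Terminal fusions use one linker of 2–12 repeats; insertional fusions
place the ZFD (start/stop codons stripped) between codons `j` and `j+1`
(1-based; the default junction is 278) with independent left/right
linkers of 1–8 repeats. All outputs are checked to stay in frame and to
introduce no stop codon.

**Reference pairs.** A backbone template carries literal anchors
`<SITE1><INTERSITE><SITE2>` and `<CDS>`. UNREC substitutes the composite
site twice around the excisable segment; REC models the excision product:
recombination resolves within the 8-nt lox spacer of two directly
repeated sites, so exactly one full composite site remains and
`|UNREC| − |REC| = |intersite| + |site|`. Annotated intervals
(`target_site`, `intersite`, `fusion_diagnostic` = the fusion CDS) are
0-based half-open and drive the coverage filter. Published lox/zif
sequences are not distributed with the package; all sequences are inputs,
and tests use synthetic stand-ins.

## Read classification and rates

Reads are first filtered by **mean Phred ≥ 10** (mean of per-base error
probabilities converted back to Phred; median available). Reads without
qualities pass.

Classification scores the read and its reverse complement against every
variant × state reference with unit-cost edit distance (edlib, infix
mode, so the aligned reference span is known), after a shared-k-mer
prefilter (k = 13) that restricts alignment to the top-ranked candidate
references — references within a screen share most of their sequence, so
the candidate list is generous (default 32). The single best reference
wins only if it beats the runner-up by a **margin ≥ 2** edit operations;
this separates references differing by a single 9-nt GGS repeat while
refusing genuinely ambiguous reads, which are never tie-broken randomly —
they are flagged and excluded. The aligned span must fully contain the
target-site and fusion-diagnostic intervals (containment; an
overlap-fraction mode exists).

Rates are `n_rec / (n_rec + n_unrec)` per variant; reads with
undetermined state are excluded from numerator *and* denominator. A raw
odds output (`n_rec / n_unrec`) is provided separately. Gel-based
efficiencies use the same fraction on band intensities supplied as
numbers (image densitometry is out of scope). Heat maps pivot keyed rate
records into linker × spacing matrices per orientation;
`summed_left_right` pools counts over all (L, R) linker pairs with equal
L + R before recomputing the rate, so pooling conserves counts.

Two-phase demultiplexing assigns each read to a backbone
(recombinase × state — e.g. three recombinases give six phase-1
references), then within the winning backbone's library of insertion
variants; the recombination state carries over from phase 1. The margin
rule doubles as the "unambiguously mapping" criterion, which published
descriptions leave unspecified.

## Affine alignment and insertion profiling

The Gotoh three-matrix recurrence computes optimal global alignments
under affine gap scoring: a gap of length L costs
`gap_open + L·gap_extend`; defaults are match +2, mismatch −4, gap_open
−4, gap_extend −2 (chosen for noisy long reads; the original screen's
aligner parameters are not published, so they are configurable).
Traceback tie-breaks are fixed (match/mismatch > deletion > insertion) so
CIGARs are deterministic. The inner loop is numba-compiled.

Insertion runs within `tolerance` (default 0) of the 15-nt target are
extracted from the CIGAR and **left-normalized**: placement of an
insertion adjacent to a repeat is alignment-ambiguous, so events shift to
the leftmost equivalent position (idempotent, length-preserving).
Reference coordinates map to residue junctions by nearest codon boundary
(`round((pos − orf_start)/3)`); sequencing errors shift apparent
positions off frame, hence rounding rather than strict mode (strict is
available). By default all accepted events of a read are counted
(one-per-read mode available); profiles merge across libraries for
cumulative views, and `top_positions` ranks junctions with ties going to
the lower index.

## Motif scanning

PPMs use `(count + c)/(n + 4c)` with pseudocount c = 0.1 by default
(suited to matrices built from ~6 aligned sites); PWMs are
`log2(p/background)` with a uniform default background. P-values are
computed by DP convolution of per-position score distributions after
discretizing the matrix into 0.001-score bins; a conservative
`ceil(width/2)`-bin slack absorbs the difference between binning a summed
score and summing binned entries, so `p(min_score) = 1` exactly, p is
monotone non-increasing in score, and DP agrees with exhaustive 4^w
enumeration within the discretization bound (verified for widths ≤ 8).
Windows containing non-ACGT bases are skipped; minus-strand hits are
reported at forward-strand coordinates.

The composite lox scan tests each 13-bp half matrix independently against
the p-threshold (conservative AND) with an unscored fixed-length 8-bp
spacer between them; a full-34-bp single-matrix mode is available via
`scan_sequence` for relaxed-specificity site searches. The
flank-constrained scan then requires a ZF motif whose near edge lies 4–6
bp (inclusive) from the lox boundary: upstream on the reverse strand and
downstream on the forward strand in the site's own frame (minus-strand
lox hits are mirrored). Hits report which sides conform (`both`, `left`,
`right`).

The evolved-clone tally compares equal-length protein sequences to the
designed parent, counting per-position mutated clones and distinct
non-parent residues; indel-containing clones are rejected, matching the
fixed-length ZFD comparison this summarizes.

## Synthetic data

The generators define the study conditions for every test:

- **Error model:** i.i.d. per-base substitutions and single-base indels.
  The standard "3 % error" condition is substitutions 1.5 %, insertions
  0.75 %, deletions 0.75 % — a long-read-like error mix without
  homopolymer structure. Per-read Phred values are constant per read,
  drawn from N(12, 3) clipped to [2, 40], so the Q ≥ 10 filter has both
  outcomes (~¾ of reads pass).
- **Screen reads:** each read picks the REC template with probability
  equal to its variant's planted rate, is reverse-complemented with
  probability ½, then mutated.
- **Insertion reads:** one 15-nt insert at a junction drawn from a
  planted distribution. Inserts are resampled so the planted placement is
  already left-normal (otherwise the planted coordinate itself would be
  ambiguous); the optional duplication mode emulates Mu-transposition
  chemistry (insert = 10 random nt + a copy of the 5 nt immediately 5′ of
  the junction), where the canonical placement necessarily sits 5 nt
  upstream — the truth table records both the sampled and the canonical
  junction.
- **Planted genomes:** uniform (or biased) random background with
  non-overlapping composite blocks at recorded coordinates; truth emitted
  as a table/BED.

Determinism: one integer seed per run; per-read substreams come from
`SeedSequence(seed, spawn_key=(read_index,))`, so results are independent
of generation order.

What passing these tests does **not** show about real data: no
homopolymer or pore-specific error structure, no chimeric reads or
adapters, no coverage bias across variants, and uniform-random genome
background rather than real genome composition. Rates and p-values on
real data inherit whatever biases those effects introduce.

## Problem sizes

Chosen so the full suite and the acceptance script each run comfortably
on one CPU: rate recovery uses 10 variants × 1,000 reads (≈2 kb
amplicons); insertion profiling a 343-codon ORF with 120 error-free plus
300 noisy reads; plant-and-recover a 100-kb genome with 8 positive and 1
negative plant; the aligner oracle 40–60 random pairs ≤ 12 nt; p-value
enumeration all widths 2–8.

## Known limitations

- The classifier's margin is in edit operations; scores are not
  quality-aware.
- The exact p-value DP assumes position independence (standard PWM
  assumption) and a fixed background; no higher-order background model.
- The composite scan's AND combination of half-site p-values is
  conservative; composite-level p-values are not calibrated jointly.
- Insertion profiling assumes one reference ORF; paralog cross-mapping is
  not modeled.
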