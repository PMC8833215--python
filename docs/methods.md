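# Methods

## Scope and model

`delfold` implements the informatic backbone of a dual-library selection:
a bead-displayed DNA-encoded small-molecule library screened against a
library of RNA three-dimensional folds, with a base-paired RNA as the
counter screen.  Three measurement processes are modeled:

1. sequencing of DNA tags from FACS-sorted beads (compound identity),
2. sequencing of selected vs starting RNA pools (fold preference),
3. annotation-driven mapping of preferred folds onto miRNA hairpins
   (target nomination).

Wet-lab aspects — bead chemistry, FACS gating physics, microarray
fabrication, binding thermodynamics, cell assays — are out of scope;
their outputs are this package's inputs.

## DNA encoding

Each library member is the 4-tuple (cycle-1 amino acid of 96, hub
diastereomer, acylation route R2/R3, cycle-2 acid of 192).  The hub
stereocenter is not encoded (the synthesis uses a stoichiometric
diastereomer mixture), so the 73,728 members map onto 36,864 tags; all
tag-level analyses (decoding, replicate counting, selectivity, clustering)
operate on the stereo-collapsed key, and stereochemistry is resolved only
downstream when hits are resynthesized as pure diastereomers.

Tags are positional: `primer5 | codon(R1) | codon(acid) | codon(acyl) |
primer3`.  Codons default to 8 nt with pairwise Hamming distance ≥ 3,
designed by seeded rejection sampling over one joint pool (so cross-field
pairs also satisfy the distance bound) and checked by brute-force all-pairs
verification; infeasible requests fail the Singleton bound or the search
budget explicitly.  Production codon tables can be loaded from JSON
configuration — the design here is contract-compatible plumbing, not a
claim about any particular instrument's tag set.

**Decoding.**  Primers anchor exactly; each codon field maps to the
nearest table codon within `max_mismatch_per_codon` (default 1).  With
design distance 3, one error per codon is uniquely correctable (errors
below half the distance cannot reach another codeword's ball); ambiguous
or out-of-tolerance fields return reason-coded failures rather than
exceptions so decode statistics remain computable.  A bead is called by
majority vote over its decoded reads; ties and read-less beads are dropped
and logged.  Channel selectivity is a hard set-difference of compound keys
between the target (DY647) and counter (TAMRA) tables — the in-silico
analogue of the two-color sort gate.

**Clustering.**  Leader clustering on Tanimoto similarity, threshold 0.8:
seeds processed in descending replicate class *k*, ties broken
lexicographically by compound key, each hit joining the first seed at or
above threshold.  This is deterministic and order-invariant by
construction; the representative is the max-*k* member.  The default
fingerprint is a building-block one-hot (4 bits per member), which makes
similarity a share-count of building blocks and keeps the package free of
a cheminformatics dependency; Morgan structure fingerprints (rdkit) plug
in when assembled SMILES are available.

## Enrichment statistic

`Z_obs` is the pooled two-proportion z statistic on (selected, library)
counts; its square is the 1-df chi-square statistic of the 2×2 table
without continuity correction, which the test suite verifies against an
independent implementation.  An unpooled-variance variant is provided
behind a flag for sensitivity analysis; the pooled form is the default and
is what the `privileged` call uses.  The privileged cutoff is fixed at
`Z_obs > 4` with no further multiple-testing correction — the cutoff is an
empirical affinity-anchored operating point, not a p-value procedure.  At
the default simulation depth (10⁵ reads over 4,096 folds, expected count
≈ 24 per fold) the null distribution of `Z_obs` is close to standard
normal (KS distance ≈ 0.03; upper z = 4 tail consistent with 3.2 × 10⁻⁵),
so the false-call budget at the cutoff is a fraction of a fold per
selection.

When a compound is selected at several doses, the default privileged set
is the union over doses; a highest-stringency-dose policy is available
(`dose_policy="max_dose"`).  Per-dose results are always emitted.

**Profiles and difference logos.**  Position profiles count nucleotide
frequencies over the six window positions, optionally weighted (e.g. by
`Z_obs`).  Information content is 2 − H bits per position; the small-sample
correction e_n = 3/(2·ln2·n) is off by default and flag-controlled.
Profile pairs are compared by per-position Jensen–Shannon divergence
(base 2): 0 for identical columns, 1 bit for disjoint point masses,
symmetric and bounded.

## Loops, windows, and the 3×3 frame

The fold library's six variable nucleotides may partially pair, so a
library member presents as anything from a 3×3 internal loop down to a
1×1 loop inside a longer helix.  Matching therefore works on **windows**:
an extracted a×b loop (a, b ≥ 1, ≤ 3) is padded back to the 6-nt frame
using flanking base pairs.  Padding crosses only genuine Watson–Crick or
GU pairs; symmetric loops pad the same number of pairs on each strand, and
padding is balanced (window centered on the loop), which makes the 1×1
window unique (one closing pair each side — `5'GAG/3'CCC` is the 1×1 A·C
loop closed by G:C pairs), gives a 2×2 loop its two one-sided choices, and
a 3×3 loop itself.  Asymmetric loops pad each strand independently and a
motif match on any window counts, mirroring database-style motif lookup.
Bulges (0×n) are extracted and reported but excluded from 3×3 matching by
default, since the library is an internal-loop pattern.

Coordinates are 0-based half-open internally and 1-based inclusive in all
file I/O (miRBase/GFF convention); cleavage bonds are indexed by the
number of nucleotides 5' of the cut.  The hairpin cassette (12-nt tails,
6-bp GC-rich stems, UUCG tetraloop) is configuration, not a claim about
any particular construct; any production cassette drops in.

`nussinov_fold` (base-pair maximization, WC+GU, min hairpin 3,
deterministic traceback) exists only as a synthetic-data convenience;
real hairpin structures are inputs.  Thermodynamic folding is deliberately
out of scope.

## Processing sites and target ranking

Drosha cleaves at the 5' end of the 5p arm and the 3' end of the 3p arm;
Dicer at the 3' end of the 5p arm and the 5' end of the 3p arm — all four
bonds derive directly from the mature-arm intervals, and one-armed entries
yield only their derivable cuts.  A loop is "in" a processing site when
its boundary lies within K nt of a cleavage bond or spans it; K defaults
to 2 nt and is exposed as `--site-window`, since the biological definition
of the site's extent is not sharp.  Disease association is an input flag
per hairpin (curated upstream).  Candidates are ranked within each
(motif, site) group by expression (reads per million, mean over
experiments as provided), with pairwise fold-differences reported to two
significant figures — expression weighting reflects that occupancy, and
hence functional effect, scales with target abundance.  All loop
occurrences are reported, not only site-overlapping ones, so tandem motif
copies near a site surface naturally.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *informatic* structure of the inputs under
known ground truth:

- **Bead reads** — per-bead read replicates (default 5) with i.i.d.
  per-base substitutions; substitution-only by design, since the decoder
  is positional (indel tolerance would be a decoder extension, not a
  property of the screen).  No PCR duplication, chimeras, or quality-score
  structure.
- **Selection counts** — starting library multinomial over a uniform
  4,096-fold distribution; selected pool multinomial with planted
  per-fold enrichment factors.  Real starting libraries are non-uniform
  (the pipeline takes sequenced library counts as input; the uniform model
  is the simulation fallback), and real selections have replicate
  structure this model omits.
- **Toy miRnome** — fully paired random stems with mature arms at fixed
  columns, motifs planted as pair/loop columns at exact bond distances,
  log-normal expression (median 500 rpm, σ = 2 — a heavy-tailed spread of
  the kind mature-miRNA counts show).  Real hairpins have bulges,
  multiloops and imperfect arms that these constructs do not.

Passing recovery tests therefore demonstrates the pipeline's correctness
under its stated error model — not performance on any particular
instrument's noise, nor on a real genome-scale miRNA database (whose
counts depend on the external database and its structure predictions).

## Problem sizes and numerics

Default analysis sizes: full 73,728-member enumeration (exact cardinality
checks are instantaneous); planted screens of 60 beads (15 compounds × 3
beads, plus counter channel), selections at depth 10⁵ over all 4,096
folds, null calibration over 100 replicate selections (≈ 4 × 10⁵ null
statistics), and the exhaustive 4,096-member structural round-trip.  These
sizes keep the full suite and the acceptance script in the seconds-to-
minutes range while exercising the same regime as a production run.

Tie-breaking is lexicographic everywhere a ranking needs determinism
(bead votes are ties→drop; cluster seeds and representatives by (−k,
key)).  Degenerate inputs: `Z_obs` returns 0 when the pooled proportion is
0 or 1; Tanimoto of two empty fingerprints is 0 by convention; the
standard deviation of a single compound's fold count is 0 by convention;
zero-rpm competitors make fold-differences infinite and flagged.  All
randomness flows through `numpy.random.default_rng` with explicit seeds;
identical seeds produce byte-identical artifacts.

## Known limitations

- The encoding scheme is contract-compatible with bead-tag designs, not
  sequence-identical to any published tag set; decode accuracy claims are
  about the design distance, not a specific instrument.
- Selectivity filtering is a hard set-difference; a frequency-aware filter
  (e.g. ratio of channel replicate classes) would be a natural extension
  for noisier data.
- Asymmetric-loop windowing is a documented package choice (independent
  per-strand padding); other motif databases may frame such loops
  differently.
- The miRnome scan counts motif occurrences in internal-loop windows of
  supplied structures; results are only as good as the structure
  annotations given.
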