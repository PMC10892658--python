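# Methods

This note documents the models, conventions and design choices behind
scripkit, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not show.

## Domain model

A candidate record is a coding sequence (CDS) with its translation and
biology metadata (species, hexacorallian family, lineage, genome vs
transcriptome origin, completeness, life stage, tissue).  Coordinates are
1-based and inclusive; `signal_peptide_end` is the last residue of the
signal peptide.  Complete records must satisfy `translate(nt) == aa` under
the standard genetic code; a terminal stop is stripped, an internal stop
is an error, and any codon containing a non-ACGT character translates to
`X`.  `X` (and ambiguous nucleotides) never count as matches in any
identity computation — the conservative reading of "informative =
non-ambiguous, non-gap".

Support-annotated trees accept three internal-label dialects: a bare
number (bootstrap %), an IQ-TREE-style `SH-aLRT/aBayes/bootstrap` slash
triplet, or an opaque clade name.  Missing support is stored as absent and
never coerced to zero, so a support-thresholded rule cannot accidentally
pass an unlabelled node.

## Cysteine frameworks

The descriptor grammar is `("C" ["P"] ["(" int ")"])+` with an optional
trailing tail count.  `CP(k)` places a proline immediately after the
cysteine and counts it inside the gap (gap = k+1): this is the only
reading under which homologous descriptors keep the same gap sums at the
same framework positions across species.  Underscores and spacing in
published tables are normalised away; `format(parse(s))` is the canonical
form.  When a peptide carries more than eight cysteines the derivation
uses the first eight and the caller is expected to flag the record — how
supernumerary cysteines were treated upstream is generally not stated in
survey papers, so the choice is explicit here.  Frameworks are derived
from whatever region is supplied (preprotein or mature); the region used
should be recorded alongside.

## Screening cascade

Stages run in a fixed order — length, duplicate collapse, secretion,
homology — and each stage is idempotent; a record rejected at stage *k*
carries no outcomes for later stages, so every rejection is attributable.
Boundary semantics follow the usual wording of such filters literally:
length bounds inclusive (60 and 100 aa pass), signal-peptide probability
strictly greater than 0.65, identity ≥ 40% kept.

The duplicate collapse groups records by exact protein equality only
(the 100%-identity clustering threshold); representatives are the
lexicographically smallest id, so the operation is deterministic and
idempotent.

Secretion features come from an external predictions TSV when available
(`id, sp_prob, cleavage_end, tm_count`) — neural predictors are out of
scope and their outputs are ingested, not imitated.  The built-in
stand-in is a transparent hydropathy heuristic: the score is a fixed
logistic `1/(1+exp(-2.0·(m - 1.8)))` of the maximal 8-residue mean
Kyte–Doolittle hydropathy *m* within the first 30 residues, and the
predicted cleavage is the end of the best window plus two residues.  The
constants were chosen once so that hydrophobic signal-peptide cores
(mean KD ≈ 2.5–4.5) score well above 0.65 and hydrophilic N-termini well
below; sequences shorter than 20 residues score 0.  Transmembrane
segments are counted as clusters of 15-residue windows with mean KD ≥
2.0, clusters separated by more than one window length counting
separately; the signal peptide itself is one such segment, hence the
"at most 1" default.

Homology is exhaustive pairwise Needleman–Wunsch (BLOSUM62, gap open 10,
extend 1) against the reference panel — reference sets here are at most
hundreds of short peptides, so a heuristic search adds nothing.  Identity
uses alignment columns (including gap columns) as the denominator, the
stricter convention, stated in report headers.  An e-value ceiling is
retained only for optionally ingested external hit tables.

## Identity and masking

Codon alignments require gaps as whole codons.  A codon column is kept
when its informative fraction is ≥ the threshold ("less than" drops);
defaults are 0.10 before tree building and 0.50 before selection
analysis.  Pairwise identity over masked columns excludes positions where
both rows are gaps and counts one-sided gaps as mismatches (the "union"
denominator).  Published identity values may follow either convention, so
"overlap" (both rows non-gap) is available as a switch; all reports state
which was used.  Protein identity is computed from the codon alignment's
translation rather than an independent protein alignment, keeping ni and
pi on identical column sets.  p-distance = (100 − identity)/100; it may
violate the triangle inequality, which neighbor joining tolerates.

## Tree inference

Classical Saitou–Nei neighbor joining with a deterministic tie rule
(the joined pair with the lexicographically smallest leaf-name pair wins)
and negative branch-length estimates clamped to zero.  NJ on p-distances
replaces external maximum-likelihood inference so that delimitation is
testable self-contained; externally computed ML trees are read through
the Newick parser and everything downstream is tree-source-agnostic.
Bootstrap supports resample masked codon columns with replacement
(default 1000 replicates; large published analyses use 10,000, a
deliberate, documented divergence), rebuild NJ per replicate, and score
each original bipartition by its replicate frequency.  Rooting places the
root on the branch separating a declared outgroup, errors listing
intruding leaves if the outgroup is not monophyletic, and reassigns edge
supports so that every edge keeps the support of its (unchanged)
bipartition — including the two root children, which share the root-edge
bipartition.

## Subfamily delimitation

Top-down search from the root: a clade is accepted when its subtending
node's bootstrap support is strictly above `min_support` (default 95),
its mean within-clade nucleotide identity strictly above `min_within_ni`
(default 55), and its mean identity to every already-accepted subfamily
and every sibling candidate strictly below `max_between_ni` (default 55).
A failing clade is decomposed into its children; leaves never captured
are reported unplaced, not force-assigned.  "Divergence node" is read as
the accepted clade's own subtending node, and the between-group rule is
evaluated against accepted subfamilies and sibling candidates — the only
reading that makes the criterion decidable top-down.  All thresholds are
configurable because published clade tables in this family include groups
at support 70–91 and within-identity 47%, i.e. real analyses have applied
the criteria loosely; reproducing such partitions is a matter of passing
relaxed thresholds, not of changing code.

Names are Greek letters in first-encounter order on the ladderized tree
(children by descending subtree size, ties by smallest member id), so the
first major clade is α; machine-readable outputs spell `alpha`, `beta`, …
and glyphs appear only in human-readable output.  Note one property that
does *not* hold: the number of accepted subfamilies is not monotone in
`min_support` — a clade that fails a raised threshold can split into two
accepted children.  What is monotone (with the between-group rule
inactive) is the set of placed leaves, and the test suite asserts exactly
that, alongside equivalence with an exhaustive clade-enumeration oracle.

## Selection analysis

Preprocessing mirrors standard practice for secreted toxins: the signal
peptide is removed (it evolves under different pressures than the mature
toxin), named high-divergence outliers can be excluded, and each analysis
replicate keeps one randomly chosen paralog per species (default 3
replicates; replicate r draws from a stream seeded `seed + r`), so the
species diversity is identical across replicates.

Counting follows Nei–Gojobori (1986): each non-stop single-nucleotide
neighbour of a codon contributes ⅓ of a site to its class, stop
neighbours contribute nothing (so ES+EN = (9 − stops)/3, checked against
an enumeration oracle for all 61 sense codons).  Ancestral codons come
from Fitch parsimony over codon states, with ambiguity resolved toward
the state carried by the most leaves of the subtree, ties broken
lexicographically; leaves with gap/ambiguous/stop codons carry no state
and their branches are skipped.  Multi-nucleotide changes average N and S
over all shortest mutational pathways avoiding stops (all pathways in the
rare case every one is blocked).  Expected sites are summed over the
parent codon of each counted branch.

The per-site test is a two-sided exact binomial of round(N) successes in
round(N+S) trials against EN/(EN+ES) — the rounding of pathway-averaged
counts is the one approximation, stated here; significance defaults to
α = 0.05 with no multiple-testing correction (matching the conventions of
the per-site tests this emulates), and a significant site is called
positive or negative by whether the observed nonsynonymous proportion
exceeds expectation.  The global estimate ω = (ΣN/ΣEN)/(ΣS/ΣES) is
undefined (reported absent, with a warning) when no synonymous change is
observed.  This counting estimator stands in for likelihood codon-model
fits (MG94-style); it is labelled as SLAC-style counting and never as an
equivalent of MEME/FEL/FUBAR, whose output tables can be ingested for
reporting instead.

## Synthetic data generator

The generator emulates the structure of the real family: a hydrophobic
signal peptide (default 22 residues, M + draws from {L,A,V,I,F}), a
mature region of 48 residues (the family's mature peptides span roughly
40–48 aa) realising a fixed eight-cysteine framework with the
tail-triplet hallmark, four subfamilies by default, and per-subfamily ω
regimes defaulting to one diversifying (1.3) and three purifying
(0.65/0.6/0.55) groups, mirroring the published pattern of one
positively selected subfamily among purifying ones.

Evolution is per-branch codon substitution sampling: proposals are
uniform over mutable codon positions and alternative bases; stops, new
cysteines, and prolines directly after cysteines are never created
(framework conservation mirrors the real family); nonsynonymous proposals
are accepted with min(1, ω) and synonymous with min(1, 1/ω).  Because
proposal mass is proportional to neighbour counts, the realised N/S ratio
tracks ω·EN/ES and the counting estimator recovers ω to within ~25–30%
at 150 codons — verified, not assumed.  This is a transparent
simplification, not an MG94 rate matrix: it has no transition/
transversion bias, no codon-frequency structure, no rate variation among
sites, and no indels, so passing benchmarks demonstrate correctness of
the counting machinery and of the screening/delimitation logic, not
robustness to those real-data complications.

Identity structure is calibrated by bisection on substitution counts:
the total separation that realises the within-subfamily identity target
(default 75%) and the between-subfamily target (default 45%) is found on
trial pairs, then members diverge from subfamily ancestors and ancestors
from the root accordingly.  The deep structure is a star (the true tree's
root is a polytomy of subfamily ancestors), so arbitrary resolutions of
it earn low bootstrap support while planted clades earn ~100% — the
situation the delimitation criteria are designed for.  Targets are
realised to within ±2 percentage points; the within/between gap of 30
points comfortably exceeds the 20-point margin at which delimitation
recovery is expected.  With targets 75/45 the *merged* identity of two or
three subfamilies sits near the 55% threshold (~54%), which is the
realistic hard case: at unlucky generator seeds a merged group can edge
just above 55 and the criteria then legitimately accept the merger.  The
packaged benchmark datasets use fixed generator seeds, which is also how
the planted-recovery condition is defined.

Members redraw deterministically (attempt-indexed streams) if evolution
happens to assemble a second hydrophobic run that the TM heuristic would
read as a membrane segment, so every emitted record passes the default
cascade by construction.  Decoys share the family's ancestral templates
so that they fail *only* their planted criterion: length violations keep
intact secretion features and homology; the no-signal decoy replaces the
signal with hydrophilic residues; the extra-TM decoy appends a
C-terminal hydrophobic segment well separated from the signal; the
low-identity decoy randomises everything including its own (independent)
signal so its best-hit identity lands near 25%, far from the 40%
boundary.

## Reporting

Percentages are rounded half-even to two decimals; published tables
occasionally truncate (63.09 vs 63.10 for 106/168), so comparisons allow
±0.01.  Replicate-mean ω values are arithmetic means rounded to three
decimals.  Every pipeline run can emit a manifest (tool version, config
hash, seeds, input checksums, per-stage counts) sufficient to reproduce
its outputs byte-identically.

## Problem sizes

The packaged benchmarks are sized for a single CPU: families of 32–40
records with 48-codon mature regions, 100–200 bootstrap replicates,
selection simulations of 12 taxa × 150–200 codons with 20 seeds per
regime, and exhaustive topology enumeration at 4–5 taxa.  The full test
suite runs in ~10 s and the acceptance script in ~5 s.

## Known limitations

- The signal-peptide/TM heuristics are deliberately simple hydropathy
  statistics; they are calibrated for the synthetic benchmarks and for
  triage, and real analyses should ingest predictions from dedicated
  predictors via the TSV interface.
- NJ + nonparametric bootstrap is not ML inference; supports on real
  data will differ from ultrafast-bootstrap values, and published ML
  trees should be supplied as inputs where available.
- The counting selection test has low power at few sequences (binomial
  trials are per-site substitution counts); it controls type-I error
  conservatively (~1–3% at α = 0.05 in the neutral benchmark).
- Alignments are inputs: the package masks and analyses codon MSAs but
  does not build them, and there is no indel simulation.
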