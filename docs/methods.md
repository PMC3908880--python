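# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the known limitations.

## Motif detection

The eight-cysteine motif is treated as a *subsequence* pattern: eight
cysteines satisfying the `CC` adjacency and `CXC` one-residue separation,
with the five gap lengths constrained to configurable per-gap bounds.
Residues inside gaps are unconstrained and extra cysteines outside the
chosen eight are permitted, since genuine family members can carry
additional C residues.  Default bounds (s1 3–20, s2 8–25, s3 5–35,
s4 8–35, s5 3–25) are the envelope of all spacings observed across the
reference family, widened with margin; they are configuration, not a
claim about the family's true limits.

When several eight-cysteine assignments are valid, selection is
deterministic: prefer assignments whose signature classifies to a named
type, then the leftmost first cysteine, then the smallest total span,
then lexicographic position order.  Family curation in practice is
manual; this rule is a reproducible proxy, validated by reproducing the
full reference inventory and by exhaustive-enumeration oracle tests on
short sequences.

## Type classification

Classification uses only the spacing signature — not sequence identity.
Rules are evaluated in a fixed order chosen as the minimal ordered set
consistent with every member of the 63-protein reference family:

1. s3 = 19 → I; 2. s1 = 7 → II; 3. s1 = 14 → V; 4. s1 = 13 → IX;
5. s3 = 13 → XI; 6. s4 = 12 → III; 7. s4 = 27 → VII;
8. s1 = 6 ∧ s4 = 25 → VIII; 9. s1 = 10 ∧ s2 ∈ {16,17} → VI;
10. s3 ∈ {9,12} ∧ s1 ∈ {9,10} → IV; otherwise unclassified.

The precedence of s3 encodes the family's own ruling on its most
ambiguous member (XI-like s1/s2 but s3 = 19 → type I).  Types IV and VI
have no single diagnostic gap and are resolved by envelope membership.
Unclassified signatures are reported as candidate nsLTP-Y only when the
protein passed the full identification cascade, because the Y group is
defined residually, not by a diagnostic.  The per-type envelopes ship as
YAML and can be overridden for other genomes.

Limitation: surveys in this field typically classify primarily by
sequence-identity clustering and use spacings as a cross-check; here the
spacing rules *are* the classifier.  On the reference family the two
agree exactly (63/63 labels), but the spacing rules alone cannot
adjudicate types defined only by similarity (e.g. the Solanaceae type X).

## Identification cascade

Stage order and semantics are described in the package README.  Choices
that needed a declared constant:

- **Proline-rich threshold**: a protein is removed when the
  Pro+His+Gly fraction of the region between the signal-peptide cleavage
  and the first motif cysteine is ≥ 0.35.  The literature says only
  "high proportion"; 0.35 sits well above the background expectation of
  ~0.16 for uniform composition and well below genuine hybrid
  proline-rich linkers (≥ 0.5).  Configurable.
- **Alignment thresholds**: external E-value cutoffs are mapped to raw
  local-alignment scores via Karlin–Altschul statistics because E-values
  depend on the original database size, which is not reproducible.
  Protein side: BLOSUM62, gap open −11 / extend −1, gapped λ = 0.267,
  K = 0.041; an E ≤ 1e−3 cutoff at a ~1e7 search space gives a raw-score
  threshold of ≈ 75 (the rescue default).  The storage/inhibitor
  exclusion threshold (raw score 100) is a declared constant — no
  threshold is stated anywhere for that step.
- **Identity rescue route**: identity ≥ 0.5 counts only over alignments
  of ≥ 50 columns, because the best local alignment of unrelated
  sequences is short and can have high identity by chance.
- **Signal peptides, GPI anchors and domain calls are inputs**, produced
  by dedicated predictors outside this package and read from a TSV.  A
  hydrophobic-core heuristic (8-residue window with ≥ 6 hydrophobic
  residues in the first 30 positions, cleavage 5 residues after the
  core) is available for annotation-free runs and is explicitly
  lower-fidelity.

## Per-protein descriptors

Masses are average (not monoisotopic) masses of the free mature peptide,
computed with Biopython's standard residue table; reported family masses
match average-mass magnitudes.  The isoelectric point solves
net-charge = 0 by bisection on pH 0–14 to 1e−3, using a Bjellqvist-style
pKa set (N-term 7.50, C-term 3.55, D 4.05, E 4.45, H 5.98, C 9.0,
Y 10.0, K 10.0, R 12.0) — the constants behind the common web
calculators.  Cysteine side chains are excluded from the charge model by
default: mature nsLTPs hold all eight cysteines in disulfide bonds, so
free-thiol charges are not physical.  Exact pKa constants differ between
tools, so cross-tool pI agreement is tolerance-based by nature; the
bisection is verified against a dense-grid oracle to 2e−3 pH units.
The residue between the `CXC` cysteines is classed hydrophobic
(Y/L/F/V/I/A/G) or hydrophilic (R/K/E/Q) per the groups observed in the
family, with a Kyte–Doolittle fallback for unobserved residues.

## Genomic context

Tandem duplication: two family members on one chromosome are tandem
duplicates when at most five gene loci lie between them, measured on
genome-wide gene ordinals (for BRAD-style loci, the numeric part of the
identifier), chained by single linkage so a cluster may span more than
the bound end-to-end.  On the reference family this recovers all 19
published tandem genes — including the four-gene cluster that mixes
three type XI members with a type I member — and correctly excludes the
pair separated by six loci.  Known limitation: locus distance alone also
pairs one adjacent but sequence-divergent pair of type I loci
(Bra036788/Bra036789, coding identity near 50%) that the original
synteny-based duplicate calling did not treat as duplicates.  Tandem
*duplication* implies homology; a locus-distance rule cannot see
sequence divergence.  The tests pin this behaviour explicitly.

Intron phases are computed in coding orientation (exons reversed for
minus-strand genes): the phase after cumulative coding length L is
L mod 3, and intron lengths are genomic gaps between consecutive exons.
Phases are therefore strand-symmetric by construction.

## Digital expression

EST clusters are assigned by local nucleotide alignment (match +1,
mismatch −2, gap −5/−2) under joint thresholds: raw score > 100 and
Karlin–Altschul E < 1e−10 (λ = 1.28, K = 0.46, database size
configurable, defaulting to the total cluster length).  TPM is
count / library-total × 1e6.  Specificity calls depend only on the
zero/nonzero pattern over the six surveyed organs (bud, flower, leaf,
root, seed, silique): exactly one nonzero organ → single-organ; support
exactly {bud, flower} → inflorescence; rows with no numeric organ data →
no-data; anything else → broad.  Auxiliary whole-plant/unspecified-tissue
columns never disqualify specificity.  Applying the inflorescence rule to
the packaged expression matrix yields seven bud+flower genes where the
original prose counts six; the discrepant gene is elsewhere argued to be
inflorescence-specific, so the rule is kept and the prose count treated
as the inconsistency.

## Promoters and cis-elements

Promoters are the ≤ 2 kb immediately upstream of the translation start,
truncated at the adjacent upstream gene or the contig edge (truncation
reason recorded), reverse-complemented for minus-strand genes.  Motifs
are IUPAC strings keyed by PLACE identifiers; matching is
exact-degenerate, both strands by default, overlapping occurrences
counted, and an N in the subject never matches any code.  Whether the
original counts were single- or double-stranded is not stated anywhere;
both-strand counting is the PLACE convention and is configurable.

## Synthetic data

The generators emulate the *structure* the analyses assume, not the
evolution that produced it: planted spacing signatures are drawn
uniformly from each type's envelope; inter-cysteine segments are uniform
over the 19 non-cysteine residues (a stray C would corrupt the planted
signature); the flank between signal and first cysteine is additionally
P/H/G-free so planted members sit clearly below the proline-rich
threshold; signal peptides are hydrophobic-core-first, 21–27 aa (27–35
for the 7-kDa-type members).  Decoy classes are constructed to fail
exactly one cascade stage.  Planted tandem clusters use intra-cluster
ordinal gaps within the bound and inter-item gaps beyond it; planted
promoters are screened so the background contains no accidental motif
hits.  Consequences: passing tests demonstrate exact recovery under
noiseless, identifiable conditions — they do not demonstrate robustness
to real-proteome ambiguity (multiple near-valid motifs, borderline
linker compositions, partial annotations), which is why the cascade also
carries property tests (conservation, length-cap monotonicity) that hold
regardless of composition.

## Problem sizes and determinism

The default test suite runs a 123-protein synthetic proteome through the
cascade, 50 planted round-trips per type for the motif detector,
exhaustive-enumeration oracle checks on sequences ≤ 60 aa, and the
packaged 63-member reference tables; the whole suite completes in well
under a minute on one CPU.  All generator randomness flows through a
single seeded `numpy.random.Generator`; placement arithmetic is integer,
so outputs are platform-stable.  Reports are byte-stable across reruns
with the same inputs and seed.

## What is *not* reproduced

Genome-scale identification (the 152-candidate funnel) requires the full
*B. rapa* proteome and live external predictors; the package documents
the cascade as the computation of record and runs it on synthetic
proteomes instead.  Sequence-identity phylogenetics (NJ/Bayesian trees),
synteny-block and subgenome assignment, 3-D structure prediction, and
qRT-PCR analysis are out of scope.  The published mature-protein
sequences themselves are not redistributed; descriptor operations
(mass, pI, pentapeptides, tryptophan) are validated against independent
oracles and the printed per-gene mature lengths (64–120 aa) rather than
against recomputed per-protein values.
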