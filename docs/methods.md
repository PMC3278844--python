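# Methods

This note documents the models and procedures implemented in `ptigsid`,
the parameter choices behind them, and what the synthetic-data tests do
and do not demonstrate about real data.

## The identification problem

The *psbA–trnH* intergenic spacer (PTIGS) is a short plastid region with
high discriminating power across land plants, but frequent indels make
its multiple alignment unreliable, which breaks the usual
alignment-centric barcoding pipelines. Identification here is
nearest-neighbor: a query is assigned the species of the reference
sequence(s) at minimal distance. Nearest-neighbor is used because, for
barcoding markers with porous species boundaries, one-nearest-neighbor is
as reliable as model-based classifiers while staying interpretable.

## Base distances

**DNFP (D).** Each sequence is reduced to its vector of k-mer frequencies
over {A,C,G,T}^k (lexicographic coordinates). Sliding windows containing
any non-ACGT character are skipped and excluded from the window total.
The distance is d = 1 − r with r the Pearson correlation of the two
frequency vectors, so identical (or proportionally composed) sequences
are at 0 and anti-correlated profiles approach 2. Pearson correlation is
invariant to positive scaling, so counts and frequencies give the same
distance; frequencies are stored and the invariance is asserted by test.
A zero-variance profile (all 4^k frequencies equal — essentially
impossible for real sequences at k = 2) has undefined correlation; it is
defined as r = 0 (d = 1) with a warning. Default k = 2 (the
di-nucleotide profile, which already separates most species pairs at a
fraction of the cost of larger k); k is configurable 1–8, with 4^k vector
growth the reason for the cap.

**Edit distance (E).** Unit-cost Levenshtein distance (substitution,
insertion, deletion each cost 1), computed by `edlib`. "Substitution"
means any base to any other; no transition/transversion asymmetry. E is
the only base method that uses *every* nucleotide of both sequences,
which is why it has the highest resolution on indel-rich spacers — and
the highest cost.

**P / K2P (P).** A Needleman–Wunsch global alignment (match +1, mismatch
−1, gap −2, linear) is computed; columns containing a gap or an ambiguity
code in either row are excluded. Over the remaining comparable columns,
the p-distance is the mismatch proportion, and the Kimura two-parameter
distance is d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) with P/Q the
transition/transversion proportions. Method P reports K2P by default
(`p_metric="p"` switches to the raw proportion); K2P ≥ p always, the two
converge at low divergence, and saturated alignments (log argument ≤ 0)
return +inf with a warning rather than raising mid-scan.

**Local alignment (B).** Smith–Waterman with blastn-like scoring (match
+1, mismatch −3, gap open −5, extend −2). The distance is the negated
raw score; a best score ≤ 0 is "no hit". Auxiliary output carries the
raw score, percent identity over the aligned columns (2 decimals), and
1-based inclusive query/target spans, mirroring tabular similarity-search
reports. E-values and BLAST bit-score statistics are deliberately not
reproduced: ranking by raw local score needs no database-size statistics.

Global and local alignments are computed by `Bio.Align.PairwiseAligner`;
among co-optimal tracebacks its deterministic first-listed alignment is
taken, so all outputs are bit-stable. The alignment engine's optimality
is cross-checked in the test suite against exhaustive recursive
enumeration on short strings, and edit distance against the naive
recursive definition.

## Cascades

A chain (e.g. D+P+E) runs its first stage over the whole database and
collects every target within tie tolerance of the minimum distance
(ε = 1e−9 for real-valued distances — doubles computed identically must
tie — and exact for integer edit distance). If the tied set maps to a
single species the chain stops, resolved. Otherwise the next stage
recomputes distances *only between the query and the tied candidates*,
re-ties, and so on; this candidate restriction is what makes hybrid
methods nearly as fast as their first stage. "Unsuccessfully identified"
means the tied set spans more than one species taxid (not more than one
sequence): a tie among conspecifics is already a species call. If a
stage yields no hit (method B against entirely dissimilar candidates),
the chain falls through to its next stage over the same candidate set.
After the last stage any remaining multi-species tie is reported as
`ambiguous` with all tied species, matching a server that returns "taxid
or taxids". Chains must start with one of the two fast methods (B or D);
the eight named chains are B, B+P, B+E, D, D+P, D+E, B+P+E, D+P+E.

## Reference database and consensus

Records are indexed along two dimensions: locus region (5′/core/3′/full)
and taxonomy level (species, genus, family, order, class), with the
lineage stored as a flat per-species level map (the NCBI taxonomy tree is
not mirrored; taxids are the species labels). Records with region
`unknown` are treated as core, since bare spacer submissions carry no
region annotation. `retrieve` with region `full_locus` returns records
stored as full loci; it does not synthesize loci by concatenating
separately stored parts. Database construction can require a minimum
number of core sequences per species: 1 for identification databases, 2
for evaluation databases (leave-one-out with self excluded is undefined
for singleton species).

Per-species consensus references are built by star alignment: every
member is globally aligned to the longest member, the pairwise alignments
are merged into one matrix (insertions relative to the center padded to
their maximum length), and each column is voted — columns where gaps are
the strict majority are dropped, ties among bases become the covering
IUPAC ambiguity code. This is a deliberately simple, fully specified
substitute for legacy assembler-based consensus building; for
same-species spacer variants (high identity, scattered indels) the star
alignment to the longest member is adequate. How discordant within-
species variants "should" be merged is genuinely open; majority voting is
a choice, not a reconstruction of any particular assembler's behavior.

## Evaluation

Leave-one-out, core region only. Include-self mode searches the full
database (the query always finds itself at distance 0; the question is
what ties with it); exclude-self removes the query record but keeps its
conspecifics. Success under the default `species` criterion: the final
tied set's species equal exactly the query's species; cascades ending
`ambiguous` therefore count as wrong unless all surviving species match.
The literal `strict_sequence` reading — the tie set is the query alone —
is available behind a flag for include-self mode, because the two natural
phrasings of include-self success differ precisely when a species
contains duplicated sequences; the species-level criterion harmonizes
with the exclude-self definition and is the default. Counts always
conserve: correct + wrong = number of queries, asserted for every chain
and mode. Mean per-query wall time is reported for orientation only;
it is hardware-dependent and never asserted.

`kmer_size_scan` evaluates the single-stage D chain at each requested k;
`evaluate_by_taxon` partitions queries by their lineage at a chosen level
while still searching the full database, matching per-group reporting of
a global search.

## Profile-HMM annotation

A minimal position-specific profile (match/insert/delete states) is
estimated from an alignment of conserved flank fragments: columns with
> 50% gaps become insert columns, the rest match columns; match emissions
are column base frequencies with +1 Laplace pseudocounts; transitions are
counted from each sequence's implied state path, also with +1
pseudocounts. Recommended training input is > 10 fragments of 20–30
aligned positions (a warning fires below 10). Scanning is local-mode
Viterbi in log-odds bits against a uniform background: the profile may be
entered and left at any match state, unmodelled flanking residues are
free, and insert emissions equal the background (log-odds 0). The default
acceptance threshold is 0 bits; raise it (e.g. 10–15 bits) to suppress
spurious matches when flanks may be absent. Equivalence with HMMER bit
scores is a non-goal; the model is self-contained and its coordinate
recovery is validated on planted-motif fixtures.

`annotate_locus` scans both strands with the 5′ and 3′ models, keeps the
strand with the higher combined score (forward wins ties), and reports
the core as the interval between the 5′ match end and the 3′ match start
— coordinates always 0-based half-open on the input's forward strand. One
flank above threshold gives a `partial` annotation with an open-ended
core; none gives a `none` result (not an exception); a 3′ match
preceding the 5′ match on the reading strand is an error, since no
consistent segmentation exists.

## Synthetic data

The generator emulates the marker's data regime rather than any specific
clade: a uniformly random root core (length drawn from 250–450 nt)
descends a family → genus → species hierarchy, accumulating substitutions
(default 0.15/base per edge) and indels (default 0.02/base per edge,
geometric lengths with mean 3 nt — a standard minimal indel model) at
inter-species rates, then individuals diverge at intra-species rates
(defaults 0.01 and 0.002). One ancestral 25-nt flank pair is attached to
every locus, substituted per individual at the intra-species rate with
*no* indels, so each dataset's flank sets double as ungapped training
alignments for the HMM module. Taxids are consecutive integers from
900,000,000, far above real NCBI taxids. Ambiguity (N) injection defaults
to 0 and is switched on only to test the ambiguity-handling rules.
Everything is reproducible byte-for-byte from the seed.

What passing tests on this generator show: the distance kernels, tie
logic, cascade semantics, evaluation bookkeeping and boundary recovery
are correct, and identification behaves as theory predicts (perfect at
intra ≪ inter divergence, degrading as they approach). What they do not
show: real PTIGS success rates. Real data carry micro-inversions,
clade-specific composition bias, mislabelled vouchers and shared
haplotypes across species — none of which the generator models — so
published-scale success ratios (~0.56–0.78 across methods on an ~11k
GenBank-derived dataset) cannot be reproduced or predicted from synthetic
fixtures, and the evaluation-scale tests here use 30-sequence datasets
(10 species × 3 individuals) chosen to keep the full eight-chain,
two-mode evaluation matrix comfortably desk-scale.

The bundled worked-example trio (`exemplar_trio`) is likewise synthetic:
three targets differing from a query by exactly one substitution tie
under local-alignment score (position-independent mismatch cost), while
K2P separates the transition from the transversions — reproducing the
classic cascade demonstration in which a local-alignment tie across two
species is resolved by the P stage. With raw-score ranking an
exact-copy construction cannot produce such a tie (an exact copy
out-scores every imperfect match, and a contained exact copy has K2P 0),
which is why the trio uses equal-scoring single-substitution variants.

## Numerical and degenerate-input choices

- Sequences are uppercased and U→T on input; non-IUPAC characters are a
  parse error naming the position. Ambiguity codes: excluded from P/K2P
  comparable sites, mismatched in alignment scoring unless identical,
  and k-mer windows containing them are skipped.
- A taxonomy TSV overrides header taxids, with a warning on conflict;
  duplicate accessions with conflicting taxids are an error.
- K2P of identical sequences is clamped to exactly 0.0 (avoiding −0.0);
  saturation returns +inf with a warning.
- Empty chains, empty databases, mixed-species consensus input,
  ragged HMM training alignments and zero-match-column alignments are
  errors; unknown retrieval taxids warn and return empty.
- All randomness flows through seeded `numpy` generators; hypothesis
  profiles are derandomized, so the suite is deterministic.

## Known limitations

- BLAST statistics (e-values, bit scores) are not reproduced; method B
  ranks by raw Smith–Waterman score.
- Alignment scoring parameters for P/E/B follow stated conventions; other
  parameter choices would shift cascade tie structure on real data.
- The consensus procedure is order-insensitive but center-dependent: a
  different longest-member choice could shift gap placement in rare ties.
- The profile HMM is a minimal local-mode implementation — no
  calibration, no e-values, no model file interchange.
- Identification quality is only as good as the reference database;
  queries from species absent from it are unreliable by construction.
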