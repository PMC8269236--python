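# Methods

## Model and procedure

`cobpath` treats curated functional-gene profiling as a three-stage database
construction followed by best-hit read assignment.

**Registry.** A gene (sub)family has a unique id, an annotation, a non-empty
set of member pathways, and a symmetric homology relation to other families.
Sub-family suffixes (`cobC-beta` vs `cobC-ado`, `cobS-co` vs `cobS-gdp`) are
distinct ids: same gene symbol, different enzymatic role.  Families shared by
several pathways are stored once with a pathway-membership set; the packaged
per-pathway count fixture carries one printed row per (family, pathway) pair
and is validated to be identical across a shared family's rows before
collapsing.  Pathway rollups come in two share modes: `replicate` (a family
shared by k pathways contributes its full count to each, so pathway totals
over-count relative to family totals) and `fractional` (the count is split
equally, conserving total mass).  Both are always emitted, since either
convention is defensible for pathway-level percentages.

**Database tiers.** Seed: curated records stored as-is (duplicate ids and
unknown families are errors).  Core: each candidate is globally aligned
against the pooled seeds of its nominal family *plus declared homolog
families*; it is recruited to the best-hit seed's family if global identity
≥ 0.30, with score ties resolved by the family holding the majority of tied
seeds and final ties by lexicographic family id.  Full: orthology groups are
classified by best-hitting each member against the core targets — a group
merges into a family when ≥ 50% of its members best-hit that family at the
identity floor, becomes a homolog-decoy group when at least one member hits
any target, and is dropped otherwise; genome proteins are then routed to the
family or decoy group of their best hit (carrying taxonomy); finally,
byte-identical residue strings within a family/group are collapsed to the
earliest-inserted representative.  Identical strings in *different* buckets
are flagged, not collapsed: collapsing could silently delete a family's only
evidence.  Tier monotonicity (seed ⊆ core ⊆ full target ids) holds by
construction and is tested.

The 50% majority fraction is an auditable surrogate for curator judgement;
the per-group report carries the evidence (members hitting, top family, hit
fraction) so every automated call can be reviewed.  Candidates failing the
30% floor are discarded and reported; they are not retained elsewhere.

**Profiling.** Each read receives the single best hit over targets ∪ decoys.
Best hit on a target ⇒ `assigned(family)`; on a decoy ⇒ `homolog_absorbed`;
none ⇒ `unassigned`.  The three statuses partition every read set (tested as
an invariant).  Absorption is the mechanism that suppresses false positives:
with decoys present, a homolog-derived read's best hit is the decoy, so the
read never inflates a family count.  Removing the decoys ("small database")
re-exposes those reads to the targets; `small_db_effect` quantifies the
fraction of decoy-absorbable reads among those a targets-only database
assigns, overall and per family (the denominator convention — all
core-assigned reads vs per-family reads — is ambiguous in general, so both
are reported).

Relative abundance divides family counts by the number of *assigned* reads;
gene-length normalisation is available but off by default, and the choice is
recorded in the profile metadata.  Taxonomy defaults to best-hit transfer
(the read inherits its best-hit reference's 7-rank lineage); an external
k-mer classifier can be plugged in as a callable adapter but is never
re-implemented here.

## Alignment and search conventions

* Engine: Biopython `PairwiseAligner` (optimal Needleman–Wunsch /
  Smith–Waterman, affine gaps).  Default scheme BLOSUM62 with gap open 11,
  gap extend 1; a gap of length k costs `11 + k`.  Global alignments
  penalize end gaps.
* Identity = identical columns / all alignment columns including gap columns
  (local: columns of the local span only).  This is a declared convention;
  published search tools differ in their identity denominators, so the
  convention is documented rather than inferred.
* Best hit: highest score passing the identity floor (default 0.30) and the
  score floor; score ties broken by higher identity, then lexicographically
  smallest reference id.  Repeated calls and permuted databases give the
  identical hit (tested).  Co-optimal *tracebacks* are resolved by the
  engine's deterministic preference order; scores and hit choices never
  depend on it.
* Score floors: 0 in global mode (optimal global scores between unrelated
  proteins are strongly negative, and the identity floor gates the rest);
  60 raw units in local mode.  The local floor is a Karlin–Altschul-style
  estimate: for fragment queries of ≤ 80 residues against desk-scale
  databases (~10²–10⁴ reference residues × ~10² references) the expected
  maximal unrelated local score is ≈ 45, while any true fragment hit at
  ≥ 40% identity scores well above 100.  E-values belong to external
  engines; the adapter contract enforces e-value ≤ 1e-4 and identity ≥ 30%
  on BLAST-style 12-column tabular input.
* Nucleotide reads (detected by alphabet, overridable) are translated in six
  frames with the standard code (stops `*`, N-codons `X`, trailing partial
  codons dropped); the best frame's best hit is used.
* Full-length protein queries (candidate recruitment, the artificial
  evaluation set) are searched in global mode, matching the recruitment
  contract; fragment reads use local mode.

## Synthetic data: what it emulates and what it does not

The generator plants one random i.i.d. ancestor protein per family
(default length 180–240, uniform residue background) and derives members by
point substitutions to a sampled identity in 0.90–0.99.  Decoy groups mutate
a randomly chosen *family ancestor* down to 0.40–0.60 identity — decoys are
genuine homologs that attract hits, reproducing the small-database mechanism
— and then add within-group members near the decoy ancestor.  Unrelated
sequences are fresh i.i.d. draws.  Each family carries one planted 7-rank
lineage (phylum drawn from five common bacterial phyla).  Reads are sampled
by community proportion, source member and start position uniform, lengths
40–80 residues (the scale of merged short-read pairs after translation);
optional reverse translation (uniform codon choice) produces nucleotide
reads whose source peptide appears in exactly one frame.

Mutation is substitution-only by default so that identity is exactly
controllable and truth audits need no alignment; an indel mode exists but is
off.  The artificial evaluation set defaults to 143 target-derived, 57
homolog-derived and 70 unrelated full-length queries, mirroring the
published evaluation design (its actual sequences are not public; the
generator reproduces the design, not the sequences).

Consequences for interpretation: real protein families have conserved
domains, indels, compositional bias and inter-family homology continua; real
decoy sets are not uniformly 40–60% distant.  Passing the synthetic
accuracy checks therefore demonstrates the *correctness of the machinery*
(assignment logic, decoy absorption, bookkeeping) under separable identity
tiers — not field accuracy on real metagenomes, where the published
large-scale percentages (e.g. the ~52% reassignment fraction on ocean data)
depend on real database content and are out of desk-scale reach.

## Numerical and design choices

* Exact deduplication means byte-equal strings, replacing 100%-identity
  clustering; it is idempotent and bit-reproducible.
* Bray–Curtis is computed on the union key set (absent = 0) and errors on
  two all-zero profiles.  PCoA is classical scaling (double-centred −D²/2,
  `eigh`, eigenvector scaling by √λ) with a deterministic per-axis sign
  convention; negative eigenvalues — expected for Bray–Curtis — are
  reported and their axes dropped, with no Lingoes/Cailliez correction.
* Degenerate inputs: empty read sets give empty (not erroneous) results;
  zero assigned reads give all-zero abundances with an explicit flag; an
  empty reference set is an error; absence of a best hit is a value.
* Problem sizes in tests and the acceptance script (3–10 families, 2–8
  members, reads ≤ 5,000, lengths ≤ 240) were chosen as the smallest scales
  at which the statistical checks (3-binomial-SE recovery, separability)
  are meaningful.
* `--threads` distributes reads over a process pool; results are
  independent of thread count and database record order (tested).

## Known limitations

* The built-in searcher is optimal but exhaustive (no seeding/indexing); it
  is meant for desk-scale validation and tests, with external engines
  adapted through the tabular contract for production-scale searches.
* Manual curation steps in the original workflow (keyword refinement,
  semimanual orthology inspection) are represented by explicit, logged
  rules, not reproduced.
* Identity-based recruitment with a single global floor cannot separate
  families whose genuine divergence is below 30%; the homolog-pool +
  majority-rule mechanism handles declared homologs only.
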