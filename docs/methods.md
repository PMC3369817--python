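# Methods

This note documents the models and procedures implemented in `panclog`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic test bed does and does not establish about real data.

## Orthology model

Orthology is inferred from reciprocal similarity alone, with no synteny or
tree reconciliation. The unit of similarity is the local-alignment bit
score; the unit of orthology evidence is the bidirectional hit rate

    BHR(a,b) = (S(a,b) / S_b^bestA) · (S(b,a) / S_a^bestB),

the product of each direction's score normalised by the partner's best
score against the other gene's genome. BHR lies in (0, 1] whenever both
directed hits survive the score floor, equals 1 exactly for mutual best
hits, and is undefined (treated as 0) otherwise. The model assumes that
genuine orthologs are near-mutual-best hits; in-paralogs and out-paralogs
are not distinguished, and domain-level chimerism is invisible to a single
pairwise score.

Clustering proceeds in two stages. Pre-clusters are connected components of
the BHR ≥ 0.95 graph; because components can chain weakly related genes
through intermediates, each pre-cluster is re-clustered agglomeratively:
merge the entity pair with the highest inter-entity BHR while that maximum
is ≥ 0.75, recomputing the merged entity's similarity to each other entity
as the size-weighted average (|A|·BHR(A,C) + |B|·BHR(B,C)) / (|A|+|B|).
This incremental update is algebraically identical to the plain mean of all
cross gene-pair BHRs — the package's tests exploit that equivalence by
checking the production path against an independently coded mean-over-pairs
agglomerator. The final entities over all pre-clusters partition the gene
universe: every gene is in exactly one CLOG.

### Scoring

The internal scorer is Smith–Waterman with BLOSUM62, gap open 11, gap
extend 1 (a length-k gap costs 11 + k), run through Biopython's C pairwise
aligner. Raw scores convert to bits with the standard gapped
Karlin–Altschul parameters, bits = (0.267·S − ln 0.041)/ln 2. Only relative
magnitudes matter to BHR, so the conversion constants affect nothing except
the interpretation of the 50-bit floor. The scorer is exactly symmetric;
imported tabular scores (blast outfmt-6-style, bit score in the final
column) need not be, and the pipeline never assumes symmetry downstream.
`X` residues score 0 against everything; other ambiguity codes are
rejected. The floor is applied at table construction, so best-hit queries
range over surviving hits only.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `min_bits` | 50 bits | directed hits below this are discarded |
| `cap_same_genome` | 0.95 | ceiling on within-genome BHR |
| `ortholog_threshold` | 0.95 | BHR ≥ threshold ⇒ putative ortholog edge |
| `upgma_min` | 0.75 | agglomeration stops below this average BHR |
| codon `n_select` | 100 genes | selection size per codon-usage profile |
| codon `n_repeats` | 100 | re-selections averaged into d² |
| codon `min_len_aa` | 50 aa | length floor for codon-usage genes |
| rarefaction `n_iterations` | 1000 | sampled strain permutations |

The 0.95 cap together with the ≥ 0.95 threshold deliberately lets
within-genome mutual-best pairs (recent duplicates) enter pre-clusters;
no additional same-genome exclusion is applied.

## Numerical choices

- Missing BHR values (one or both directions below the floor) contribute
  exactly 0 to the agglomeration average; this is the conservative reading
  of a rejected hit.
- Threshold comparisons are exact (`>=`, no epsilon); BHR is kept at full
  double precision. Reproducibility is preferred over leniency at the
  boundary.
- Agglomeration ties on the maximal BHR are broken toward the merge whose
  combined sorted gene-id tuple is lexicographically smallest; component
  and CLOG orderings are by smallest member id. All outputs are therefore
  byte-stable under a fixed seed.
- Rarefaction quantiles use linear interpolation between order statistics
  (`numpy` default); at 1000 iterations the choice of quantile convention
  is immaterial.
- The gene-sharing distance transform (max entry minus entry) does not
  guarantee a zero diagonal; the diagonal is explicitly zeroed before
  neighbor joining, which requires a hollow matrix.
- Negative neighbor-joining branch lengths are clamped to zero with the
  difference moved to the adjacent branch (scikit-bio's `neg_as_zero`),
  matching common practice. Outgroup rooting inserts the root at the
  midpoint of the outgroup's pendant edge.
- Codon frequencies are pooled (codon counts summed over the selection,
  then normalised per amino acid), not averaged per gene. An amino acid
  absent from a selection carries frequency 0 for all its codons, so it
  contributes to d'² only if the other group observed it. Stop codons are
  excluded everywhere; a single trailing stop codon on an input CDS is
  stripped, internal stops are errors.
- Groups smaller than `n_select` contribute all their genes (selection is
  without replacement); the profile records how many genes were used.
- r_x uses the averaged d² in numerator and denominator; the KS test runs
  on the two 100-value replicate samples with the asymptotic p-value.
- EC "incomplete forms" generalise field-wise: x is an incomplete form of
  y if every field of x equals y's or is `-`. Collapse keeps the more
  specific number and is idempotent.
- The shared-EC heatmap clustering uses Hamming distance (fraction of
  disagreeing strain columns) with average linkage, for both rows and
  columns.

## The synthetic pangenome generator

The generator plants K strains and three family classes — core (all
strains), shared (a uniform 2..K−1 strain subset), unique (one strain) —
with one ancestor protein per family, i.i.d. uniform over the 20 amino
acids, length uniform on 60–400 aa (never below the 50-aa codon-usage
floor). Members diverge from the ancestor by i.i.d. per-site substitution
to a uniformly chosen different residue; there are no indels by default.
Optional within-genome paralogs are copies mutated at a quarter of the
family divergence, exercising the same-genome BHR cap. Coding sequences
are back-translated with per-strain synonymous-codon preference tables
(preferred codon weight 0.85 by default) for core and shared genes and one
separate, independently drawn table for all unique genes, emulating the
atypical codon usage of strain-specific genes. Written CDS records carry a
conventional trailing stop codon, stripped again on read. Identical
configuration and seed give byte-identical fixture files.

What this emulates well: mutual-best-hit structure within families,
well-separated families (uniform random ancestors essentially never align
above 50 bits), the U-shaped strain-count distribution, and a clean
core/unique codon-usage contrast. What it does not emulate: realistic
amino-acid composition and low-complexity regions (which inflate spurious
hits in real proteomes), indels and domain shuffling, gene birth/death
phylogenetics, horizontal transfer, GC-content gradients, and annotation
noise. Passing the planted-recovery tests therefore demonstrates the
pipeline's correctness, not that real proteomes will cluster with the same
fidelity — real data inherit all the ambiguity of borderline similarity.

The standard test fixture uses 5 strains, 10 core + 20 shared + 6
unique-per-strain families (144 genes) at divergence 0.1. The codon test
bed uses 3 strains with 150 core and 120 unique families each (810 genes).
The null calibration of r_x draws both groups from a single codon table
with 800 genes of 60 aa per group: group sizes must exceed the 100-gene
selection by a wide margin, because two selections from the *same* small
group share most genes, deflating d²(core,core) and biasing r_x upward
even under the null. With 800-gene groups the residual bias is a few
percent and the null median of r_x sits near 1.

## Known limitations

- All-vs-all scoring is quadratic in total gene count and single-threaded;
  desk-scale collections (a few hundred genes across a handful of strains)
  cluster in seconds, but full bacterial proteome collections should import
  precomputed blast scores via `load_external_scores` instead of the
  internal aligner.
- The BHR graph is built only from surviving directed pairs; a gene whose
  every hit falls below 50 bits is structurally a singleton, which
  overcounts unique genes in fragmented or highly divergent inputs.
- The core/shared/unique trichotomy degenerates for K = 1 (a single-strain
  CLOG is labelled core); K ≥ 2 is enforced where the distinction matters.
- EC annotation quality is entirely inherited from the input gene→EC
  mapping; the package validates the format, not the biology.
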