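# Methods

## Model

`uscgam` estimates the abundance of a gene *per genome* in a mixed microbial
community. The core assumption is that 14 ribosomal protein families
(large- and small-subunit ribosomal proteins; one or two KEGG Orthology ids
and one COG each) are present in essentially every bacterial and archaeal
genome exactly once. Summed over a sample, each family's depth-normalised
abundance (RUSCG, in RPKM) is then an estimate of the community's "genome
equivalent" on the RPKM scale, and the ratio of a gene's RPKM to that
community size is the fraction of genomes carrying the gene (times its copy
number):

* `RPKM = MRC × 10⁹ / (TRC × L)` with `MRC` the retained alignment count of
  a reference sequence, `TRC` the sample's length-filtered read total (a raw
  count; the 10⁹ combines the per-million and per-kilobase scalings), and
  `L` the reference length in bp. Protein reference lengths from translated
  search are converted at 3 bp per residue (`aa_to_bp=3`; set 1 for
  nucleotide databases).
* `RUSCG_f` sums per-subject RPKMs over a family's member references. The
  sum (rather than a pooled count over an average length) stays well defined
  when members differ in length and reduces to the plain RPKM for
  single-member families.
* `MRUSCG` is the geometric mean of the 14 RUSCG values, computed in log
  space. The geometric mean damps occasional false-positive multi-copy
  matches in single families far better than the arithmetic mean.
* `GAM = RG / MRUSCG × 100 %`.

The per-sample coefficient of variation of the 14 RUSCG values (sample
standard deviation over the mean; the 14 families are treated as a sample)
is reported as a quality diagnostic: large CV means the single-copy
assumption or the alignment filtering is failing for some families.

## Alignment handling

Tabular alignments are reduced to a single hit per read before filtering —
highest bitscore, then lowest e-value, then lexicographically smallest
subject id — emulating an aligner run with single-best-hit reporting. Order
matters: when a read's best hit fails the filters, the read is dropped even
if a weaker hit would have passed, exactly as with aligner-side truncation.
Marker hits are filtered on bitscore ≥ 40 and per-HSP query coverage ≥ 80 %
(no identity test; the references are conserved enough that bitscore carries
the specificity); gene hits on identity ≥ 50 % and coverage ≥ 80 % (no
bitscore test). All bounds are inclusive and user-adjustable. Coverage is
taken from the aligner-reported `qcovhsp` column rather than recomputed, to
avoid depending on read lengths at parse time.

## Parameters

| parameter            | default | meaning |
|----------------------|---------|---------|
| `min_length`         | 50 bp   | reads shorter than this are excluded from TRC; 50-bp reads are retained |
| `uscg_min_bitscore`  | 40      | marker-hit bitscore floor |
| `uscg_min_coverage`  | 80 %    | marker-hit query-coverage floor |
| `filter_identity`    | 50 %    | gene-hit identity floor |
| `filter_coverage`    | 80 %    | gene-hit query-coverage floor |
| `derep_identity`     | 0.60    | reference dereplication identity |
| `zero_policy`        | `na`    | marker family with zero abundance ⇒ MRUSCG is NA |
| `aa_to_bp`           | 3       | protein→nucleotide length conversion for Eq. RPKM |

A family with zero retained hits would make the geometric mean zero and
every GAM infinite; the default policy therefore reports MRUSCG (and all
downstream GAM values) as NA with a warning naming the zero families. A
pseudocount policy (10⁻⁶ RPKM by default) exists for exploratory use; it
was deliberately not made the default because it silently converts "marker
not observed" into "very large GAM".

## Reference dereplication

References are clustered greedily, longest first (ties by id), each sequence
joining the first representative sharing ≥ 60 % global identity (identical
columns / alignment length under a Needleman–Wunsch alignment with affine
gaps). This preserves the semantics of word-based clustering tools — greedy,
longest-first, fixed identity — without their word-filter heuristics, so
representative sets are deterministic but not bit-identical to external
tools; a precomputed representative FASTA can be supplied instead.

## Synthetic communities

The simulator generates ground-truth fixtures for parameter-recovery
testing. A community of `n_genomes` genomes (default abundances uniform)
each carries one copy of every marker family; the first
`round(carriage_fraction × n_genomes)` genomes also carry one copy of the
target gene. Each genome is a fixed `genome_length_bp` stretch (default
500 kb) in which the marker and gene loci occupy length-proportional slices
and the remainder is unaligned background. Reads are thrown multinomially
over (genome × locus-or-background) cells with probability
`abundance × locus_bp / genome_length_bp`, so every locus's expected mapped
count is depth-proportional and the expected GAM equals
`100 × Σ carrier abundances` exactly; the per-family expected RUSCG is
`10⁹ / genome_length_bp` regardless of family length. The fixed genome size
is what makes the estimator unbiased: distributing reads over loci only
would over-weight markers in non-carrier genomes and bias GAM low.

Defaults: 200,000 reads of 150 bp; marker lengths set to typical bacterial
ribosomal-protein sizes (89–275 aa); gene length 1245 aa (the scale of a
nitrate-reductase catalytic subunit); genome length 500 kb, a deliberately
scaled-down genome that keeps each marker at tens-to-hundreds of reads at
this depth. Hit attributes (identity, coverage, bitscore, e-value) are
jittered uniformly above the default filter thresholds so that filtering
preserves the planted counts. All sampling comes from one seeded generator
in a fixed order; outputs are byte-identical for a fixed seed.

`simulate_reads` additionally emits error-free reads as exact substrings of
synthetic nucleotide references (plus an optional fraction of sub-50-bp
decoys for the length filter), and `exact_match_m6` — a deliberately naive
exact-substring matcher usable only on those reads — closes the loop without
an external aligner.

What the simulator does **not** emulate: sequencing errors, chimeras,
between-genome sequence homology, length variation within a marker family,
multi-copy markers, and aligner scoring behaviour. Passing recovery tests
therefore validate the normalisation and filtering arithmetic, not alignment
sensitivity on real data.

## Numerical and interface choices

* Geometric means are computed in log space; they agree with the naive
  product form to 10⁻¹⁰ relative on 14-vectors.
* TPM rescales length-normalised rates to sum to 10⁶ per sample (checked to
  10⁻⁶ relative); CPM rescales raw counts the same way.
* TSV outputs render NA as the literal `NA` and numbers at 6 significant
  digits; re-running on identical inputs is byte-identical. GAM from a
  precomputed RG table is byte-identical to GAM from the alignment path on
  matched inputs.
* For paired-end data only forward (R1) reads are used; the CLI refuses
  filenames that look like reverse mates instead of silently merging.
* The m6 dialect is fixed to 8 columns (`qseqid sseqid pident length evalue
  bitscore slen qcovhsp`) because the math needs subject length and
  coverage; the 12-column standard is accepted when subject lengths are
  resolvable from a reference database.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
recovery studies use 50 genomes, 200,000 reads and 20 seeds per condition
(carriage 0, 0.3, 1.0); oracle-equivalence checks use 10,000 random
alignment rows; normalisation identities use 1,000 random tables. These
sizes give the recovery means a standard error well under half a percentage
point while keeping a full run in seconds.

## Known limitations

* GAM conflates carriage fraction with copy number: a gene at two copies in
  half the genomes and one copy in all genomes both give GAM ≈ 100 %.
* Communities dominated by genomes missing some ribosomal families (reduced
  genomes, some archaea) violate the single-copy assumption and bias MRUSCG.
* The bundled dereplication is quadratic in the number of references; it is
  meant for desk-scale reference sets, with a passthrough for externally
  clustered databases.
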