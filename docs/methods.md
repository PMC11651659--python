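# Methods

## The statistic

splicefans quantifies alternative 3' splice-site (3'SS) usage between two
genotypes from splice-junction read counts. For an alternative junction
that shares the canonical 5'SS of an intron, the **fraction of annotated
splicing** is

    FAnS = n_alt / n_canonical

where both counts are unique-read junction counts in the same
(replicate-pooled) sample. Because numerator and denominator come from
the same gene in the same sample, FAnS is invariant to expression
changes: multiplying all of one genotype's counts by any k > 0 leaves it
unchanged. The between-genotype comparison is the ratio

    FAnS ratio = FAnS_mut / FAnS_wt,    reported as log10.

log10 ratio > 0 means the alternative site is up-regulated in the
mutant. The denominator is the canonical *junction's* reads, not total
gene reads: the canonical junction is the one defined by the annotated
(or count-dominant) 5'SS and 3'SS pair, so the statistic compares two
isoforms of the same splicing decision.

A junction-level percent-spliced-in is carried alongside:
PSI_i = n_i / (n_canonical + sum of n_alt) over the junctions sharing one
canonical end of one intron. This is a junction-ratio PSI, simpler than
event-model PSI definitions used by dedicated differential-splicing
tools; the `delta_psi_ge_10` flag (|ΔPSI| >= 0.10 by default) is labeled
accordingly and is a filter aid, not a significance call.

### Undefined values

No pseudocounts are added by default. FAnS with a zero canonical count,
and ratios with FAnS_wt = 0, are reported as NaN with `ratio_defined =
False` and excluded from ratio summaries; a `pseudocount` option adds a
constant to all four counts for sensitivity analysis. Adding
pseudocounts silently would change the statistic, and the
presence-in-all-samples filter already removes most zero cells.

## Pipeline order and filters

Stages run in this order: per-sample false-positive filter ->
cross-sample presence filter -> replicate pooling -> junction-to-gene
assignment -> canonical-site calling -> event table -> motifs ->
summaries.

* **False-positive filter** (per sample): keep junctions with
  `motif_code > 0` (a canonical splice-site dinucleotide pair in the
  SJ.out.tab dialect) and `unique_reads > 2`. The unique-read rule
  subsumes the "supported by multi-mappers only" rule. Thresholds are
  configurable (`motif_code_min`, `unique_reads_min`).
* **Presence filter**: a junction must survive the per-sample filter in
  *every* sample of the experiment (all four in the default 2x2
  design), so every retained junction has a defined count in both
  genotypes. Toggleable.
* **Replicate pooling**: unique and multi-mapping counts are summed per
  junction within a genotype; strand and motif code must agree across
  replicates.
* **Assignment**: a stranded junction is assigned to an annotated
  intron when both ends fall inside the intron extended by a window
  (default 500 nt) on the same chromosome and strand. The window admits
  acceptors upstream of the branch point and downstream of the
  canonical site (observed alternatives cluster within ~40 nt, so the
  margin is generous). In multi-intron genes the intron with the
  nearest donor wins; junctions matching introns of two different genes
  are flagged ambiguous and dropped; strand-unknown junctions are
  dropped. All drops are counted in the run log.
* **Canonical calling**: the canonical junction per intron is the one
  with the highest unique-read count pooled across *both* genotypes, so
  one canonical site anchors the comparison (per-genotype calling is
  available but can pick different anchors in each strain). Ties break
  toward the junction matching the annotated intron bounds, then toward
  smaller genomic coordinates — a total order, so input order never
  changes the call.

## Geometry conventions

All coordinates are 1-based inclusive (the SJ dialect); junction start/
end are the first/last intron base. On the + strand the donor is the
intron start and the acceptor the intron end; on the − strand the
reverse. Signed distances are in transcript direction:

* `delta_3ss` = alternative acceptor − canonical acceptor
  (+ strand: `alt_end − canon_end`; − strand: `canon_start − alt_start`).
  Negative = upstream (branch-point-proximal side).
* `bp_distance` = alternative acceptor − branch-point adenosine.
  `upstream_of_bp` is `bp_distance <= 0`; both endpoints are included in
  a bin such as "<= 20 nt from the BP", i.e. a threshold of >= 21 nt to
  the BP corresponds to `bp_distance >= 21`.

Alternative-5'SS events (shared canonical 3'SS) receive FAnS, ratios
and PSI but no direction/BP-distance/motif columns, which are defined
only for acceptor shifts.

## Motifs

The last three intron nucleotides (offsets −2..0, transcript
orientation, RNA alphabet) classify the acceptor: `YAG` (Y = C/U, the
consensus), `NAG_nonY` (AG preceded by A/G, e.g. the cryptic GAG class),
`BG` (B = C/G/U at −2, G at −1, not AG), `HAU` (H = A/C/U at −3, AU),
else `OTHER`. AG-ending sites are always judged at position −3 first,
so e.g. AAG is NAG_nonY, never BG. The classifier is total over the 64
trinucleotides (enumerated in tests). Position-frequency matrices for
sequence logos use a default window of −9..+2 (ten intron bases
covering the pyrimidine-tract region plus three exon bases); the window
is configurable and `N` bases are excluded from a column's denominator.
Logo and motif-stratified summaries are restricted to events with
FAnS > 0. Softmasked genome letters are uppercased on read.

## Second-step efficiency

From band intensities of a primer-extension assay, the exon-ligation
efficiency of a reporter is `mRNA / (mRNA + lariat intermediate)`,
bounded in [0,1] and invariant to the arbitrary intensity scale.
Replicate groups are summarized as mean ± SD (ddof = 1) and genotypes
compared per reporter with an unpaired two-sided Welch t-test
(scipy's unequal-variance t-test). Groups with identical values in both
genotypes have no testable variance; they are flagged
`degenerate_variance` with t = 0 and p = NaN rather than ±infinity.
Groups with fewer than two replicates are skipped with a warning.

## Suppressor-screen variant filtering

Variant calls from independently isolated colonies against a
non-isogenic reference share thousands of background SNPs. The
background is the union of the call sets of two colonies isolated on
different plates (any number of background colonies is accepted;
same-plate backgrounds are rejected because a suppressor arising once
could then be present in both sets and be subtracted everywhere). Each
colony's unique set is its calls minus the background; a background
colony subtracts only the *other* background colonies, so its own
candidates survive. Subtraction is monotone (unique sets only shrink as
the background grows) and order-independent. Variant-effect prediction
is out of scope: the `effect_note` column is passthrough.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: two
genotypes x two replicates of bulk RNA-seq over intron-containing
yeast-like genes, with NMD assumed inactive so alternative isoforms
persist. Defaults (one number each, chosen once as a realistic
desk-scale layout):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 100 | single-intron genes on one chromosome |
| `exon_len` / `intron_len` | 300 / 120 nt | gene geometry |
| `bp_offset_from_3ss` | 30 nt | BP-to-canonical-3'SS distance |
| `minus_fraction` | 0.5 | fraction of genes on the − strand |
| `rpg_fraction` | 0.3 | genes labeled RPG (class column only) |
| `expression_mean` | 1000 | expected canonical junction reads/replicate |
| `replicates_per_genotype` | 2 | the four-sample design |
| `noise_model` | poisson | NB with `nb_dispersion` available |
| alt site | −20 nt, 2% usage, fold 5 | one upstream acceptor per gene |

Each alternative site is specified by `(delta_3ss, wt_usage,
mut_fold_change, motif_class)`. **The fold change applies to the site's
FAnS value**, not to its raw usage fraction: mutant usages are derived
by `FAnS_mut = fold x FAnS_wt` and renormalized so per-gene usages sum
to 1 in both genotypes. Under this definition the planted log10 FAnS
ratio equals log10(fold) exactly, which is what recovery tests compare
against.

Counts are simulated at the junction level — every quantity the
pipeline computes is a function of junction counts, so read-level
simulation would add cost without coverage. Each junction's count is an
independent Poisson (default) or negative-binomial draw with mean
`expression_mean x usage`; independent Poisson is used rather than a
multinomial over isoforms because FAnS is a count ratio and the
conditioning does not change it. Each (genotype, replicate) sample uses
an RNG stream keyed by the master seed plus fixed indices, so adding
replicates never perturbs existing samples and identical configs give
byte-identical outputs.

The toy genome is random background with splice elements planted in
transcript orientation (reverse-complemented on −): GT at donors, A at
branch points, UAG at canonical acceptors and a class-representative
trinucleotide (YAG→CAG, NAG_nonY→GAG, HAU→AAU, BG→UGG, OTHER→GAC,
overridable) at alternative acceptors. Conflicting letters from
overlapping planted elements raise an error rather than silently
overwriting. Planted non-AG acceptors (HAU, BG) receive SJ motif code 0
by default, faithful to the dialect — which means the default
false-positive filter removes them, exactly as it would in real data;
`non_ag_motif_code` can be set nonzero to carry them through for motif-
stratified analyses.

What the generator does *not* emulate: alignment artifacts and mapping
bias, overlapping genes, intron-less genes, library-size differences
between samples beyond what the noise model produces, sequencing
errors, and BP shifts accompanying 3'SS shifts. Passing recovery tests
therefore demonstrates correctness of the statistics and of the
strand/coordinate bookkeeping on clean counts, not robustness to
alignment pathology.

## Validation approach and problem sizes

Every pipeline claim is checked against an independent route: the
direction/distance classifier against a literal per-base transcript
walk (1000 random introns, both strands); the motif classifier against
an exhaustive 64-trinucleotide enumeration and an independently written
set-membership oracle; the Welch test against the textbook formula;
filter output against brute-force enumeration of the keep rules; and
the whole pipeline against planted truth (FAnS recovery at usage ratios
0.01/0.1/0.5, depth 1000, 200 genes; ratio recovery at folds 1 and 5)
and against its own strand-mirrored image (reverse-complemented genome,
flipped coordinates and strands must reproduce every event's
classification). These sizes run in seconds and give medians stable to
well within the tolerances asserted (±10% relative on FAnS medians,
±0.1 on median log10 ratios).

## Known limitations

* The event-level PSI is a junction ratio, not an event-model PSI; its
  10% threshold flag is a convenience, not a reimplementation of a
  differential-splicing caller.
* Whether ratios with FAnS_wt = 0 should be floored instead of excluded
  is a judgment call; exclusion is the default, pseudocounts the
  sensitivity knob.
* Canonical-site calling pools genotypes by default; with dominant
  isoform switches between strains, per-genotype calling
  (`pool_genotypes=False`) changes the anchor and hence the sign of
  ratios.
* Genes whose assigned junctions all fail the filters silently produce
  no events; consult the run log's stage counts.
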