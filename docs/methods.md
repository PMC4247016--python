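# Methods

This note documents the models and procedures implemented in `srnascape`,
the defaults that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Data model and coordinates

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is shifted on read and write. An aligned read carries chromosome, interval,
strand, optional sequence, a multiplicity (number of genomic matches; from
the BAM NH tag, the 7th BED column, or 1) and a library label. Its coverage
weight is 1/multiplicity, so the sum of a reweighted coverage track always
equals Σ weight·length over contributing reads. `unique` mode counts only
multiplicity-1 reads. Reads outside the 18–36 nt size selection are flagged
and excluded downstream by default (bounds configurable). The alignment BED
dialect stores the read sequence in the name column because two downstream
analyses (CCA detection, 5′ composition) need the read — not the genome —
sequence.

## Locus clustering and distribution classes

Loci are single-linkage chains of reads with inter-read gap < 100 nt
(end-to-start of nearest reads; overlap = gap 0), kept at ≥ 10 reads. Both
thresholds are parameters; on sorted 1-D intervals the sweep algorithm is
exactly single linkage, which the tests verify against a brute-force
union-find oracle.

A locus is a **PILE** when the majority strand holds ≥ 90% of reads
(strand_fraction S) and ≥ 80% of 5′ ends fall within ±2 nt of the modal 5′
end (localization L); otherwise **DISTRIBUTED**. S and L are exposed in
configuration: they operationalize "strand-specific, highly localized"
processing signatures, and no published constants exist for them, so they
are documented defaults rather than reference values. Modal quantities
break ties toward the smaller value (shorter length, leftmost coordinate)
for determinism.

Candidate processed-sRNA loci are PILEs with dominant length in 19–29 nt,
passing S and L, whose genomic sequence has Shannon entropy ≥ 1.5 bits/nt
and no dinucleotide covering ≥ 60% of it (a DUST-like low-complexity
proxy), and not lying fully inside an annotated rRNA-like structural RNA
without a localized 5′ mode (a degradation proxy). Candidates are typed by
annotation overlap with precedence tRNA > known ncRNA > intergenic-novel.
Merging across libraries takes the interval union; the merged record lists
supporting libraries, and the operation is idempotent and order-independent.

## Category accounting

Two semantics are provided because published per-annotation tables need not
partition the reads: `partition` assigns each read once by a configurable
priority (tRNA > other ncRNA > repeat > gene > intergenic, any-overlap
≥ 1 bp), while `overlap` counts a read in every annotation row it touches.
Fractions use aligned reads as the denominator in both modes. Strand is
ignored: TE-derived reads accumulate on both strands of the element.

## tRF classification

Fragments are mapped to mature-tRNA coordinates (strand-aware) and classed
with 3 nt of anchor slack at either terminus (which absorbs the CCA whether
genome-templated or post-transcriptionally added):

* `3p_short`: length 17–22 nt, 3′-anchored — "around 19 nt" widened to a
  closed window;
* `3p_long` / `5p_long`: length 30–36 nt anchored 3′ / 5′;
* `half_tRNA`: 5′-anchored, 3′ end from the middle of the anticodon loop to
  its end (+slack) — halves are cleaved *at the anticodon*, so a 30–35 nt
  5′ fragment that merely reaches the loop's proximal side stays a 5′-tRF;
* `dloop_anticodon`: length 17–22 nt over the D loop or anticodon loop and
  not 3′-anchored;
* `unclassified` otherwise.

Precedence (most specific first): half > 3′-anchored > 5p_long >
dloop_anticodon; exactly one class per fragment. CCA status is `present`
iff the fragment is 3′-anchored and its **read** sequence ends in CCA,
`absent` for 3′-anchored without CCA, `not_applicable` elsewhere.

## TE / methylation / expression statistics

RPKM = count · 10⁹ / (region length · total aligned reads), reweighted
counts by default (configurable). Bins: low < 5, middle [5, 10], high > 10
— the verbal bin definition uses strict inequalities at both cut points, so
the boundary values are assigned to the middle bin to keep bins exhaustive.
Methylation level is the fraction of overlapping probes called methylated;
regions with no probes are flagged undefined rather than 0. Expression is
dichotomized at the 15th percentile, computed over a reference population
(all genes) when one is supplied and applied to TEs; with all-equal values
everything is "low". TE region sets are filtered to length > 50 nt
(family-level summaries conventionally use > 300 bp).

Association battery: one-sided Mann–Whitney U (H1: coverage higher on
low/none-expression regions; exact distribution for n+m ≤ 20 without ties,
tie-corrected normal approximation otherwise), the same test for methylated
(level > 0.5) vs unmethylated regions, Spearman and Pearson correlations
between methylation level and RPKM, and a pairwise Spearman matrix of
per-region counts between libraries. Groups under 3 regions return NA with
a warning. 5′ composition reports A/C/G/U frequencies at read positions
1–5 (T reported as U).

## Periodicity scan

Coverage (multimapper-reweighted — multimappers are deliberately included
here, unlike the unique-match default elsewhere) is scanned with 1000 nt
windows every 100 nt. Per window: optional linear detrend (default on),
real FFT, main period n/k* for the magnitude-maximal bin k* within the
allowed period band [50, 500] nt (DC-adjacent bins otherwise dominate),
coefficient = |X(k*)| / Σ non-DC |X(k)| ∈ [0, 1]. Windows with coefficient
above 75% of the scan-wide maximum (global by default; per-chromosome flag
available) are significant; ≥ 3 significant windows inside a 5 kb span seed
regions, overlapping seeds merge, and a region's mean period is flagged
when inside 175–225 nt.

Numerical choices, each verified in the tests:

* **Sub-bin peak interpolation.** 1000-nt windows put bins at 200.0 and
  166.7 nt around a 180 nt signal, so the peak position is refined by
  quadratic interpolation over the three bins around k* (applied only at a
  true local maximum, shift clamped to ±½ bin, flag to disable). Exact-bin
  signals (pure cosine, impulse train with an integer cycle count) have
  symmetric neighbors and are returned exactly.
* **Harmonic preference.** A pulse train whose fundamental falls between
  bins leaks its energy over two bins while the second harmonic may land
  on a bin, making the *single-bin* maximum report half the true period
  (180 nt signals showing up as 90 nt). The rule "prefer the longer period
  when the sub-harmonic carries comparable energy" is therefore evaluated
  on 3-bin line energies at floor/ceil(k*/2) with 5% tolerance; a strong
  second harmonic also flags the window as harmonic-ambiguous.
* **Linear detrending.** A window straddling the edge of a deeply covered
  element is a step whose 1/k leakage otherwise produces the scan-wide
  maximal coefficient at the longest allowed period, starving genuinely
  periodic windows of significance. Least-squares line removal suppresses
  this without measurably changing periodic windows.
* All-zero or constant windows return no period and coefficient 0.

## Hairpin evaluation

Candidates are extended by 50 nt flanks (clipped at chromosome ends,
reverse-complemented for minus-strand candidates), and up to the 6 most
abundant distinct fragments (ties: leftmost, then shortest) are proposed as
matures. Folding uses a pluggable backend: the ViennaRNA nearest-neighbor
model at 24 °C — the organism's growth temperature rather than the 37 °C
default — when the bindings are importable, else a bundled base-pair
maximization (Nussinov) whose "energy" is minus the pair count and which is
suitable only for structure-shape tests.

Fold stability is scored by an empirical p-value: the fraction of n = 1000
regions of the same length, drawn uniformly from the genome (strand
probability ½, overlaps allowed), whose MFE is strictly below the
candidate's. Because lower MFE = more stable, a small p means the candidate
folds more stably than random genomic sequence; p < 0.05 is significant.
The p-value is monotone in candidate stability, approximately uniform under
the null (verified by a Kolmogorov–Smirnov check over seeded trials), and
bit-reproducible given the recorded seed.

The star is derived from the structure as the base-pairing partner span of
the mature extended by the 2-nt 3′ tail; duplex status is `both_3p_2nt`
when each strand's 3′ end extends its partner's pairing by exactly 2 nt
(the canonical Dicer signature), `one_side_only` with the signature on one
end, `none` otherwise (including matures not on a stem). A candidate on a
significantly stable fold with a structure-supported star is *miRNA-like*;
the overhang status records whether it is canonical.

## Synthetic data generator

The generator is the package's stand-in for a sequencing study: a uniform
ACGT genome (GC 0.48) on two chromosomes (60 + 40 kb), with planted
features placed at disjoint positions and every read's truth label
recorded. Defaults (all in `SyntheticConfig`):

* 12 pile loci (19–25 nt, 1200 identical reads each, alternating strands);
* one intergenic plateau of two overlapping 24/25 nt stacks (2500 reads
  each) with near-identical 5′ ends;
* a 226 nt U2-snRNA-like gene with a 3′ pile of 2600 reads and a 5′ pile of
  120 reads — the ~22:1 peak ratio of the real two-population U2 locus at
  one tenth of its sequenced depth;
* six 76 nt tRNA genes with canonical arm coordinates, emitting per-class
  tRF reads (600/150/120/80/50 for 3p_short/dloop_anticodon/3p_long/
  5p_long/half); half the genes have genome-templated CCA, the other
  half's 3′-anchored reads get CCA appended to the read only;
* eight TEs (0.9–3 kb; Copia/PiggyBac alternating): methylated ones carry
  ~700 reads/kb of both-strand 25–30 nt coverage clustered into piles
  spaced 190 nt (the coverage shape reported on silenced LTR
  retrotransposons) plus a 30% uniform component, low expression, and
  methylated probes every 60 nt; unmethylated ones carry no planted reads
  and high expression — so the coverage/methylation/expression associations
  exist by construction. One Copia pair is sequence-duplicated and 10% of
  its reads carry multiplicity 2 to exercise reweighting;
* reads over TEs and the periodic region draw their first base as U with
  probability 0.6 (else uniform over A/C/G);
* one 5.4 kb highly methylated region with piles of 60 both-strand 25 nt
  reads spaced 180 ± 2 nt;
* a 5S-like rRNA with an unlocalized 200-read smear (degradation-filter
  exercise) and a Poisson background of ~50 geometric-length reads.

Everything is a pure function of the seed; identical seeds produce
byte-identical written bundles. Depths are roughly 200× below the real
study's 8.1 M reads; they preserve the structural features (size selection,
peak ratios, composition bias, periods, class mixes) but not sequencing
error, adapter artifacts, genome repeat structure or realistic nucleotide
composition — so passing tests demonstrate algorithmic correctness and
statistical power at these planted effect sizes, not performance on real
libraries. At these depths RPKM values are coarse (one read on a 2 kb
region ≈ 14 RPKM at ~35 k aligned reads), which is why expressed TEs are
planted with zero reads rather than "few".

`truth_compare` scores detected loci against the planted table (1 bp
overlap matching): recall over planted loci of the requested kind,
precision over detections matching any planted feature, and class
agreement on matched pairs.

## Pipeline and provenance

`run_all` executes io → loci → categories → trf → te_meth → periodicity →
hairpin, writing TSV/BED/JSON only. Optional inputs (methylation, tRNAs,
expression) skip their stages with a warning; any stage failure raises an
error naming the stage, leaving earlier outputs in place. A manifest
records parameters, the seed, and SHA-256 hashes of every output; reruns
with identical configuration reproduce identical hashes (hairpin seeds are
spawned deterministically from the run seed). HMR-like intervals for
overlap reporting are built by merging methylated probes closer than
200 nt.

## Known limitations

* The candidate-filter constants (strand fraction, localization, entropy)
  are package defaults, not published values; results on real data should
  be read with that in mind.
* The periodicity coefficient is relative to the scan-wide maximum, so a
  single extreme window suppresses significance elsewhere; detrending
  mitigates the common cause but per-chromosome or quantile thresholds may
  suit other genomes.
* Star support is structure-derived; read support for the star is reported
  separately rather than folded into the verdict.
* The Nussinov fallback is not thermodynamic: its MFEs must not be compared
  with nearest-neighbor energies.
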