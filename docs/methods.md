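# Methods

This note documents the models, parameters and numerical choices behind
paleocoat, and what its synthetic-data tests do and do not demonstrate about
real ancient-DNA data.

## Targets and coordinates

Three loci on two amplicons: `MC1R_R301C` and `MC1R_R306ter` (both C→T
substitutions on one 79-nt *Mc1r* amplicon, 15 nt apart, matching their
five-codon spacing) and `CBD103_DG23` (a fixed 3-nt deletion window on a
76-nt *CBD103* amplicon; allele labels K^y = `GGG`, K^B = `-`). Coordinates
are 0-based half-open internally; reports print 1-based positions. The
bundled amplicon sequences are *synthetic stand-ins* of the correct lengths
and variant placements: the real fragments are recoverable from public
consensus records but are not required for any computation here, and every
structural invariant (window content, flanking composition that keeps the
deletion left-alignment unique) is enforced and tested. The deletion window
is deliberately flanked by non-G bases so that the left-normalised gap
placement is unambiguous; on a reference where the window extended a longer
G homopolymer, the annotated window would have to be the leftmost placement.

## Read simulator

The simulator emulates PCR-amplicon pools from degraded template, with
known truth. Per sample it draws, for each of `n_replicates` independent
products, `reads_per_replicate` full-length reads:

1. parental haplotype — allele 1 with probability `allele_bias` (default
   0.5); haplotypes are built by substituting or deleting each locus's
   allele, so the two Mc1r variants are phased allele-1-with-allele-1;
2. orientation — `+`/`-` with equal probability; sequences are stored in
   reference orientation and the flag records the read strand;
3. deamination — each C (on `+` reads) or G (on `-` reads) independently
   flips to T (resp. A) with probability δ;
4. base error — each site independently replaced by one of the three other
   bases with probability ε.

Defaults are the study-like conditions used throughout the tests:
3 replicates × 422 reads (the published per-amplicon average), δ = 0.02 and
ε = 0.002 — δ sits inside the 0.7–1.5 %C→T range such material shows, ε at
a typical pyrosequencing error rate. Deamination is uniform along the read:
the amplicons are 76–79 nt and all downstream statistics are per-sequence
averages, so the end-of-fragment elevation seen in shotgun aDNA would add
nothing but parameters. Read counts are exactly constant (no dropout),
reads are full-length (no fragmentation model), qualities are constant and
unused, and there is no contamination or PCR-duplicate structure — mixing
scenarios can emulate contamination if needed. Consequences for
interpretation: passing tests show the estimators are correct *under this
generative model*; they do not certify behaviour under position-dependent
damage profiles, index hopping, or reference bias, which real data can add.

All randomness flows through `numpy.random.default_rng`; cohort runs derive
per-sample seeds from one master seed, so outputs (including FASTQ bytes)
are reproducible.

## Alignment and pileups

Reads are complete amplicons, so alignment is global (local alignment would
only introduce soft-clip ambiguity). Scoring is match +1, mismatch −1, gap
open −4, gap extend −1, with a length-L gap costing `open + (L−1)·extend`;
N scores as a mismatch against everything. Under these scores an
equal-length read can never prefer a gapped alignment over substitutions
(a gapped equal-length alignment scores ≤ n−9; ≤ 4 substitutions score
≥ n−8), which is the property that stops deamination from ever being read
as the 3-nt deletion. Ties are broken deterministically: traceback prefers
the substitution state, and gap runs are then shifted to their leftmost
score-equivalent placement (the standard indel convention).

The implementation is a vectorised three-state Gotoh DP with full
traceback; the within-row insertion recurrence uses the running-maximum
closed form `Y[i,j] = max_{k<j} max(M,X)[i,k] + open + (j−1−k)·extend`.
Two provably-optimal shortcuts (enabled only for the default scoring, with
the DP as fallback) keep cohort-scale runs fast: equal-length reads with
≤ 4 mismatches take the ungapped alignment, and reads shorter by exactly 3
whose best single-3-gap placement leaves ≤ 1 mismatch take that placement
(any multi-gap structure pays ≥ 9 in gap costs and would need to save ≥ 2
mismatches). Both shortcuts are tested column-for-column against the DP,
and the DP itself against a brute-force recursion.

A pileup records, per reference position, counts over {A, C, G, T, gap,
other}, split by read orientation; every non-skipped read contributes
exactly one symbol per position, so columns always sum to the read count.
Reads with > 20% N are skipped with a warning. A read is flagged as the
deletion allele iff its alignment gaps the *entire* variant window; 1–2 nt
partial gaps there are recorded as "other", never as the deletion — the
ΔG23 event is an exact in-frame 3-nt loss. Insertions relative to the
reference occupy no pileup column.

## Damage statistics

The per-sample consensus is the majority base per position (ties and
zero-coverage positions resolve to the reference). Degradation percentages
are computed per read-site *observation* rather than per consensus site:
the phrase "percent degraded sites" is ambiguous at depth > 1, and the
per-observation definition uses all coverage and stays well defined at any
depth. `pct_degraded` is the percentage of base observations at non-variant
positions differing from the consensus; `pct_ct` pools forward-read T
observations at consensus-C sites with reverse-read A observations at
consensus-G sites (the two orientations of the same chemistry) over the
base observations at those sites. Splitting by orientation makes `pct_ct`
an unbiased estimator of δ; a pooled version would halve it, since each
orientation is blind to the other strand's damage. Variant windows (both
Mc1r windows on that shared amplicon) are excluded so genuine alleles are
never counted as damage; with ε > 0, `pct_ct` absorbs the one-third of
base errors that happen to be C→T/G→A. Zero usable observations raise an
error rather than returning a silent 0.

Group comparison uses Welch's unequal-variance t test (scipy backend,
Welch–Satterthwaite df), two-sided. Identical zero-variance groups return
t = 0, p = 1 — identical measurements carry no evidence of a difference —
rather than NaN; zero variance with different means returns p = 0.

## Variant authentication

`authenticate_variant` runs three screens (defaults: α = 0.05,
concordance tolerance 0.25, het lower bound 0.25, damage factor 3):

1. **damage association** — Welch comparisons of carrier vs non-carrier
   `pct_ct` *and* `pct_degraded` must both be non-significant. The two
   statistics are tested at α/2 each (Bonferroni), i.e. α is a family-wise
   level: with two highly correlated screens, per-test α would nearly
   double the false-alarm rate against genuine variants while adding no
   sensitivity.
2. **replicate concordance** — within each carrier, max−min replicate
   alt-frequency ≤ 0.25 (half the het window: ~10σ of binomial noise at
   400 reads, so genuine alleles pass while irreproducible artifacts fail).
3. **frequency level** — every carrier's mean alt-frequency ≥ 0.25, the
   het lower bound; deamination cannot push a site there.

All pass → `authentic`. If only the frequency screen fails and the mean
alt-frequency is ≤ 3× the measured carrier C→T rate, the signal is
`artifact`; sub-het frequencies well above damage expectation, failed
damage/concordance screens, or insufficient inputs (< 2 carriers, < 2
non-carriers, or a carrier with < 2 replicates) give `inconclusive` with a
reason — never an exception.

## Genotype calling

Replicate alt-frequencies classify as hom-ref (< 0.10), ambiguous
([0.10, 0.25)), het ([0.25, 0.75)) or hom-alt (≥ 0.75). The het lower
bound anchors to the 25–100% frequency range observed for genuine carriers
in this kind of data; the hom-ref ceiling 0.10 sits above plausible
deamination (1–5%) but below the het window. Ambiguous replicates abstain
rather than veto — tolerant of one noisy product — but a call requires
≥ 2 non-ambiguous replicates that unanimously agree; everything else is
ND, the deliberate failure mode. The two Mc1r variants are called
independently on the same pileups; haplotype phasing is out of scope.
At the default depth the windows are far wider than binomial noise
(σ ≈ 0.024 at 422 reads for a het), which is why simulated recovery at
study scale is effectively 100%; the margin shrinks for products below
~50 reads.

## Phenotype rules

Precedence: (1) R306ter e/e → recessive yellow regardless of the K locus;
(2) else ≥ 1 K^B with ≥ 1 E → black; (3) else both determined and wild
type → agouti; (4) a genotype needed by the first applicable rule being ND
→ undetermined. Placing recessive yellow above the K locus is the standard
pigmentation epistasis; the packaged cohort contains no e allele, so that
precedence cannot be discriminated from this material and reports flag the
rule that fired. The agouti phenotype carries the display alias
"Yellow (wild type)" to match the cohort table's column, which labels the
agouti pattern by its yellowish appearance; both labels are reported.
R301C never enters the rules — its phenotypic effect in isolation is not
established — and a test asserts the phenotype column is invariant to that
column.

## Problem sizes in the acceptance checks

Sizes fixed by the pipeline's validation design: 500 cohorts for the Welch
null calibration, 10⁵ observations for rate recovery, 200 trials for the
verdict rates, 50 seeds × 20 samples × 3 × 422 reads for genotype
recovery, 200 random pairs for the alignment oracle, 10⁴ reads for
deletion discrimination. Compositions chosen once for statistical
adequacy: calibration cohorts use 5 carriers vs 5 non-carriers at 2 × 60
reads (per-sample %C→T then has ~0.3 percentage-point noise on a 2% rate,
comfortably normal for the t test); verdict trials use 4 vs 4 at 2 × 80
reads with δ = 0.03, where a genuine het sits ~20σ above the artifact
regime.

## Known limitations

* The damage model is uniform along the read; no UDG treatment, no
  mapDamage-style positional curves.
* No likelihood-based genotype caller and no contamination estimation; the
  frequency windows assume roughly unbiased allele amplification
  (`allele_bias` can probe violations).
* The bundled amplicon sequences are synthetic stand-ins; analyses of real
  read data should load the true references via `load_loci`.
* `pct_ct` conflates deamination with the C→T fraction of polymerase or
  sequencing error; at ε ≪ δ this bias is negligible.
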