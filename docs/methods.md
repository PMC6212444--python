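# Methods

`eurodiff` implements a genome-wide scan for spatially varying selection
between two population samples of inbred Drosophila strains, exercised
end-to-end on a synthetic cohort whose statistical structure matches the
assumptions of the analysis. This note documents the models, the
estimators, the numerical conventions, and the choices made where the
design was genuinely open.

## The differentiation estimator

Site-level differentiation is the Weir & Cockerham (1984) estimator for
two populations of diploid individuals. For population *i* with *n_i*
called individuals, alt-allele sample frequency *p_i* and observed
heterozygote fraction *h_i* (r = 2):

```
n̄  = Σ n_i / r
n_c = (r·n̄ − Σ n_i² / (r·n̄)) / (r − 1)
p̄  = Σ n_i p_i / (r·n̄)
s²  = Σ n_i (p_i − p̄)² / ((r − 1)·n̄)
h̄  = Σ n_i h_i / (r·n̄)

a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²·(r−1)/r − h̄/4) / (n̄ − 1) ]
b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²·(r−1)/r − h̄·(2n̄−1)/(4n̄) ]
c = h̄/2
θ̂ = a / (a + b + c)
```

Sites with `a+b+c ≤ 0`, with a fully missing population, or with `n̄ ≤ 1`
(one individual per population leaves the finite-sample corrections
undefined) are flagged unusable and excluded from ranks and sums, with the
reason retained. Negative θ̂ values are kept in the empirical
distributions — they carry information about the null — and are never
truncated at zero. The *global* weighted estimate is the ratio of sums
Σa / Σ(a+b+c) over usable sites, not a mean of per-site ratios.

θ̂ = 1 exactly (to one double-precision ulp; the cancellation
p̄(1−p̄) − s²/2 is not always representable) when the populations are
fixed for different alleles, and the estimator is symmetric in the
population labels. A scalar re-derivation of the components serves as an
independent oracle in the tests; the vectorized path matches it to 1e-12.

## Synthetic cohort

The generator emulates the study design the scan targets: two samples of
individually sequenced isofemale lines (defaults 26 and 16 strains,
passively inbred, modelled as a per-site homozygosity probability of
0.95), mean coverage 28.6x, and five chromosome arms named 2L, 2R, 3L,
3R, X. Arm lengths are scaled to ~1–1.2 Mb so a full run takes seconds;
the euchromatin mask trims 50 kb from each end. For real-coordinate data
the release-5 euchromatic bounds ship as `vcfio.EUCHROMATIN_DM5`.

**Neutral sites.** Ancestral frequencies are uniform on (0.05, 0.95);
population frequencies are independent Balding–Nichols draws,
Beta(p(1−F)/F, (1−p)(1−F)/F), whose dispersion parameter F (default
baseline 0.05) is exactly the estimand of the θ̂ above — this gives the
closed-form recovery target checked by the tests (global weighted θ̂
within [0.08, 0.12] when simulating at F = 0.1).

**Selected loci.** Loci under spatially antagonistic selection are not
well described by independent high-F Balding–Nichols draws: at F = 0.6
the two populations frequently land on the same side of the ancestral
frequency and the locus is undetectable in principle (measured top-5%
sensitivity ≈ 0.56 under the sampling design). Planted selected loci are
therefore directionally divergent: a midpoint p̄ ~ U(0.4, 0.6) and a
half-difference d = sqrt(selected_F · p̄(1−p̄)) with random sign, so that
the parametric among/total variance ratio d²/(p̄q̄) equals `selected_F`.
This models the biology the scan is meant to detect — an allele favoured
in one region and disfavoured in the other — and yields planted-locus
sensitivity ≈ 1 at the default settings. Selected sites are placed inside
a small set of "selected genes" (default 2% of genes) with the remainder
of the quota (1% of sites overall) intergenic, so gene-level recovery is
well defined.

**Genotypes, depths, missingness.** Strains are homozygous with
probability `inbreeding`, else Hardy–Weinberg; DP is Poisson(mean_depth);
heterozygous calls split reads Binomial(DP, 1/2), homozygous calls put all
reads on the carried allele; calls are missing completely at random at
rate 0.03.

**Gene models.** 500 non-overlapping genes, strand random, each with a
5'UTR, 2–3 CDS exons (per-exon length divisible by 3; sequence starts ATG
with no internal stops), introns, and a 3'UTR. About 35% of genes carry a
small intron (55–65 bp), and 2% of sites are placed directly into
positions 8–30 of small introns so the neutral background category is
populated at realistic density (in real fly data small-intron SNP density
is above genome average). Repeat-mask intervals are placed in intergenic
space; indel spans avoid planted sites by ±6 bp so the indel filter does
not silently consume signal.

**Inversion.** One region (default 2L:300,000–700,000) has a homozygous
arrangement simulated per strain (frequencies 0.4 / 0.1 by default),
tagged perfectly by 10 marker SNPs; non-marker sites inside the region
get F multiplied by 1.3 (a mild, realistic elevation — the resulting
Mann–Whitney contrast is detectable but not dramatic at desk scale).

**TE table.** T-lex-style presence/absence calls, with strains treated as
homozygous carriers. Composition mirrors the field's experience: ~55%
fixed in both populations, ~34% rare in both, ~1.5% missing-heavy, the
rest common, plus 2 planted divergent TEs drawn from the same
directional model as selected SNPs.

Everything is drawn from a single `numpy.random.default_rng(seed)`
stream; a fixed seed reproduces every output file byte-for-byte.

## Filtering

The cascade runs in a fixed order: euchromatin inclusion → repeat
exclusion → indel proximity (distance ≤ 5 bp from any indel span,
configurable) → biallelic SNV only → non-singleton (pooled minor-allele
count > 1) → genotype depth QC → call rate ≥ 0.70 → pooled MAF ≥ 0.05,
each stage logged with in/out counts. Boundary conventions: DP < 10 is
removed and DP = 10 kept; DP above the per-strain 0.975 depth quantile is
removed and equality kept; MAF and call-rate thresholds keep equality.
All quantiles are nearest-rank (`sorted[ceil(q·n)]`) for exact
reproducibility. Depth thresholds are a genome-wide per-strain property:
they are computed from the input matrix before any site is removed, and
can be passed in explicitly (re-applying the cascade with the same
thresholds is then exactly idempotent; recomputing them on a filtered
matrix would shift the quantile slightly). Pooled MAF and call rate are
computed over the two focal populations combined, missing calls excluded
from numerator and denominator.

## Outlier tiers

Candidate SNPs are defined per chromosome arm from the empirical θ̂
distribution by rank: tier *t* holds exactly `floor(t·n_arm)` top sites
(ties broken by genomic position, earlier first), and the critical value
is the smallest θ̂ in the tier. Rank-based tiers, rather than
interpolated quantiles, reproduce exact printed arithmetic (e.g. 657 of
13,140) and make membership a pure function of the per-arm θ̂ multiset.
Default tails are 5% / 1% / 0.5%. By construction just under 5% of usable
sites fall in the 5% tier on null data, which the calibration test
verifies.

## Functional categories and stratified enrichment

Each SNP receives exactly one category by precedence: coding (split
synonymous / non-synonymous by codon translation against the CDS, with
mismatching reference codons kept coding but flagged unresolved) > splice
site (2 intronic bases at each intron end) > 5'/3' UTR > intron — where
positions 8–30 from the 5' end (transcribed strand) of introns ≤ 65 bp
form the near-neutral `small_intron_bg` class > core promoter (1–316 bp
upstream of the TSS, strand-aware) > promoter (317–1,000 bp) >
intergenic. Where features of several genes overlap, the
highest-precedence category wins.

Tier enrichment of each category against the small-intron background is a
stratified 2×2 analysis: within each stratum (pooled-MAF decile ×
chromosome arm × inversion status) the table (category vs background) ×
(in tier vs not) is formed, and the strata are combined with the
Cochran–Mantel–Haenszel test (common odds ratio and asymptotic p). CMH is
the standard exact-family combination for stratified 2×2 tables; the
unstratified two-sided Fisher test is reported alongside for comparison.
On null cohorts the CMH p-values are approximately uniform (KS against
U(0,1) not rejected over 50 replicates).

## Gene-level Z_ST

Each gene is scored by the maximum θ̂ over its transcribed region plus a
strand-aware 1 kb upstream window (a SNP may serve several overlapping
genes; genes without usable SNPs are excluded and logged). Max-θ̂ is
normalized within each arm by the rank-based inverse-normal transform
Z = Φ⁻¹((rank − 0.5)/n), average ranks for ties; this was chosen over
mean/sd standardization (available behind `mode="meansd"`) because max-θ̂
is strongly right-skewed while the gene score should be approximately
normal. Because the maximum of more draws is stochastically larger, Z
correlates with the SNP count; genes are therefore sorted by n_snps into
16 equal-occupancy bins (value ties kept in the earlier bin) and
median-centered: Z_ST = Z − median(Z | bin). Centering only — no
dispersion rescaling — is used; nothing in the procedure's description
requires a scale correction, and centering alone removes the planted bias
in simulation (Spearman r(n_snps, Z) ≈ 0.78 before, |r(n_snps, Z_ST)| <
0.05 after, on a 2,000-gene cohort with SNP counts log-uniform on
1–100). Candidates are the top `floor(0.05·N)` genes by Z_ST genome-wide
(ties at the cut broken by gene id), matching the 657/13,140 arithmetic.

## GO enrichment

Annotations follow the true-path rule over the `is_a` graph of the
biological-process namespace (propagation is idempotent; cyclic
ontologies are rejected). Three tests:

* **classic Fisher** — one-sided hypergeometric over-representation of
  candidates per term; only terms with ≥ 5 candidate genes are reported.
* **KS score test** — one-sided two-sample Kolmogorov–Smirnov comparing a
  term's Z_ST scores with all remaining scored genes, alternative "term
  scores stochastically larger" (high Z_ST = differentiated); minimum 5
  annotated scored genes, since the 5-candidate rule is specific to the
  Fisher test.
* **elim** — terms are processed children-before-parents (lexicographic
  topological order, so iteration within a level is fixed by term id);
  each term is tested on its current gene set, and when p < cutoff
  (default 0.01, the conventional choice for this algorithm) its
  *originally* annotated genes are removed from every ancestor's current
  set before those are tested. Result filtering uses original counts, so
  deflated ancestors remain visible. Raw elim p-values are treated as
  corrected; no further multiple-testing adjustment is applied.

The `weight`/`weight01` variants are out of scope.

## Diversity

Per-site π is the unbiased mean pairwise difference c_ref·c_alt / C(n,2)
over called chromosomes (sites with n < 2 skipped). Windows hold a fixed
number of SNPs (default 10,000 at genome scale; 2,000 in the analysis
scripts at synthetic scale) and report both per-bp (π summed / genomic
span) and per-SNP means, since either denominator is defensible.
Pseudo-haploid sampling keeps one allele per strain per site — drawn from
the genotype's alleles with probability AD/DP for heterozygotes, the
carried allele for homozygotes, uniform when a het has no informative
reads — acknowledging that an isofemale strain genome may effectively
carry more or fewer than two alleles per locus. With fully inbred data
the haploid and diploid estimators agree deterministically up to the
exact denominator ratio (2N−1)/(2N−2); they are not numerically equal at
finite N and the tests assert the exact relationship instead.

## TE differentiation

Presence/absence calls are treated as a biallelic locus with homozygous
genotypes (consistent with inbred lines): present = 1/1, absent = 0/0,
missing dropped. Classification precedes testing: `undetermined` when
either population's missing fraction exceeds 0.30 (the source caller's
"could not determine frequency" has no published numeric rule, so a
missingness rule is used and is configurable); else `fixed_both` when the
presence frequency among called strains is exactly 1 in both populations;
else `low_freq_both` below 5% in both; else `testable`. Testable TEs get
θ̂ from the same code path as SNPs (exact equality is tested) and are
candidates at tier *t* iff θ̂ ≥ that arm's tier-*t* SNP critical value,
calibrating the TE test on the genome-wide SNP distribution; the
population with the higher insertion frequency is reported as the
direction.

## Inversion statistics

The inversion contrast compares θ̂ inside the region with the rest of the
arm: medians plus a two-sided Mann–Whitney U (exact for small tie-free
samples, normal approximation with tie correction otherwise — scipy's
`method="auto"`), and per-tier inside/outside 2×2 tables for exact tests.
Inversion frequency is estimated from a marker panel as the mean, across
genotyped markers, of the tagging-allele frequency per population; with
markers in perfect association this equals the realized sample
arrangement frequency.

## Problem sizes and what passing does not show

Default scales — 20,000 SNPs on five ~1 Mb arms, 42 strains, 500 genes,
100 TEs — were chosen so the full pipeline runs in seconds and the
50-replicate calibration suite in about a minute, while every estimator
operates far from its small-sample edge cases. The generator draws sites
independently: there is no linkage disequilibrium, no demographic history
beyond the one-parameter divergence, no admixture, no sequencing error in
the allele labels, and gene structures are simplified. Passing tests
therefore demonstrate correctness of the estimators, filters and rank
logic and internal calibration of the tests — not robustness to LD,
admixture or calling artefacts in real cohorts. Quantities that depend on
the real data's scale (genome-wide π levels, absolute filtered SNP
counts, the exact inversion contrast p) are reported by the pipeline but
have no synthetic target.
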