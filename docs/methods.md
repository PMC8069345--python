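# Methods

## The emission model and the 5mC caller

Nanopore current levels depend on the ~6 bases in the pore, so methylation
detection is framed as model comparison between two Gaussian emission models
per 6-mer: the unmethylated variant (CpG written `CG`) and the methylated
variant (`MG`, with M = 5mC). The model covers all 4096 canonical 6-mers;
every CpG-containing 6-mer has both variants, and 6-mers that would mix a
methylated with an unmethylated CpG cytosine are excluded — methylation is
all-or-nothing within one 6-mer. The synthetic model draws per-6-mer mean
currents from N(100, 10²) pA with a common spread of σ = 2 pA, and shifts
the methylated variant by ±4 pA (2σ, random sign per 6-mer). The 2σ
separation per informative event is the design point of the calibration
study: it makes single events weak evidence and multi-event sites strong
evidence, which is the regime the three-way caller is built for.

For one CpG site on one read, the log-likelihood ratio (natural log) sums
over the overlapping 6-mer events, treated as independent:

LLR = Σ_e [ log N(x_e; μ_M, σ_M) − log N(x_e; μ_C, σ_C) ].

Each simulated site carries 11 events (the 6-mers tiling a 16-bp context
with the CpG placed so that 6 of the 11 contain it); non-CpG 6-mers have
identical variants and contribute exactly zero. Under the default model the
expected LLR of a truly methylated site is Σ (Δμ)²/(2σ²) = 6·2 = 12, with
standard deviation √24 ≈ 4.9, so at the calling threshold of 2.5 the
per-read error rate on confident calls is ≈ 0.15% and the ambiguous rate a
few percent.

Calls are methylated when LLR ≥ +2.5, unmethylated when LLR ≤ −2.5,
otherwise ambiguous. The threshold is inclusive on both sides (read as the
minimum acceptable confidence) and is applied per read per site; ambiguous
calls are excluded from both the numerator and the denominator of per-site
frequencies, so "coverage" downstream means confident calls. A site whose
reads are all ambiguous is reported with coverage 0 rather than dropped, so
promoter coverage accounting stays explicit. Bisulfite count tables become
frequencies only at sites with ≥ 5 reads; sites below that are not called
at all.

## The synthetic landscape and what it does (not) emulate

The toy genome has one or more chromosomes, promoters placed non-overlapping
(one per gene, TSS jittered inside equal segments, strand random), and CpG
sites at a background density with a 10× enrichment inside promoter windows
to mimic CpG islands (adjacent positions are thinned because a CpG occupies
two bases). Promoters receive one of three true classes — hyper5mC, hypo,
hyper5hmC — with exact largest-remainder counts from the configured
fractions, default (0.25, 0.55, 0.20): most promoters unmethylated, a
quarter 5mC-silenced, a fifth hydroxymethylated, a deliberately 5hmC-rich
mix so the discrimination logic is exercised hard. Within-promoter site
states are Bernoulli: P(5mC) = p_in = 0.9 in hyper5mC promoters, p_out =
0.05 in hypo promoters, P(5hmC) = p_in in hyper5hmC promoters. Sites outside
promoters are 5mC with probability 0.8, the typical methylated genomic
baseline, which is what produces the TSS dip over hypomethylated promoters.

The two read-outs are deliberately asymmetric:

* nanopore events for 5mC sites come from the M-variant Gaussians;
  unmethylated **and 5hmC** sites emit from the C-variant Gaussians. No
  published current characterisation of 5hmC is assumed; emitting 5hmC as
  unmethylated-like reproduces the observable that matters — the 5mC caller
  finds no or low 5mC at hydroxymethylated promoters — without inventing a
  third distribution.
* bisulfite methylated counts are Binomial(total, 1 − err) for **both** 5mC
  and 5hmC sites and Binomial(total, err) for unmethylated sites
  (err = conversion error, default 0.005): bisulfite cannot distinguish the
  two marks. EPIC is the same read-out restricted to a random 30% of sites
  (targeted capture) at higher depth.

Read depth is Poisson per site (nanopore 15×, WGBS 30×, EPIC 60× by
default); reads are independent between sites, not contiguous molecules.
Not emulated: raw squiggle/FAST5 signal, event segmentation, basecalling or
alignment error, bisulfite conversion chemistry beyond a flat error rate,
PCR duplicates, copy-number or allele-specific effects, CpG-island
annotation. Passing tests therefore demonstrate the *logic* of the
integration and filtering cascade under a faithful noise model of counts
and currents — not robustness to the artefacts of real sequencing runs.

Expression tables: per-gene baselines are log-normal around 50 TPM-like
units; planted candidate genes are divided by 4 at 4 h post-hepatectomy
(returning to sham level at one week) and by 4 in tumor samples; all values
carry mean-one log-normal noise with CV 0.2. The planted fold of 4 against
a filter threshold of 2 places true candidates several noise SDs above the
cut, which is the regime the recovery study quantifies; the cohort defaults
to 371 tumors vs 50 normals, mirroring a typical public HCC cohort. Mouse
regeneration symbols are emitted capitalised and upper-cased on entry to
the cascade (symbol-level matching only; orthology resolution is out of
scope).

## Promoter classification and integration

Promoter windows are −1000/+500 bp around the TSS (the annotation source
does not pin a window; this is configurable), half-open in strand-oriented
offset: a site at offset d belongs iff −1000 ≤ d < 500, mirrored on the
minus strand. Sites with frequency strictly > 0.5 are hypermethylated
("more than 50%"). Each promoter becomes a 20-bin vector of per-bin
hypermethylated-site fractions; empty bins are imputed with the
promoter-wide fraction so the vector stays defined, and promoters with
fewer than 3 covered sites are unclassifiable (1–2 sites cannot support a
profile). Binned fractions rather than raw frequencies are clustered
because the object of interest is where hypermethylated sites concentrate,
not absolute methylation. k-means uses k = 2, Euclidean distance,
k-means++ seeding, best of 10 restarts, fixed seed (scikit-learn); the
cluster with the larger centroid mean is "hyper". If every profile is
identical the classification degenerates to a mean-vs-0.5 rule with a
warning. Gene collapse is OR-logic over promoters, and both promoter-level
and gene-level counts are reported.

Integration is exact set algebra with the overlap percentage denominated on
the nanopore set. The putative-5hmC rule quantifies "no or low 5mC" as mean
promoter frequency ≤ 0.1 and "covered" as ≥ 5 nanopore reads, both
configurable; a gene's depth and frequency are taken from its maximally
covered promoter, and genes failing the depth test are labelled
insufficient-coverage rather than not-5hmC.

## The filter cascade

Fold changes carry a pseudocount of 0.1 to guard zero denominators
(continuity in the pseudocount is tested). Recovery — unquantified in
prose descriptions of such designs — is defined as one-week expression
within twofold of sham. The tumor stage uses medians (robust on skewed
cohorts) and a two-sided Mann–Whitney test with normal approximation and
tie correction; a gene constant across all samples gets p = 1 by
convention. The pass rule uses the raw p-value at α = 1e-4 to match the
star-threshold style of cohort comparisons, with Benjamini–Hochberg
q-values reported alongside and available as the pass criterion by config.
The known-TSG exclusion list defaults to {AJAP1, GATA5, LRAT}. Stage
counts are reported in pipeline order and are non-increasing by
construction.

## Numerical and reproducibility choices

* All randomness flows from one pipeline seed through
  `numpy.random.SeedSequence([seed, stage])` children, so stages are
  individually reproducible and CLI reruns are byte-identical (gzip mtime
  pinned to zero).
* The model enforces σ > 0; the σ → 0 limit is exercised with σ = 1e-12,
  where simulated currents equal the mean to float precision because draws
  are μ + σ·z.
* Largest-remainder rounding (ties by position) makes promoter class counts
  exact, so count assertions need no tolerance.
* Spearman uses average ranks on ties; at least 3 shared sites are required
  or the correlation is refused rather than returned as noise.
* Default problem size (one 300 kb chromosome, 40 genes, ~4000 CpGs) runs
  the full pipeline in about a second; the 20-replicate recovery study and
  the acceptance script use this size and finish in well under a minute.
  The reduced tumor cohort in multi-replicate tests (40–60 vs 15–20
  samples) keeps the rank test far into its asymptotic regime while staying
  fast.

## Known limitations

* The 5hmC emission stand-in means the caller's behaviour on real 5hmC
  signal (which perturbs current differently from both C and 5mC) is not
  evaluated.
* Single-sample design: no differential methylation between samples, no
  replicate-level variance model for the regeneration time course (one
  value per condition, matching per-condition means).
* The cross-platform Spearman on synthetic data (~0.7) reflects the chosen
  coverages and noise, and is a property check, not a calibration target.
* Gene symbols are the only join key across species and platforms;
  real-data use would need orthology and promoter-annotation reconciliation.
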