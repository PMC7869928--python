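# Methods

This document describes the statistical model behind each stage, the default
parameters and why they were chosen, and the package's known limitations.

## Somatic call filtering (`clonkit.filters`)

A call is retained only if it passes every rule; attrition is attributed to
the *first* failing rule in a fixed order so the report's counts sum exactly
to the input size:

1. `target` — position inside the target regions (BED, 0-based half-open),
   when a BED is given.
2. `zero_tumor_depth` — tumor depth must be positive (VAF undefined
   otherwise).
3. `normal_depth` — matched-normal depth ≥ 20 (default), enough reads to
   trust the absence of the variant in the normal.
4. `vaf_ratio` — tumor VAF ≥ 5× normal VAF (default). The rule is the
   literal inequality `t_vaf < ratio * n_vaf`, so equality is retained and a
   normal VAF of 0 can never fail (any tumor support is then infinitely
   enriched).
5. `pop_maf` — population minor-allele frequency ≤ 5% (default); equality
   retained; missing MAF treated as "not known common" and retained.

Defaults follow standard tumor/normal WES practice: normal depth 20 gives
<1% chance of missing a heterozygous germline variant; the 5× ratio and 5%
MAF thresholds separate somatic calls from germline leakage and common
polymorphisms.

## CCF estimation and clonal classification (`clonkit.ccf`)

For a mutation with multiplicity m in a region of tumor copy number
`cn_t` (normal `cn_n` = 2), in a sample of purity ρ, the expected VAF of a
mutation present in a fraction `ccf` of tumor cells is

    f(ccf) = ρ · m · ccf / (ρ · cn_t + (1 − ρ) · cn_n),   clamped to [0, 1].

The alt read count is modeled Binomial(depth, f(ccf)). A flat prior over the
grid {0.01, 0.02, …, 1.00} (step 0.01 by default — resolution well below the
binomial noise at practical depths) gives the posterior by direct
normalization of the likelihood.

- **Multiplicity** is chosen from {1, …, major copy number} by likelihood at
  the moment estimate of CCF; ties go to the smaller m (the conservative
  choice — a lower multiplicity implies a higher CCF is *not* assumed).
- **Point estimate** is the posterior mode.
- **95% credible interval** uses the midpoint (Hazen) percentile convention
  on the discrete grid, `cdf_mid = cumsum(post) − 0.5·post`. Plain
  equal-tailed discrete percentiles undercover at the CCF = 1 boundary
  (the upper bound can only reach 1.0 when the single top grid point holds
  >2.5% mass); the midpoint convention is a standard discrete-percentile
  definition that restores near-nominal coverage there. Measured pooled
  coverage at depth 100, purity 0.5 is ≈ 0.93 (see
  `scripts/acceptance.py`).
- **Clonal classification**: clonal iff `p_clonal > 0.5` **or**
  `ci_low > 0.9`, where `p_clonal` is the posterior mass at CCF ≥ 0.9. The
  two rules are kept as independent code paths; with these definitions the
  interval rule is in practice a numerically stricter subset of the
  probability rule, but both are evaluated.
- A total copy number of 0 makes the CCF unestimable and is flagged rather
  than guessed.

## Clonality index (`clonkit.clonality`)

For two lesions sharing mutation set S with per-mutation population
frequencies pₘ, each shared mutation contributes the probability pₘ² that
two independent lesions both acquire it (binomial, n = 2, k = 2). The index
is

    CI = −log₁₀ ∏ₘ pₘ² = −2 · Σₘ log₁₀ pₘ.

Frequencies are looked up by exact variant, then by (gene, protein change),
then floored at 1e-6 (a mutation never seen in a reference cohort is still
possible) and capped at 0.5 (no single variant is "more likely than not").

**Null calibration.** Because CI grows with the number of shared mutations
regardless of their rarity, relatedness is declared only when the observed
CI exceeds the (1 − α) quantile (α = 0.05 default) of a permutation null
that redraws each lesion's observed mutation count from the frequency
catalog, weighted by pₘ, without replacement (vectorized via the
exponential-race trick). α ≥ 1 is treated as "never related" (a
significance level of 1 rejects nothing). Default `n_perm` = 10,000 gives
the 95th percentile ~500 tail points.

The catalog must represent the *opportunity space* of possible somatic
variants, not just the observed ones: if the null can only re-draw the
observed mutations, chance overlap is artificially common and the test loses
its power. When no frequency table is supplied, the pipeline therefore pads
the observed mutations with 20,000 rare (p = 1e-4) synthetic background
entries — roughly one rare-variant slot per gene of an exome — so expected
chance overlap of rare variants between two lesions with m₁ and m₂
mutations is m₁·m₂/N ≪ 1.

## Phylogeny (`clonkit.phylogeny`)

Input is the binary mutation-presence matrix over samples (optionally
thresholded on CCF). If the presence patterns are laminar (pairwise nested
or disjoint) the perfect phylogeny is unique and built directly, each
pattern's mutations assigned to the edge above its clade. Otherwise all
rooted binary topologies (double factorial (2n−3)!!, practical for the ≤ 8
samples enforced) are scored by small-parsimony dynamic programming with the
germline root fixed at state 0 and losses costing 1; ties break
lexicographically on the Newick string for determinism. Branch lengths are
mutation counts; a mutation lands on the edge above the most recent common
ancestor of its carriers.

## Mutational signatures (`clonkit.signatures`)

Spectra use the conventional 96 channels (6 pyrimidine substitutions × 16
flanking contexts, alphabetical); purine-annotated calls are
reverse-complemented. Exposures are fitted by non-negative least squares on
the normalized spectrum, then signatures below a 5% exposure floor are
dropped and the remainder refitted (sparsity refit) — small exposures at
these catalog sizes are mostly noise. Fits from fewer than 5 mutations are
flagged low-confidence.

The shipped catalog is **SYNTHETIC**: a stylized 5-signature
(SBS1/SBS2/SBS5/SBS13/SBS18) matrix constructed programmatically from the
qualitative channel structure of those signatures (e.g. SBS1 concentrates
C>T at NpCpG; SBS2/13 at TpCpN), because published reference matrices are
not redistributable here. It is column-stochastic and its columns are
mutually discriminable (pairwise correlation < 0.9), which is what the
fitting tests require; exposures fitted against it are not comparable to
exposures against published catalogs.

## Arm-level copy number (`clonkit.cna`)

Per arm, segments are intersected with the arm interval and the mean log2
ratio is weighted by intersection length (half-open arithmetic). Arms with
less than 50% covered length are reported neutral and flagged rather than
called from sparse evidence. Gain ≥ +0.2, loss ≤ −0.2 (common single-copy
thresholds at moderate purity). Fraction of genome altered is the
length-share of segments beyond either threshold. A convenience check
reports concurrent 1q gain and 16q loss.

## Synthetic data (`clonkit.simulate`)

The simulator places mutations on a toy genome (22 chromosomes × 10 Mb,
arms split at 5 Mb) so cross-case coordinate collisions are quantifiable.
A case has a clonal trunk (carrying a hotspot driver), subset branches, and
private mutations (true CCF ~ Uniform(0.2, 1)); depths are Poisson, alt
reads Binomial at the expected VAF; trinucleotide contexts are drawn from
per-lesion signature mixtures; copy-number events are per-arm log2 shifts.
Every generated quantity is recorded in `SimTruth`. Presets: `jup3_like`
(benign + two carcinoma lesions, 3-mutation trunk, 29-mutation carcinoma
branch, APOBEC-dominant carcinoma mixtures, carcinoma-only 1q+/16q−) and
`null_pair` (two unrelated cases).

The packaged `load_jup3_fixture()` case is deterministic: mutation
identities and the sharing structure follow a published JP/DCIS/IDC case
narrative, while read counts, depths, contexts and CCFs are SYNTHETIC.
Fixture alt counts are the *expected* count at the stated CCF (noise-free by
design — the fixture encodes its intended truth exactly; read-count noise is
the simulator's job). Unnamed branch/private mutations carry synthetic
placeholder gene symbols (`SYNBR*`, `SYNPR*`).

## Pipeline (`clonkit.pipeline`, `clonkit.cli`)

Stages run in order filter → CCF → clonality → tree → signatures → CNA; all
randomness flows from the single config seed, and identical config + inputs
produce byte-identical outputs. Optional stages are skipped with a warning
when their inputs are absent; failures raise a `StageError` naming the
stage. Outputs: per-stage TSVs, the Newick tree, and a markdown summary.

## Limitations

- CCF assumes a single clean segment per mutation and integer multiplicity;
  no subclonal copy number, no kataegis/clustering model.
- The clonality-index null treats mutations as independent draws from the
  catalog; hotspot recurrence is modeled only through its larger pₘ.
- Parsimony search is exhaustive and limited to 8 samples.
- The signature catalog is synthetic and 5 signatures wide; exposures are
  qualitative, not comparable to fits against published catalogs.
- The simulator is not a read-level simulator (no FASTQ/BAM, no mapping or
  sequencing-error model).
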