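# Methods

This note documents the models, defaults, and numerical choices behind
`secretomapper`, and what the synthetic-data tests do and do not establish
about real data.

## Data model

The central container (`IntensityTable`) is a protein × sample matrix of
LFQ intensities with NaN as the explicit missing state, bound to a design
(cell type × replicate). Two facts are tracked independently:

* the numeric **value** (which imputation may fill), and
* the **detection state** (whether the protein was quantified in that run
  at all), frozen at ingestion.

All replicate-presence logic — the 5-of-6 filter, the specificity rules,
fluid mapping — reads the detection mask, never the imputed matrix. This
separation is the single most consequential design choice: it makes
detection counts provably invariant under imputation (asserted by tests).

Zeros and empty cells on the raw scale mean "not quantified" (the MaxQuant
convention) and become missing at ingestion; nothing is imputed silently.
A protein group is keyed by its first accession; the full group string is
kept as metadata. Isoform suffixes (`-2`) are stripped only where datasets
are joined (network building).

## Preprocessing

**Replicate filter.** Keep a protein if some group (or a named group) has
≥ `min_detected` detections; defaults 5 of 6 for secretome tables, 2 for
lysate reanalysis, 3 of 4 for CSF — all held in one `ParameterSet`. The
filter runs after decoy/contaminant removal.

**Imputation.** Log2 scale only. Per sample column with observed mean *m*
and SD *s* (ddof = 1), missing entries are drawn independently from
𝒩(*m* − shift·*s*, (width·*s*)²), shift = 1.8, width = 0.3. Column-wise
moments (rather than one global pair) follow the Perseus convention for
this procedure. One PCG64 generator seeded once fills columns left to
right, so outputs are reproducible across platforms; the generator name is
part of the contract. A column with < 2 present values is a hard error
directing the user to a stricter filter (its moments would be undefined or
degenerate).

The shift/width defaults place imputed values where left-censored values
plausibly were. They are statistical conventions, not estimates; the
synthetic generator's logistic-censoring model gives a smooth target
against which the imputation's location and scale are verified
(acceptance checks accept the imputed sample only if a z-test on the mean
and a χ² test on the variance both pass at the 1% level with 10,000
draws).

## Differential abundance

**Moderated t.** Per protein, the two-group contrast is an OLS difference
of means with pooled residual variance s²_g on d = n_A + n_B − 2 df. The
empirical-Bayes prior (d₀, s₀²) is fitted by moment-matching on
z = log s²_g: with e = z − ψ(d/2) + log(d/2), solve
ψ′(d₀/2) = var(e) − ψ′(d/2) by Newton inversion of the trigamma function,
then s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). Posterior variance
s²_post = (d₀ s₀² + d s²_g)/(d₀ + d); moderated t on d + d₀ df. Two edge
cases follow the reference behaviour of limma (against which the
implementation is frozen-fixture-verified to ~1e-13): when the spread of
log-variances is no wider than χ² sampling alone explains, the prior df is
infinite and the prior variance is the arithmetic mean of the s²_g; and the
total df is capped at the dataset's pooled residual df. With < 10 proteins
the prior cannot be estimated stably, so shrinkage is disabled (classical
t), and `prior_df` can be forced for diagnostics.

Significance requires both Bonferroni-corrected p < α (default 0.05) and
|log2 FC| ≥ 2; the fold floor exists because imputed values can manufacture
small but precise fold changes.

**s0 / permutation FDR.** The modified statistic adds s₀ (default 0.1) to
the pooled standard error, damping significance of near-zero fold changes.
Group labels are permuted (default 250 draws; exhaustive enumeration with a
warning when fewer than 20 distinct assignments exist). For each candidate
cutoff (the observed |t| values, descending) the FDR estimate is the mean
permuted exceedance count divided by the observed count, with π₀ fixed at 1
(conservative) and enforced monotone by a step-down pass; the smallest
cutoff with estimated FDR ≤ α is chosen, maximising calls. The volcano
boundary follows from the cutoff *c*: a point with fold change *x* sits on
the curve where its classical t equals x/(x/c − s₀), defined for |x| > c·s₀.
The per-protein p-value reported is the pooled permutation p. Reference
software for this statistic does not publish its exact permutation scheme;
ours is documented here and the acceptance checks assert calibration (null
significant fraction ≤ α), not bit-identity to any tool.

**Plain t.** Pooled-variance classical t (the SAM lineage assumption),
two-sided. Proteins quantified in only one condition get no p-value; they
are reported in a separate exclusive list.

## Specificity calling

The two-rule criterion (detection ≥ 5/6 in the candidate group, plus
exclusive detection ≤ 2 elsewhere or ≥ five-fold enrichment over every
other group) is applied on detection counts and imputed log2 group means.
Decisions taken where the criterion's wording left room:

* "in another cell type" (rule i) is enforced as **every** other cell type;
* rule ii's fold margin is a difference of imputed log2 means, not a ratio
  of raw means — the workflow imputes before comparing;
* rule ii requires the ≥ 5/6 detection in the candidate group only, with no
  cap on detection elsewhere (fold dominance already penalises abundant
  competitors);
* under rule ii only one group can win (strict dominance with fold > 1);
  if a permissive parameterisation lets two groups satisfy rule i, the call
  is withheld and logged.

"Uniquely detected" (≥ 5/6 in exactly one group, sub-threshold detection
elsewhere unconstrained) is computed and reported separately; it is a
detection-overlap statistic, not a specificity call, and the two disagree
by design on proteins detected 6/6 in one group and 3–4/6 in another.

Lysate expression specificity uses the fold rule alone at 2.5-fold after a
≥ 2-replicate inclusion filter. Comparing secretome and lysate calls
splits cell-type-specific secretion into expression-driven versus
secretion-specific, with lysate-uncovered proteins in a third bucket.

## Topology, shedding, cleavage

Peptide region calls use 1-based inclusive coordinates throughout (the
UniProt convention). A peptide of a single-pass TM protein is ectodomain
only if its interval is entirely covered by extracellular segments;
any overlap with the TM segment classifies it TM-spanning (conservative:
keeps the ectodomain fraction strict); type-II orientation (intracellular
N-terminus) is honoured by reading segment kinds, not segment order.
Multi-pass membrane proteins are excluded (no single-pass topology).

The trypsin rule is cut-after-K/R with the proline exception **off** by
default (matching lenient search configurations); `cut_before_proline=False`
restores the classical rule. A semi-tryptic peptide nominates its
non-tryptic boundary: residue `start − 1` for an N-terminal non-specificity,
residue `end` for a C-terminal one. Flanking residues are validated against
the supplied sequence; a mismatch is a hard error, since it signals a
coordinate off-by-one upstream.

## Fluid origin mapping

Ranking abundance is the mean of **present** log10 intensities — imputation
never enters the ranking. Quartile bins differ in size by at most one, with
earlier (more abundant) bins taking the remainder; ties break by accession,
making the binning deterministic. Per-quartile composition counts a protein
toward every cell type whose secretome holds it at ≥ 5/6 replicates, so
bars may sum above 100% by construction. The disease join defaults to
evidence index ≥ 0.9, configurable (a stricter 0.95 is the other natural
operating point).

## Synthetic data: what it emulates, what it does not

Per protein i, group g, replicate r:
latent log2 intensity = base_i + effect·1[g = cts_i] + 𝒩(0, σ²_rep);
observed with probability logistic((latent − censor_mid)·censor_slope);
recorded as 2^latent. Defaults: 4 groups × 6 replicates, base ~ 𝒩(25, 2²),
30% planted specific proteins at eight-fold (log2 = 3) enrichment,
σ_rep = 0.5, censor_mid = 22, slope = 1.5. The logistic (soft) censoring is
chosen over hard truncation so imputation-bias checks have a smooth target;
a hard mode exists. Annotation structure: 45% soluble secreted / 40%
single-pass TM / 5% GPI / 10% other, random sequences of 200–800 residues,
21-residue TM segments with random orientation. Digests are fully tryptic
(≤ 2 missed cleavages, length 6–30) restricted to ectodomains with a
configurable intracellular leakage rate (default 0.001); planted endogenous
cuts inject semi-tryptic boundaries at positions validated to release
length-legal peptides (`pick_cleavage_site`). The fluid table mixes the
cell-type mean profiles (log-sum of weighted linear intensities), keeps
65% overlap with the resource by default, and applies the same censoring.

The generator reproduces the *statistical* structure the pipeline assumes —
log-normal abundance, MNAR left-censoring, planted effects, annotation/
topology consistency — but not: correlated peptide-level quantification,
shared-peptide protein-group ambiguity, batch effects, normalisation
artefacts, biological co-regulation between proteins, or realistic amino-
acid composition. Passing recovery tests therefore demonstrates that the
implementation is correct and calibrated under its stated model, not that
the thresholds are optimal for any particular real dataset.

## Problem sizes and determinism

Test and acceptance runs use desk-scale instances (100–2,000 proteins,
20–100 seeds per property), sizes at which every property checked is
already stable; the oracle-equality checks are exact, not statistical.
All stochastic stages take explicit integer seeds (PCG64); a pipeline rerun
with the same config and seed is byte-identical, which the test suite
asserts on the full simulation bundle and the pipeline summary.

## Known limitations

* Pairwise contrasts only; no multi-factor designs or covariates.
* No between-sample normalisation or batch correction (the workflow assumes
  LFQ normalisation upstream).
* Membership-based fluid mapping only — no proportional deconvolution.
* No topology prediction; topology must be supplied.
* The supplementary-reproduction entry point maps columns by header
  inspection and will skip tables whose headers carry no recognisable
  cell-type tokens.
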