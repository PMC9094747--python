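# Methods

This note records the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerically delicate choices.

## Cross-tissue correlation model

All correlation stages operate on log2(CPM + 1), computed per tissue. The
expression unit is a declared default, not a claim of optimality: a
monotone, variance-stabilizing transform is required before a
median/MAD-based correlation, and counts-per-million is the conventional
choice when library sizes differ.

The biweight midcorrelation uses the raw (unscaled) median absolute
deviation in the 9·MAD weighting window — the window is defined on the raw
MAD, so no 1.4826 normal-consistency factor is applied. Observations at or
beyond 9 MAD from the median get exactly zero weight, which bounds the
influence of any single sample. Two deliberate simplifications: no
winsorization cap on outlier fractions (no setting for it is defined
here), and no permutation p-values (the Student transform
t = r√(n−2)/√(1−r²) is used throughout). When a vector's MAD is zero but
the vector is not constant, that vector falls back to mean-centering with
unit weights (a Pearson-style fit) and the event is flagged; fully
constant vectors yield missing values. Missing data are handled
pairwise-complete with the per-pair n entering the p-value.

Significance of survey edges is decided per (target tissue, sex stratum)
in one of three modes:

* **2SD rule** — mean μ and SD σ of the *signed* coefficient distribution;
  an edge is significant when |r| > μ + 2σ. The signed distribution was
  chosen (over the distribution of |r|) because the surveys plot signed
  coefficient distributions; both μ and σ are reported. Under a
  well-behaved null this rule yields ~4.6% of edges per stratum by
  construction — it is a relative outlier call, not an error-rate
  guarantee.
* **Fixed p** — Student p < 0.01 for broad surveys; p < 1e-6 in the
  stringent mode reserved for direct-interaction claims. Note that the
  shorthand "p = 0.01 corresponds to |bicor| > 0.1" is only approximately
  true even at n ≈ 310 (the exact p at r = 0.1, n = 310 is ≈ 0.079); the
  implementation always follows the Student formula.
* **BH** — an optional FDR-adjusted mode for users who want a calibrated
  error rate instead of the survey conventions above.

μ, σ are computed per sex stratum (matching the per-sex distributions the
survey produces), not pooled. Edge classes: male_only / female_only /
shared (significant in both sexes with matching sign) / none; a
double-significant pair with opposite signs is classed none and flagged
discordant, since no convention defines it.

Receptor binning correlates each myokine with ESR1 and AR within muscle,
per sex stratum, at p < 0.01 (the threshold printed for the receptor
heatmaps; the bin is `both` iff both receptors pass). With two independent
tests the expected false-bin rate for a null myokine is ≈ 2 × 0.01.

## Sex differential expression

The test is the Wald test of a two-group negative-binomial GLM with log
link, the model a count-based DE tool fits for a plain sex contrast:

* size factors by median-of-ratios against a geometric-mean
  pseudo-reference restricted to genes nonzero in every sample;
* per-gene dispersion by method of moments on normalized counts, residual
  variance pooled within groups, floored at 1e-8 — no empirical-Bayes
  shrinkage. The floor only matters for near-Poisson genes;
* per-group log-means by Newton scoring of the NB score equation with size
  factors as offsets (steps clipped to ±5, β clipped to [ln 1e-8, ln 1e12]
  so all-zero groups degrade to a near-zero mean with huge variance rather
  than diverging);
* Wald z on β_male − β_female against the normal reference; log2FC is
  male-positive; BH across tested genes. Genes with zero variance across
  samples (including all-zero genes) are reported with missing p and
  excluded from BH.

Simulated calibration at the study scale (2000 null NB genes, 60/60): the
p < 0.05 rate lands at ~0.05 inside the 99% binomial interval, and planted
4-fold changes are recovered at padj < 0.05 with sensitivity ~1.0. The
known limitation of median-of-ratios applies: if differential genes are
heavily imbalanced in direction, size factors absorb part of the shift and
null genes inherit a small systematic fold-change. The generator plants
balanced male-up/female-up sets, and results on strongly asymmetric real
contrasts should be read with that caveat.

Sex-specificity binning uses raw p < 0.05 by default — the deliberately
least-stringent convention, which errs toward placing genes in sex-specific
categories — with `use_adjusted=True` available; recovery tests against
planted truth use the adjusted mode because at raw p = 0.05 the expected
false-positive load alone (~5% of null genes) exceeds the tolerance being
tested.

## Synthetic cohort

The generator is the package's test bed and defines the study conditions.
Defaults: 100 male / 50 female individuals (the paper-scale 210/100 shape,
scaled down for desk-size runs; the unequal ratio is preserved because the
female stratum's smaller n drives detection power), muscle plus three
target tissues, 2000 genes per tissue, 200 myokines, NB dispersion 0.05
and latent log-scale SD 1.2 (typical magnitudes for well-expressed genes
in deep bulk RNA-seq), planted-gene base mean 500 counts.

Structure is planted in a Gaussian latent layer and then observed through
counts:

* **Edges**: each edge-source myokine carries a per-individual factor; the
  myokine loads on it with u = √|ρ'| and the target gene with v = ρ'/u, so
  the latent correlation is exactly ρ'. Sex-specific edges apply v only in
  the active stratum (the inactive stratum keeps an independent unit
  noise, so variances match across sexes); `null`-class edges keep ρ' = 0
  and serve as labeled negatives.
* **Observation layer**: log-mean = base + s·z (+ ln2·lfc for DE myokines
  in the favored sex), counts ~ NB(exp(log-mean), α). On the log scale the
  count noise adds variance ≈ α + 1/μ, attenuating any latent correlation
  by s/√(s² + α + 1/μ) per variable. Planted loadings are inflated by
  exactly this delta-method factor so the *observed* log-expression
  correlation matches the configured strength; the correction is analytic
  (≈ 3.5% at the defaults) and capped so loadings stay inside (−0.98, 0.98).
  With very few genes per tissue the CPM denominator itself becomes noisy
  and adds attenuation the correction does not model — fidelity tests use
  enough genes (≥ ~400) for library totals to stabilize.
* **Receptors**: ESR1 and AR ride independent latents; receptor-driven
  myokines load at 0.6 (single receptor) or 0.55 each (both), again
  attenuation-compensated. The 60/20/20 ESR1/AR/both split mirrors the
  ESR1-dominant pattern such surveys report.
* **Composition**: per-individual proportions from a Dirichlet with uneven
  concentrations (fiber types dominant); muscle marker genes get NB counts
  with mean = signature × proportions, where the signature is the same
  high/low profile the single-cell reference plants (markers 10-fold
  enriched in their own type).
* **Mediation triplets**: the mediator myokine loads on the standardized
  exposure proportion with a = 0.85; full-mediation targets load on the
  mediator's *latent* (b = 0.85), so conditioning on the observed mediator
  removes the exposure association up to count noise; independent targets
  load directly on the exposure with matched marginal strength a·b.

Myokine roles (edge source, DE, receptor-driven, mediator) are disjoint in
the default configuration so truth classes are unambiguous. All draws flow
from one `numpy` Generator in a fixed order; identical seeds give
byte-identical cohorts.

Deliberately not emulated: library-size artifacts, batch effects, genotype
(eQTL) structure, gene–gene coexpression beyond the planted factors, and
any post-transcriptional layer. Passing tests therefore demonstrate that
the estimators recover the planted statistical structure through a
realistic count observation model — not that real cohorts satisfy these
generative assumptions. In particular the NB layer is a stand-in for the
unknown noise model of real population expression data, declared rather
than claimed equivalent.

## Deconvolution

Signatures: cells CPM-normalized, per-cluster mean profiles, genes ranked
per cluster by log2 fold-change of (mean CPM + 1) over the mean of the
other clusters, ties broken lexicographically by gene name, top N = 30 by
default (any manual/enrichment-guided marker curation is irreproducible,
so a deterministic criterion replaces it — a declared stand-in). A gene
marking two clusters appears once among the signature rows.

Estimators fit each bulk sample on the signature *as given* and
renormalize coefficients to sum to one; callers must supply bulk and
signature on a comparable scale (the pipeline CPM-normalizes bulk counts;
signatures are already mean-CPM). Rescaling signature columns inside the
fit would silently distort the recovered mixing weights, which is why the
normalization lives at the pipeline boundary. The admixture estimator
refits ordinary least squares after repeatedly removing the most-negative
coefficient's cell type until all remaining coefficients are nonnegative —
the iterative scheme conventionally associated with
"proportions in admixture". The elastic-net (dcq) penalty acts after the
problem is rescaled to unit mean signature magnitude, so `penalty` is
scale-free; `penalty=0` reduces to truncated OLS. All-zero solutions fall
back to uniform fractions with a warning. Sex comparison of estimated
proportions uses a two-sided rank-sum test per cell type with BH (no test
is prescribed by convention; rank-sum is robust to the non-normality of
fractions).

## Mediation

Exposure-slope inference is normal-theory OLS with t-tests; variables are
standardized by default so slopes are comparable across genes. An
exposure–mediator correlation beyond |r| > 0.999 makes the adjusted design
numerically singular: the record is flagged unstable with missing p_adj.

The mediated call requires all three of: p_unadj < 1e-6 (the stringent
direct-interaction threshold), delta_log10p > 2 decades, and p_adj > 0.01.
The first two express "a strong association that loses significance when
adjusted". The third — the association must actually collapse — was added
after the two-condition rule was shown to be wrong in a specific,
reproducible way: a mediator correlated with the exposure at r ≈ 0.85 but
carrying none of the target association inflates the adjusted standard
error by 1/√(1−r²) ≈ 1.9, which alone costs a very strong association
(p ~ 1e-25) more than ten decades, flagging 100% of planted *independent*
triplets. With the collapse condition, full-mediation triplets are flagged
at ≥ 0.97 and independent ones at 0.00 over 100 simulation seeds. All
three thresholds are exposed parameters. No Sobel or bootstrap
indirect-effect test is performed; the screen is a transparent
operationalization of "adjusting removed the significance", and the margin
has no external calibration — it is a declared parameter.

The screen selects, per (cell type, sex), the top-ranked myokine by bicor
p against the proportion vector as the candidate mediator, and takes its
stringent-significant survey edges (top 5 per tissue by default) as
targets.

## Known limitations and honest negatives

* The 2SD rule and the p < 0.01 survey mode are *survey* conventions, not
  calibrated error controls: on a pure null they label ~8.7% and ~2.0% of
  pairs respectively (two strata). The BH mode exists for users who need
  FDR control.
* Detection power at planted strength 0.4 is asymmetric by design of the
  cohort: the male stratum (n = 100) detects essentially all planted
  edges, while the female stratum (n = 50) has ~65% power at p < 0.01
  (|r| must exceed 0.354) and ~77% under the 2SD threshold. This is a
  sample-size fact, not an estimator defect; `shared` edges compound both
  strata. The acceptance suite records these recovery rates as measured.
* Deconvolution benchmarks use mixtures generated from the same signature
  being fitted; real bulk/single-cell platform mismatch is out of scope.
* Problem sizes throughout (cohort 100/50, 2000 genes/tissue, 100-seed
  mediation benchmarks, universe ≤ 30 ORA enumeration) are the package's
  desk-scale defaults chosen to keep a full run interactive.
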