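# Methods

`rsaevol` asks, branch by branch on a fixed phylogeny, whether the solvent
accessibility profile of a protein evolves faster or slower than its
amino-acid sequence.  A relative acceleration of structural change is read
as a signature of shifting intra-protein epistatic interactions: residues
moving between buried and exposed positions imply rearrangement of the
globule, whereas amino-acid turnover that preserves accessibility is
structurally conservative.

## The two channels

The amino-acid channel is an ordinary gapped protein alignment.  The RSA
channel starts from per-residue relative solvent accessibility values
discretised on a 5-unit grid from -5 ("unknown") to 95, as produced by any
structure-aware predictor, and recodes each grid value as a letter of a
20-symbol pseudo-amino-acid (PAA) alphabet:

    -5=A 0=R 5=N 10=D 15=C 20=E 25=Q 30=G 35=H 40=I
    45=L 50=K 55=M 60=F 65=P 70=S 75=T 80=W 85=Y 90,95=V

(The package's matrix ordering is A R N D C E Q G H I L K M F P S T W Y V
throughout, and the PAML writer records it in a header comment.)  The two
highest grid values share 'V', so the map is injective except for that
pair.  A coarser 10-category alphabet (adjacent grid values paired,
80–95 collapsed onto 'W') and arbitrary user reductions are supported;
`category_usage` tracks symbols that a family never uses, because absent
categories both signal data uncertainty and leave the corresponding
exchangeabilities prior-dominated.  Unknown RSA at a non-gap residue is
encoded as the 'A' (unknown) category rather than as a gap; -5 is the
grid's explicit unknown code.  The recoding lets every piece of standard
protein phylogenetics machinery run unchanged on structural data, with the
gap pattern shared between channels by construction.

## Substitution models

Each channel of each family gets its own general time-reversible (REV)
model: symmetric exchangeabilities `s_ij`, stationary frequencies `pi`, and
rate matrix `q_ij = s_ij pi_j` normalised to one expected substitution per
site per unit branch length.  Frequencies are empirical (+F) with a
pseudocount of 0.5 so that absent PAA categories keep strictly positive
frequencies.  Exchangeabilities are estimated by maximum likelihood on the
fixed topology: bounded quasi-Newton (L-BFGS-B) updates on log `s` (the
last alphabet pair fixed at 1 for identifiability) alternate with
branch-length optimisation until the log-likelihood improves by less than
1e-4, capped at 50 rounds.  Models travel in PAML triangle text format.

## Likelihood engine

Likelihoods use Felsenstein pruning over unique column patterns; gaps and
unknowns contribute all-ones partials.  `P(t) = exp(Qt)` comes from the
spectral decomposition of the pi-symmetrised rate matrix, so the
single-branch site likelihood has the form `sum_k coef_k exp(lam_k t)`.
Branch lengths are optimised coordinate-wise on that spectral form with a
safeguarded Newton iteration (first and second derivatives are nearly free
in this parameterisation; steps that would lower the objective backtrack,
and lengths are clamped to [1e-6, 10] — ten substitutions per site is the
conventional cap, configurable).  Sweeps repeat until the log-likelihood
gain drops below 1e-4.  With a bifurcating root only the sum of the two
root-adjacent lengths is identifiable for a reversible model (pulley
principle); the optimiser splits that sum equally after each sweep, which
leaves the likelihood untouched and keeps both branches' downstream
statistics stable.  The hot loops (postorder pass, branch sweep) are
numba-compiled; the numpy implementations remain as the reference path and
the two are asserted to agree.

### Heterotachy mixture

Heterotachy — a site's rate varying across the tree — is modelled as a
mixture of H classes (default 3), each with its own full branch-length set
and, by default, its own frequency vector; exchangeabilities are shared
with the family model.  Fitting is EM: classes start from the single-set
optimum with lengths scaled by a geometric ladder ({0.5, 1, 2} for H=3) and
uniform weights; each iteration runs the weight updates to convergence on
the current class likelihoods (weights are the slowest-mixing coordinate),
takes two joint branch sweeps per class with responsibility-weighted
pattern counts, updates class frequencies from responsibility-weighted
counts (accepted only if the mixture likelihood does not drop), and then
attempts a step-doubling extrapolation of (lengths, frequencies) along the
EM direction, again accepted only on improvement.  Convergence is a
mixture log-likelihood gain below 1e-3.  Classes whose weight falls below
1e-4 are frozen and reported.  A cold fit that somehow ends below the
single-set optimum falls back to that optimum, so the mixture likelihood
never undercuts the nested model.  Branches and frequency vectors that
stop moving are skipped between periodic full passes; every skipped update
would have contributed less than the convergence tolerance.  Inside the
jackknife stage, each replicate's fit warm-starts from the previous
replicate's optimum (the first replicate runs the cold ladder) — replicates
are exchangeable halves of the same data, so this is an initialisation
device only; EM still runs to the same tolerance.

The scalar branch length reported for a mixture is the weight-averaged
class length — the expected evolved distance, which reduces to the
single-set value when the classes agree.  Reports sort classes by total
tree length, fixing the otherwise arbitrary class labelling.

### Site partitions

The baseline model assigns each site a diversity category: the count of
distinct non-missing symbols, binned into 8 equal-width bins over the
achievable range [1, min(K, n_taxa)] (quantile binning available behind a
flag).  Each non-empty category gets its own empirical frequencies and its
own edge-unlinked branch-length set; categories under 5 sites are merged
into their nearest neighbour.  The combined per-branch length weights each
category by its fraction of sites, and `effective_categories` reports how
many categories hold at least 5% of sites and what share of the alignment
they cover.

## The branch statistic

Data variation is simulated by the delete-half jackknife: 100 replicates,
each floor(n/2) distinct columns drawn without replacement, the same column
sets applied to both channels so the ratio compares like with like.  For
every inner branch and replicate the statistic is `ln L = ln(l_rsa/l_aa)`,
both lengths floored at 5e-5 (the meaningful minimum of a branch length)
before dividing.  Branches whose median RSA-channel length falls below the
floor are filtered out, as are branches whose ln(L) interquartile range
reaches 6 (|ln L| > 6 is exactly a floored length against a large one, so
such spreads flag model instability rather than signal; 4 and 5 are probed
as well).  Each retained branch's ln(L) sample (the 1-set) is then tested
against the pooled ln(L) values of all retained inner branches of the same
tree (the 0-set, randomly subsampled to at most 10x the 1-set size) with a
two-sided Mann-Whitney U test (tie-corrected normal approximation), Holm
correction across the tree's branches, and Cliff's delta as effect size.
A branch is called accelerated at delta >= 0.7 with Holm-adjusted
p < 1e-4, decelerated at the mirrored condition; in consensus mode a call
stands only if the partition model agrees at its own threshold of 0.6.

The 0-set deliberately includes the focal branch's own values.  On small
trees this matters: each branch's ln(L) sample carries a dataset-level
offset (the two channels' independent estimation errors do not cancel), and
with only a handful of reference branches an excluded-self pool understates
that offset distribution, letting noise saturate the effect size.  The
self-ties anchor delta (its ceiling is `1 - n_1/n_0`), which is what keeps
the false-call rate low while a genuinely shifted branch still clears the
threshold whenever at least four inner branches are available.

Summaries follow the same robust theme: per-family median ln(L) and the
mean shift `(mean - median)/median` (undefined at median 0), signed
differences of positive versus negative Cliff's delta counts at thresholds
0.3–0.7, distribution moments of per-branch median lengths per channel
with a Welch t-test between channels, per-class RSA/AA heterotachy weight
ratios (classes paired by tree-length rank), and per-clade counts of
accelerated (Na) and decelerated (Nd) branches driven by a user-supplied
clade-to-branch-labels map.

## Synthetic data

The generator emulates the pipeline's three inputs with known truth: a
shared topology (fixed or Yule-shaped), independent REV models per channel
(log-normal exchangeabilities, Dirichlet frequencies), root states from
`pi` and descent through `P(t)`, and a numeric RSA profile obtained by
decoding the simulated PAA alignment through representative grid values
('V' maps back to 90), so re-encoding reproduces the PAA channel exactly.
Focal branches scale the RSA channel's generating lengths by a multiplier
f (f=1 is the exchangeable null); an optional class mixture generates
genuinely heterotachous sites.  Defaults: 6 taxa, 2,000 gap-free sites,
branch lengths uniform on [0.02, 0.12] — typical vertebrate protein-family
depths where most branches are short.  What the generator does not
emulate: indels (gap-free by default), structural constraints or real
solvent-accessibility physics, site-to-site dependence, and alignment
error; passing tests therefore demonstrate the statistical machinery's
operating characteristics, not predictor accuracy on real structures.

## Validation design choices

Tests that measure operating characteristics run scaled down: 2,000 sites,
20 jackknife replicates, 50 seeds per condition, on a rooted balanced
6-taxon tree (four inner branches — the minimum at which an accelerated
call is reachable, since self-ties cap delta at `1 - n_1/n_0`).  The
branch-length recovery check uses a trifurcating-root 6-taxon tree (every
branch identifiable), 5,000 sites, short tips and deep internal branches
with near-uniform frequencies; at these settings the MLE's own sampling
error is ~3-4% per draw, so recovery is judged per branch aggregated over
10 seeds, where a systematic 10% error would stand out at many sigma.
Exactness checks (pruning vs. explicit state enumeration, the
equal-exchangeability closed form, Cliff's delta vs. the O(nm) definition,
Holm vs. an independent implementation) run at 1e-10 or tighter.

## Known limitations

The statistic is relative to the tree's own branches; on very small trees
(three or fewer inner branches) accelerated/decelerated calls are
unreachable at the default thresholds by construction.  EM mixture fits
find local optima; the warm-start chain and extrapolation make the
jackknife columns reproducible but a different initialisation can land on
a slightly different optimum.  The U-test treats jackknife replicates as
independent samples although delete-half replicates overlap; the
thresholds (delta >= 0.7, p < 1e-4, IQR < 6) are calibrated for screening,
not for literal error-rate guarantees on real data.  Polytomies are
tolerated but their child branches are treated independently.
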