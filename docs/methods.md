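# Methods

This note documents the models implemented in `opsel`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Codon substitution model

The substitution process is the reversible 61-state Markov chain over the
sense codons of the standard nuclear genetic code.  For codons i, j
differing at exactly one nucleotide,

    q_ij = pi_j                     synonymous transversion
    q_ij = kappa * pi_j             synonymous transition
    q_ij = omega * pi_j             nonsynonymous transversion
    q_ij = kappa * omega * pi_j     nonsynonymous transition

and q_ij = 0 for multi-nucleotide changes; diagonals close the rows.
omega = dN/dS is the selection parameter: omega > 1 means positive
selection, omega < 1 purifying selection.  omega is capped at 999, the
conventional boundary, and estimates within 1e-4 (relative) of a boundary
are reported exactly at it, because boundary fits are themselves
informative (an "omega = 999" fit means the synonymous rate on that branch
is effectively zero).

Equilibrium frequencies default to **F3x4** (position-specific nucleotide
frequencies multiplied per codon, stops excluded, renormalized), with
equal-frequency and empirical (F61) options.  The frequency model used by
any particular published analysis is rarely recoverable; results that are
sensitive to this choice are validated by property-based tests rather than
value matching.

**Transition probabilities.** P(t) = exp(Qt) via eigendecomposition of the
symmetrized generator D^{1/2} Q D^{-1/2} (D = diag(pi)), which is exact
for reversible Q and lets repeated P(t) evaluations reuse one
decomposition.  When any pi_i < 1e-12 the symmetrization is ill-posed and
the code falls back to `scipy.linalg.expm`.  States with pi = 0 are
retained with zero incoming rate so matrix dimensions are stable across
genes.

**Scaling with site-class mixtures.** All class generators share a single
scale factor: the expected rate of the *background-branch* mixture,
mu = sum_c p_c * r(omega_c^bg).  One unit of branch length therefore means
one expected codon substitution on background branches.  The simulator
uses the identical convention, so simulated branch lengths and fitted
branch lengths are commensurable.  This choice matters only for the
interpretation of branch lengths, not for likelihood ratios.

## Model families and tests

| family               | site classes (proportions)        | omega structure                                   |
|----------------------|-----------------------------------|---------------------------------------------------|
| one-ratio            | 1                                 | one omega everywhere                              |
| two-ratio            | 1                                 | omega_bg, omega_fg                                |
| M1a                  | p0, p1                            | 0 < omega0 < 1; omega1 = 1                        |
| branch-site A        | p0, p1, p2a, p2b                  | classes 2a/2b: omega2 >= 1 on foreground only     |
| M2a_rel              | p0, p1, p2                        | omega0, 1, omega2 >= 0 shared across branches     |
| clade C              | p0, p1, p2                        | class 2: omega2_fg vs omega2_bg                   |

The branch-site proportions obey p2a/p2b = p0/p1 *by construction*: the
optimizer works on (s, r) with p0 = s·r, p1 = s(1−r), p2a = (1−s)r,
p2b = (1−s)(1−r), so the constraint cannot be violated.

The battery for a focal lineage runs: two-ratio vs one-ratio (df 1);
two-ratio vs the omega_fg = 1 constraint (df 1, one-sided interpretation);
branch-site Test 2 (model A vs its omega2 = 1 null, df 1); clade C vs M1a
(df 3 — clade C has three more free site parameters); and clade C vs
M2a_rel (df 1), the relaxed null that absorbs among-site variation in
constraint and reduces clade-model false positives.  A gene is flagged per
test when p < 0.05 and the relevant foreground omega exceeds 1 (for clade
C, additionally omega2_fg > omega2_bg).  No multiple-testing correction is
applied by default; a Benjamini–Hochberg column is available.

Using chi-square df 1 for Test 2 is conservative: under the null the true
large-sample distribution is a boundary mixture (½χ²₀ + ½χ²₁), so the
realized type-I error sits below the nominal level.  The calibration test
accepts any rejection count inside the exact binomial 95% interval around
0.05, which accommodates this known conservativeness.

**Fitting.** L-BFGS-B on transformed parameters: log for kappa, omegas and
branch lengths; logistic for probabilities and omega0; the stick-breaking
transform above for simplex proportions; omega2 = 1 + exp(x) for the
branch-site alternative's [1, 999] box.  Convergence tolerance 1e-8 on the
log-likelihood, finite-difference gradients (step 1e-6 in transformed
space).  Multi-start over kappa ∈ {1, 2, 5} × omega ∈ {0.1, 0.5, 1.5} by
default; per-start log-likelihoods are retained so start-value sensitivity
can be audited.  Branch lengths are estimated once under the one-ratio
model and held fixed for the other families (a flag allows co-estimation);
fixing them preserves exact nesting along the model ladder.  In nested
pairs the alternative is additionally warm-started from the null's
optimum, which guarantees lnL_alt ≥ lnL_null up to optimizer tolerance.
An LRT statistic below −0.02 is treated as a failed fit (error), not a
statistical result; within [−0.02, 0] it is clamped to zero.

## Site posteriors (NEB / BEB)

NEB plugs the MLEs into Bayes' rule per site.  BEB averages the same
posterior over a 10×10×10 grid: midpoints of (0,1)² for the stick-breaking
coordinates (s, r) and ten equal steps of omega2 on [1, 11], uniform prior,
with kappa, omega0 and branch lengths held at their MLEs and the MLE
mixture's generator scale retained throughout.  The canonical BEB
construction integrates exactly this low-dimensional parameter subset; the
grid and range are package constants documented here because the original
is not recoverable from any publication's methods text.  A site's
"positive selection" probability is the posterior mass of classes 2a + 2b,
reported with flags at 0.50 / 0.95 / 0.99.

## Ancestral reconstruction

Marginal empirical-Bayes reconstruction under fixed empirical amino-acid
models: JTT (the published Jones–Taylor–Thornton exchangeabilities and
frequencies, shipped as package constants) or Poisson (equal rates and
frequencies).  Posteriors come from the standard inside–outside pruning
pass; they are invariant to the computational root because both models are
reversible (tested to 1e-8).  Branch lengths are re-estimated by ML under
the same empirical model on the fixed topology before reconstruction —
posteriors are meaningless without calibrated lengths — unless the caller
opts out.  The best reconstruction is the maximum-posterior state; ties
are broken toward the alphabetically first residue and flagged.  Gapped or
ambiguous tip residues contribute a partial likelihood of 1 over their
compatible states (standard missing-data treatment), and ancestral states
above them are still emitted with support reflecting that uncertainty.

Substitution events are called from best states only (not integrated over
the posterior), with support = min of the two endpoint posteriors exposed
on every event; this mirrors the usual "highest posterior probability"
reporting style (e.g. support ≥ 99.4%) while keeping the uncertainty
visible.  Two branch sets share a site when both carry an event to the
same derived state there: "parallel" if the ancestral states also agree,
"convergent" otherwise.

## Reference numbering and spectral tuning

Spectral-tuning sites are indexed on bovine rhodopsin (NP_001014890,
348 aa, shipped in the package).  Query sequences are mapped by global
pairwise alignment with fixed parameters — BLOSUM62, gap open −11,
extend −1 — chosen once so that numbering is reproducible; the map is
strictly monotone and injective by construction.  The packaged rule table
carries the replacement-specific λmax effects relevant here (LWS S164A
−7 nm, LWS T269A −15 nm, SWS2 S292A +8 nm, plus two classic RH1 rules),
each with its literature citation; users can extend the table from the
mutagenesis literature.  Rules are exact (class, site, from, to) matches:
measured effects are replacement-specific, so there are no site wildcards
and no assumed reversal antisymmetry (A164S is *unmatched* unless a rule
says otherwise).  Multiple matched effects add; additivity is the standard
first-order assumption in spectral-tuning inference, and only the sum is
interpreted.  Absolute λmax values are out of scope — only shifts relative
to the reconstructed ancestor are computed.

## Synthetic data

The simulator is event-level Gillespie simulation per site and branch:
root state from pi, site class from the mixture, exponential waiting times
from the class/partition generator.  It records every substitution (with
its position along the branch and synonymous/nonsynonymous status) and all
internal-node sequences, so ancestral-reconstruction accuracy and
event-calling precision can be scored exactly; a replay invariant checks
that reapplying the history to the root reproduces the tips byte for byte.
One master seed is expanded into independent per-site streams
(`numpy.random.SeedSequence.spawn`), making datasets reproducible and
column-order independent.

What it emulates: site-class mixtures with branch-switching omegas,
transition bias, arbitrary codon frequencies, JTT/Poisson amino-acid
evolution.  What it does not: indels (simulated alignments are ungapped),
rate variation beyond the discrete classes, recombination,
alignment error, and assembly artifacts.  Passing tests therefore
demonstrate correctness of the inference machinery under the model, not
robustness to the alignment/orthology problems that dominate real
transcriptome work.

## Test problem sizes

Simulation-based tests use an 8-taxon four-clade tree (two taxa per clade,
terminal branches 0.15, stems 0.4, foreground = owl stem) unless stated:
one-ratio recovery at 500 codons (tolerance ±0.05 on omega); branch-site
power at omega2 = 5 on 10% of sites, 500 codons, 20 seeded replicates
(majority rejection required); type-I calibration on a 6-taxon tree at
200 codons, 100 seeded null replicates with a single optimizer start.
These sizes give each replicate enough information for the asymptotic
chi-square machinery to be meaningful while keeping the whole suite
runnable on a laptop; the branch lengths match the information content
used in the classic branch-site power studies.  Reconstruction accuracy
uses 16 taxa × 200 sites with branch lengths ≤ 0.1 (root best-state
accuracy > 90% required).

## Known limitations

- Codon families beyond the ladder listed above (M2a, M3, M7/M8...) are
  not implemented; amino-acid model parameters are never optimized (ASR
  uses fixed empirical matrices).
- The likelihood treats gaps as missing data; columns that are mostly gaps
  contribute little information but are not filtered automatically.
- BEB integrates proportions and omega2 only; very short alignments will
  still show plug-in bias in kappa/omega0.
- The clade-C vs M1a comparison uses df 3 asymptotics; near-boundary
  proportions make this test conservative, which is one reason the
  M2a_rel comparison is preferred.
- Branch lengths fixed from the one-ratio fit slightly understate
  uncertainty in downstream tests; co-estimation is available behind a
  flag at a runtime cost.
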