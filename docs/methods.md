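# Methods

This note records the models, conventions, numerical choices and study
sizes behind `ponevo`, and what the synthetic-data validation does and
does not establish.

## Substitution models and likelihood

Amino-acid models are GTR-form reversible matrices Q = S·diag(π) built
from a symmetric exchangeability matrix S and stationary frequencies π.
Poisson (equal S, uniform π) is included for closed-form checks; JTT and
LG ship as JSON data files (sha256-verified at load) whose values match
the published matrices.  Rate heterogeneity uses the discrete-Gamma
approximation with k equal-probability categories represented by their
**bin means** (k = 4 by default; means, not medians, to match the
convention of the programs this emulates).  An optional invariant-sites
class takes probability p_inv with rate 0; the Gamma rates are rescaled
by 1/(1 − p_inv) so the full mixture keeps mean rate 1.  Note the outer
bin means of Γ(α, α) sit at 1 ± ~1.27/√α, so even at α = 10⁴ the
discretized rates spread by ~±0.013 — the approximation collapses to a
point mass only in the limit.

Codon models follow Goldman–Yang on the 61 sense codons of the standard
code: zero rate between codons differing at more than one position or
involving stops; κ multiplies transitions, ω nonsynonymous changes, and
the target codon frequency multiplies every rate.  Codon frequencies
default to F3x4 estimated from the alignment (F1x4 and F61 available);
which frequency model the original analyses used is not knowable from
their description, so this default is declared, not inferred.

All matrices are scaled so one unit of branch length equals one expected
substitution per site under the model's own rate/class mixture.  For
branch-site models, the shared scale is the mean **background** rate of
the mixture, so branch lengths are expressed in background
substitutions; the simulator uses the identical convention, which is
what makes parameter recovery a meaningful check.

Likelihoods are exact Felsenstein pruning over compressed site patterns,
with per-node rescaling against underflow and gaps/ambiguities treated
as missing data (all-ones partials).  Transition matrices come from the
symmetric spectral decomposition of Q (π-square-root similarity), which
is exact, stable, and reusable across branches; equality with scipy's
`expm` and with exhaustive interior-state enumeration is part of the
test suite, and rerooting changes the log-likelihood by < 1e-8 (pulley
principle).

## Optimization

Branch lengths are optimized one at a time by bounded Brent searches on
a log-length scale (bounds [1e-8, 50]), cycled until a full sweep gains
< 1e-6 log units (default); free model parameters (α, p_inv, κ, ω,
mixture proportions — proportions through logit/conditional-simplex
coordinates) alternate with branch sweeps until joint convergence.
Everything is deterministic: fixed starting values (lengths 0.1, α = 1,
κ = 2, ω = 0.5; branch-site fits start at κ = 2, ω₂ = 1, the
conventional initial point for that test), no randomness.  Because the
M2a/M8/branch-site surfaces are multimodal, those fits run a small set
of deterministic restarts (ω₂ ∈ {2, 5} with complementary proportion
starts) and keep the best.  A per-branch search window (± 2.5–3 log
units, re-centered every sweep) bounds the cost of each univariate
search without constraining where the optimum can end up; wide-open
searches remain available and are used where closed-form agreement is
asserted.  Parameters that finish at a bound are flagged in the fit
diagnostics.

In the replicated simulation studies (power/size calibration), branch
lengths are estimated once under M0 and shared by the branch-site null
and alternative — a standard and much cheaper protocol than re-fitting
lengths per model, and a fair one because both hypotheses see identical
lengths.  Single analyses optimize everything by default.

## Topology contrasts and model selection

Candidate topologies are refit independently (branch lengths plus
requested free parameters) and compared by 2Δℓ against χ²(1).  These
contrasts are not nested hypotheses in the usual sense; χ²(1) is used
deliberately because it is the convention of the analyses this package
reproduces, and the raw Δℓ is always emitted so users can apply other
calibrations.  AIC = 2k − 2ℓ ranks substitution models, ties broken by
fewer parameters then label.

## Selection tests

Site-class families: M0 (one ω), M1a (ω₀ ∈ (0,1), ω₁ = 1), M2a (adds
ω₂ ≥ 1), M7 (Beta(p, q) discretized to k_b = 10 equal-probability bin
means), M8 (Beta plus a point mass at ω_s ≥ 1), and branch-site model A
(classes 0: ω₀ everywhere; 1: neutral; 2a/2b: ω₂ on foreground branches
over ω₀/1 backgrounds, selection mass split p₀:p₁), with the null
pinning ω₂ = 1.  Foreground branches are user-supplied `#1` marks in the
newick; there is no automatic foreground selection.  LRTs: χ²(2) for
M1a/M2a and M7/M8; χ²(1) for the branch-site test.  The branch-site
χ²(1) is the plain-χ² usage (not the more conservative 50:50 mixture
calibration); the statistic is always reported for recalibration.  The
M7→M8 discretization error is parameter-dependent (larger for L-shaped
betas); the suite checks that refinement gaps shrink monotonically with
k_b rather than asserting a universal tiny gap.

NEB site identification applies Bayes' rule at the MLEs.  BEB averages
the selection-class posterior over a uniform discrete prior grid —
proportions on a d × d triangle grid (d = 10) and ω₂ on d midpoints of
(1, 11) — holding κ, ω₀/beta parameters and branch lengths at their
MLEs.  This follows the published BEB scheme's structure, but numerical
agreement with other BEB implementations is **not** claimed.  Reports
carry a standing caveat that multinucleotide substitutions and
synonymous-rate variation (the BUSTED model) are not modeled and can
inflate branch-site positives.

## Family-scan rules

E-value (≤ 10⁻⁶ on both full-sequence and best-domain) and BLAST
(coverage ≥ 90%, identity ≥ 50%) thresholds are **inclusive**: a
"maximum of 1e-6" is read as an attainable bound.  The 100-kb tandem
rule measures the gap between nearest gene ends (overlap → 0) and chains
arrays by single linkage, so an array may span more than 100 kb
end-to-end when every consecutive gap passes; letters are assigned in
(scaffold, leftmost start) order, which the source convention leaves
unspecified — determinism is what matters here.  Loss calls are per
(group, family) and require absence in every species of the group.  The
retroduplication rule — exon_count = 1 against a sibling median ≥ 2 —
is this package's formalization of the intron-loss observation.
Duplication nodes on gene trees are labeled by species-set overlap of
child subtrees after deterministic (left-fold) resolution of
multifurcations.

## Structural clustering

ASA is Shrake–Rupley with a deterministic golden-spiral point set
(960 points/atom by default, probe 1.4 Å, vdW radii by element); points
exactly on a shared sphere surface are credited to the lower-indexed
atom so coincident spheres count once.  This reproduces exposure
*classification* in the spirit of surface-area tools, not any specific
program's numeric ASA.  Exposure: residue ASA ≥ 20% of the residue
type's theoretical maximum (Tien et al. 2013 values, shipped in code);
the threshold is inclusive and configurable.  The clustering statistic
is the mean pairwise Cα distance of the selected residues (mean
nearest-neighbor available behind a flag); the null draws equal-size
subsets uniformly without replacement from the exposed residues (or all
residues with a Cα, by flag).  p = (b+1)/(N+1) with b the count of null
draws at or below the observed value, so p ≥ 1/(N+1) and claims at the
10⁻⁶ scale need N ≥ 10⁶.  The original study names neither its
statistic nor its null pool; these choices are declared as this
package's own.

## Synthetic data: what it does and does not show

The sequence simulator samples the root from π and end-point states
along each branch from the exact transition matrices of the likelihood
model (no intermediate-event simulation is needed for end points), with
per-site latent classes recorded in truth tables.  Locus tables plant
tandem arrays with chosen inter-gene gaps (distinct arrays on one
scaffold are separated by 400 kb, safely beyond the 100-kb window),
whole-group absences, retrocopies (exon_count 1 vs 4–11 for others), and
e-values that optionally straddle the 10⁻⁶ cutoff on either or both
criteria.  Pseudo-structures are self-avoiding random walks with 3.8 Å
Cα steps plus an optional cluster placed uniformly in a sphere.  One
master seed spawns a named, CRC32-keyed child stream per operation, so
generators are mutually independent and individually reproducible.

Passing tests on these inputs show the *rules and estimators are
implemented correctly and calibrated under their own assumptions*.  The
generators deliberately omit indels and alignment error, selection on
synonymous rates, multinucleotide mutations, assembly artifacts
(fragmented scaffolds, uncollapsed haplotypes), and real protein
geometry (side chains, secondary structure) — so green tests here say
nothing about robustness to those real-data features.

## Study sizes

Validation studies run at these sizes (chosen to give informative error
rates at desk scale; the acceptance script scales some replicate counts
down, noted in parentheses):

- Engine-vs-enumeration: 100 random trees of 2–5 leaves, 1–10 columns.
- Closed-form distance: 20 random (n, d) two-taxon pairs.
- ω recovery: M0 at ω ∈ {0.2, 1, 3}, κ = 4, 2,000 codons, 6 taxa,
  20 replicates (12 in the script); tolerance ±20% relative.
- Branch-site power: p₂ = 0.12, ω₂ = 5, 400 codons, 50 replicates (30).
- Branch-site size: null simulations at 200 codons, 200 replicates
  (100); the χ²(1) test is conservative at this scale.
- Family scan: 200 random planted tables, exact recovery required.
- Clustering: planted 8-residue cluster (radius 6 Å) in 150 residues at
  N = 10⁴ permutations; null uniformity over 200 (100) random
  selections, KS at α = 0.01.

## Known limitations

- No topology search, bootstrap, or alignment construction: trees and
  alignments are inputs.
- BEB is a faithful-in-structure reimplementation, not a numerical
  clone of any external program; posteriors can differ in the third
  decimal and occasionally flip marginal sites.
- The branch-site χ²(1) and the non-nested topology χ²(1) are
  conventions, not exact asymptotics; both statistics are exported raw.
- Quantities that depend on the original study's data — its curated
  alignments, foreground tree, and the 1V04 crystal structure — are not
  reproducible from synthetic data; the pipeline exposes the commands to
  run them when those files are supplied.
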