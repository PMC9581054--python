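# Methods

## Model

A new missense mutation belongs to one of three fitness classes — effectively
neutral (N), mildly deleterious (M), strongly detrimental (S) — with
genome-wide priors P(N) = 0.27, P(M) = 0.53, P(S) = 0.20, and to one of
three edgotypes — quasi-wild-type (QW), edgetic (E), quasi-null (QN).
Observed mutation sets give the class-conditional edgotype probabilities:
common variants from healthy individuals (MAF ≥ 1%) estimate P(T|N),
Mendelian pathogenic mutations estimate P(T|M). Both identifications are
modelling assumptions: common variants are treated as neutral on average and
pathogenic mutations as mildly deleterious on average. No genome-wide set of
strongly detrimental missense mutations exists, so P(T|S) is bracketed by
two extreme scenarios:

* **Assumption I** — strongly detrimental mutations are all quasi-null
  (P(QN|S) = 1): the destructive extreme.
* **Assumption II** — they are edgotype-distributed like mildly deleterious
  mutations (P(T|S) = P(T|M)): the least destructive extreme.

The marginal P(T) follows from the law of total probability and the
posteriors P(F|T) from Bayes' theorem. The reported summary for each
(edgotype, fitness-class) pair is the interval from the Assumption-I value
to the mean of the two assumptions' values, reflecting the judgement that
Assumption I is the better approximation.

### Confidence intervals

Writing 1/P(F|T) = 1 + Q, the interval for Q is transformed through this
monotone equation. Q is a function of the two independent binomial
estimates p̂₁ = P(T|N) (x₁/n₁) and p̂₂ = P(T|M) (x₂/n₂):

* Whenever Q is an affine function of the single ratio r = p̂₂/p̂₁ (or its
  inverse) — all Assumption-II cases (where P(T|S) is the *same estimate*
  as P(T|M), hence perfectly dependent) and the Assumption-I quasi-wild-type
  and edgetic cases — the exact log-scale interval for a ratio of
  proportions is used: SE(log r) = √((1/x₂ − 1/n₂) + (1/x₁ − 1/n₁)).
* For the Assumption-I quasi-null forms, the constant P(T|S) = 1 term leaves
  Q a genuinely two-dimensional function of (p̂₁, p̂₂); there a first-order
  delta-method propagation of the two binomial variances is used.

A zero success count receives a ½ continuity correction with a warning.
Intervals are truncated to [0, 1] and always bracket the point estimate.
The normal quantile for 95% is fixed at 1.959964 for exact determinism.
A vectorized parametric bootstrap (`fitness.parametric_bootstrap_ci`)
provides an independent simulation check; at the published sample sizes it
agrees with the analytic intervals within ~0.2 percentage points for the
ratio cases, and simulated-coverage of the ratio interval is 94.7–95.0%
over 10⁴ replicate count tables (both verified in the test suite).
Printed fractions may be supplied in place of counts; interval estimation
then requires the explicit sample sizes (x = p·n is used in the variance
formulas).

## Structural pipeline

**Template annotation.** Reference PPIs (unordered protein pairs,
deduplicated, self-interactions retained) are annotated with a chain-pair
template when the two chains share a binding interface and each protein's
best alignment (smallest E-value ≤ 1e−5 per protein/chain pair; ties break
toward more aligned columns, then lexicographic chain id) maps ≥ 50% of
that chain's interface residues. When several chain pairs qualify, the one
maximizing min(coverage) is kept, tie-broken by summed coverage then
lexicographic chain pair — the selection criterion was an open design
choice. Template coordinates are used directly through the alignment
position maps rather than rebuilding homology models: every downstream rule
consumes residue positions and template geometry only, so results are
unchanged while an external modelling step is avoided.

**Geometry.** A residue is interfacial iff its minimum heavy-atom distance
to any residue of the partner chain is ≤ 5 Å (4 and 6 Å are the sweep
settings). ASA is computed by Shrake–Rupley sphere sampling (Fibonacci
quadrature, default 960 points/atom, probe 1.4 Å, Bondi single-element
radii) over all heavy atoms of the assembly, via `biotite.structure.sasa`.
RSA divides a residue's ASA by a per-amino-acid maximum; the default table
is the published theoretical maximum-ASA set (Tien et al. 2013), chosen as
a reproducible default since the original DSSP-percentile table is not
redistributable — a user-supplied table is accepted. RSA is not clipped at
1. Burial uses RSA ≤ 0.25 (boundary buried). Multi-model files keep the
first model; waters, hetero-compounds and hydrogens are excluded; residues
are renumbered sequentially per chain, so insertion codes never matter.

**Mutation mapping.** Pathogenic records keep only missense variants
strictly labelled pathogenic, with ≥ 1 review star and no conflicting
interpretations. Common records keep validated, non-withdrawn missense
variants with MAF ≥ 0.01 and none of the excluded assertions {pathogenic,
likely pathogenic, drug-response, uncertain significance, other}
(configurable); a missing MAF drops the record. Flank verification requires
the window of up to 10 residues on each side of the site (truncated at
sequence ends, wild-type residue at the site) to occur at the reported
position in both the transcript and the protein sequence — the identical
window on both, which is the stricter reading of an ambiguous rule. One
record is kept per (protein, position) (first in stable input order;
highest-star available behind a flag), and common records overlapping
pathogenic positions are discarded.

**Classification.** Interface membership takes priority over RSA (an
interfacial residue with burial-range RSA is interfacial). Edgetic calls
require at least one partner binding ΔΔG strictly above 0.5 kcal/mol and
list every partner above the cutoff as disrupted. Buried mutations with
folding ΔΔG ≥ 2 kcal/mol (inclusive) are quasi-null. Interfacial mutations
are never routed to the quasi-null branch, which is why quasi-null
fractions — and the quasi-null fitness posteriors — are invariant to the
binding cutoff (asserted in the sweep tests). Whether folding ΔΔG should
ever be consulted for interfacial mutations was an open question; it is not,
consistent with that invariance. ΔΔG values are consumed as input tables
(plain TSV, plus a FoldX-difference-style dialect for fixtures); computing
them is out of scope.

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
their biology. Toy chains use two heavy pseudo-atoms per residue (anchor +
1.5 Å offset, all carbon) on a 10 Å lattice line; planted interface pairs
sit at 4.5 Å and every other cross-chain pair is beyond 6.5 Å, so the 5 Å
rule recovers exactly the planted sets with margin against boundary
flakiness. Scenario chains append a compact 3×3×3 core at 4.9 Å spacing so
some residues are genuinely buried; ground-truth location labels are
derived by running the geometry module at generation time (interface truth
remains by construction and is independently checked against an O(n²)
brute-force scan). Class-conditional ΔΔG values are truncated Gaussians —
disruptive binding N(2.5, 1.0) truncated below at 0.6, benign N(0, 0.3)
truncated above at 0.45, disruptive folding N(3.5, 1.0) truncated below at
2.0 — margins that make the true edgotype unambiguous, so end-to-end
recovery must be exact. Mutation tables corrupt a requested fraction of
transcript flanks by one substitution away from the site. Default scenario
conditions use the Y2H-derived class-conditional edgotype probabilities
(97/1.5/1.5% and 74/13/13%) with 120 common and 60 pathogenic mutations
over 20 proteins and 10 PPIs — enough for every branch of the pipeline to
be exercised while the suite stays fast. What passing tests show: the
operators implement their rules exactly and the inference recovers known
parameters; what they cannot show: realistic folds, alignment error,
ΔΔG-prediction error, or allele-frequency structure, none of which the
generator models.

## Numerical choices and limitations

* Interface detection uses KD-trees; equality with the brute-force scan is
  asserted over 100 random complexes at 4/5/6 Å.
* SASA quadrature error is ~1/√points; the single-atom closed form
  4π(r + 1.4)² is reproduced within 1% at 2000 points and doubling the
  point count moves residue ASA by < 2%.
* Degenerate inputs: zero-variance t-test input raises; a zero contingency
  margin raises; P(T) = 0 raises rather than returning NaN posteriors;
  single-residue chains define the distance-to-center ratio as 0.
* The worked-example report is pure arithmetic and bit-reproducible; the
  pipeline is deterministic given the scenario seed (checksummed outputs,
  asserted byte-identical on rerun).
* Real-data quantities that depend on ClinVar/dbSNP/PDB/FoldX downloads
  (absolute mutation counts, experimental TPR/FPR values, RSA t-test
  p-values) are outside desk scale; the operations that would compute them
  are covered by the property suites instead.
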