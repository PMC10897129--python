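# Methods

## The chemistry model

`dblipid` models the one-pot, two-step, three-component construction of
degradable branched (DB) lipidoids as two formal transforms on RDKit
molecules.

**Ring opening.** A nitrogen bearing a substitutable hydrogen attacks the
terminal CH₂ of a 1,2-alkyl epoxide (SN2 at the less hindered carbon),
giving `N–CH₂–CH(OH)–alkyl` with a *secondary* alcohol. No atoms leave.
"Substitutable" means: non-aromatic N, at least one H, and not amide-like
(no neighboring carbon double-bonded to O/S/N). Hydrazine nitrogens
qualify — they do attach tails; their penalty is applied later at
headgroup classification. Applied twice this yields the aminoalcohol
lipidoid with two body tails and two hydroxyls. When several nitrogens
carry hydrogens the lowest canonical atom index reacts first, which sends
both tails to a primary amine (2 H on one N) and one tail to each nitrogen
of a di-secondary diamine (1 + 1 H) — matching the observed substitution
patterns.

**Acylation.** Each free hydroxyl is esterified by an acyl chloride with
formal elimination of HCl. The branch-tail carbon count n includes the
carbonyl carbon (an "8-carbon acyl chloride" is octanoyl), which is the
convention that makes the 18-carbon sums come out.

**Degradation.** `degrade` is the esterase inverse: each cleavage consumes
one water, the acyl fragment leaves as the fatty acid (acyl–OH) and the
remnant regains its hydroxyl. Cleaving both esters returns the
aminoalcohol, so `degrade(acylate(a, c, k), k) == a` holds by canonical
SMILES equality for k ∈ {1, 2}, and the element balance

    amine + 2 epoxide + 2 acyl chloride = product + 2 HCl
    product + k H₂O = remnant + k fatty acid

is asserted over the full 500-member factorial in the test suite.

**Structure bookkeeping.** All structures are canonical, stereo-free,
free-base SMILES: the bench reaction is racemic and run on neutralized
amines, and string equality then doubles as structure equality. Salt-form
inputs are stripped to their largest fragment and uncharged on load.
Product stage is inferred from the structure itself (two esters →
`two_branch`, one → `one_branch`, none → `aminoalcohol`).

Masses: monoisotopic masses come from a fixed table of principal-isotope
masses (reported to 2 dp for MS comparison; the lead C₄₂H₈₂N₂O₄ gives
678.63 Da, [M+H]⁺ 679.63); average masses from standard atomic weights via
RDKit. Metabolite masses use the average mass, matching how metabolite
molecular weights are conventionally quoted against the < 500 Da
rapid-clearance heuristic.

## Descriptors and design rules

For a lipidoid `x-m-n`:

* total tail carbons TC = m + n;
* tail symmetry s = n/(m − 2), deviation d = |s − 1|. The −2 offset is
  applied exactly as defined in the field; no mechanistic interpretation
  is attached to it. s is displayed rounded to one decimal (1.7, 0.6, 3)
  but all comparisons use the unrounded value. s is undefined for m ≤ 2
  and raises.
* headgroup class: primary/secondary/tertiary amine counts by SMARTS on
  the free base; the tertiary *kind* is `dimethylamino` (exactly two
  methyl substituents), `diethylamino` (exactly two ethyls),
  `pyrrolidinyl` (N in a saturated all-carbon 5-ring), else `other`
  (piperidinyl, morpholino and diisopropyl all fall here — only the three
  named kinds are known-efficacious, so anything else is conservatively
  non-efficacious). The spacer is the number of carbons strictly between
  the primary and tertiary nitrogen on the shortest bond path; any
  heteroatom on that path disqualifies the motif.

The efficacious headgroup class is: exactly one primary and one tertiary
amine, tertiary kind in the named three, spacer ∈ {2, 3}, no hydrazine.

The rule engine classifies a candidate predicted-potent iff TC = 18,
d ≤ d_max and the headgroup is efficacious. **d_max defaults to 1.0**: the
cutoff must admit the known near-symmetric hits (d = 0.7 and 0.4) and
exclude the known symmetric-rule failure (d = 2); 1.0 is the midpoint-
stable choice and is exposed in `RuleConfig`. The continuous rank score is
`d + 100·|TC − 18| + 100·(headgroup fail)`; since a compliant candidate's
score is at most d_max, the penalty of 100 guarantees any violator ranks
below every compliant candidate. Ties break lexicographically by name.

Screening over multiple library designs deduplicates products by name
(the 10/8-tailed amine-1 product appears in both shipped library designs),
so hit rates refer to unique candidates: 44 unique from 25 + 20, of which
8 are predicted potent (hit rate rounds to 18%).

## The shipped registry

Epoxides and acyl chlorides are the even-carbon C6–C14 series. Amine 1 is
3-(dimethylamino)-1-propylamine. Amines 2–20 are curator-provided fixture
structures (flagged as such in the data file): their exact identities are
not public in machine-readable form, so the fixture realizes the
documented class structure instead — monoamines (2, 3, 6), hydrazines
(4, 5), a four-carbon-spacer diamine (8), wrong-tertiary-kind diamines
(13 morpholino, 14 piperidinyl, 15 diisopropyl), di-secondary diamines
(16–20), and the six efficacious diamines (1, 7, 9, 10, 11, 12) spanning
both spacers and all three tertiary kinds. Amine 11 is pinned to
1-(2-aminoethyl)pyrrolidine (C₆H₁₄N₂) by the lead product's published
formula C₄₂H₈₂N₂O₄. Every amine in the registry can attach exactly two
body tails, the admission criterion for the factorial library. Swapping in
a corrected registry CSV changes nothing else in the pipeline.

## Packing parameter

P = V/(A·L) is computed from a single conformer: ETKDGv3 embedding with a
fixed seed, then MMFF94 minimization (up to 4000 iterations; UFF
fallback), so results are deterministic per seed and toolkit version.

* **V** — union-of-spheres van der Waals volume on a cubic grid, default
  spacing 0.2 Å (halving the spacing moves V by < 1%).
* **Head set** — by default the ionizable-amine region: every nitrogen
  plus heavy atoms within two bonds. Including the ester groups is
  available as an option but not the default: the esters sit at the
  branch point of the tails, and counting them as head inflates A for the
  four-tailed lipidoid until the shape contrast with a two-tailed
  benchmark disappears.
* **A** — the head atoms are projected onto the plane perpendicular to the
  first principal axis of the tail atoms; A is the area of the union of
  their projected van der Waals disks. A bare-point convex hull is
  available as an alternative but underestimates compact heads badly (a
  handful of near-collinear points has almost no hull area, which is why
  the disk union is the default); the hull path raises a descriptive
  error on degenerate projections.
* **L** — tails are the connected components of heavy atoms outside the
  head; each tail's length is the through-space distance from its
  attachment atom to its most distant terminal carbon, and L is their
  mean. Through-space distance (not path length) is used: P is a property
  of the folded conformer, and it is configurable via explicit
  `tail_definitions`.

Absolute P values depend on the force field and on the head/tail
convention and are **not** comparable across implementations; published
values from proprietary force-field setups are treated as orderings, not
targets. Under this module's defaults the four-tailed 10/8 lead lipidoid
has median P ≈ 2.6 over 5 seeds versus ≈ 1.8 for the MC3 benchmark — both
cone-shaped (P > 1), with the branched lead more so, which is the
reproducible claim.

## Synthetic screen generator

The generator emulates the statistical structure of a two-channel
lipidoid screen, not its biology. Per candidate:

    log10 flux = bg + boost·[compliant] − k_d·d − k_TC·|TC − 18| + σ_vivo·ε

with background bg = 6.7 (just below the 10⁷ p/s in vivo background),
boost ~ U(1, 3) orders of magnitude for rule-compliant candidates,
deviation slope k_d = 0.8, carbon penalty k_TC = 0.5 per carbon, and
log-normal noise σ_vivo = 0.3. A candidate is a *hit* when its flux
reaches the benchmark reference level, a configured constant bg + 2.5
orders (screens report potencies relative to a benchmark, so the
reference is a free constant; with boost capped at 3 this makes roughly
the upper half of compliant candidates hits). The in vitro channel is
log-normal around 10⁴·⁵ RLU (σ = 0.8) from a latent that is coupled to
the in vivo noise with correlation ρ, default 0 — the two channels are
generated independent because that is the empirically observed structure.
The one deliberate cross-channel constraint is the *necessity clamp*:
every hit's in vitro latent is rejection-resampled until it clears the
10⁴ RLU floor (bounded at 1000 draws, then set to the floor), making the
threshold necessary but not sufficient by construction.

Defaults are the package's study conditions and are not tuned per run.
`recover_parameters` closes the loop: ordinary least squares of log10
flux on [1, compliant, d, |TC − 18|] with percentile bootstrap CIs
(default 1000 resamples, seeded). On self-simulated data the estimates
recover the generating slopes — exactly at zero noise, and within 95%
CIs at n = 500 with noise 0.2 (asserted over 5 replicates, since a
single 95% interval misses 5% of the time by construction).

What the generator does **not** model: dosing and pharmacokinetics,
formulation quality, encapsulation efficiency, inter-animal variance,
replicate structure, or any mechanistic structure-activity link beyond
the additive log-linear effects above. Analyses that pass against it
validate the analysis code, not biological claims.

## SAR analytics

Heat-map cells and contour bins summarize replicates by the **median** of
log10 readouts (log-normal data; medians resist the heavy tail). Missing
(m, n) combinations stay absent rather than zero-filled. Contour bins
default to unit-width total-carbon bins and deviation edges
{0, 0.25, 0.5, 1, 2, ∞}, chosen to separate the landmark deviations 0,
0.4, 0.7 and 2; on generator defaults the argmax bin sits at TC = 18,
d < 0.5. The channel correlation is a two-tailed Pearson test on the
log10 readouts (p from the t distribution with n − 2 df, via SciPy);
p-values are reported, never thresholded internally, and no
multiple-testing correction is applied since each analysis runs one
planned test. The threshold-necessity analysis reports both conditional
directions (P(above | hit) and P(hit | above)) with the full contingency
counts.

## Formulation arithmetic

Mole percentages are proportional to weight/MW and normalized to 100;
`molar_to_weight` inverts this (round trip identity within 1e-9
relative). The optimized lead recipe is recorded at molar ratio
40/10/48.5/1.5 (lipidoid/DOPE/cholesterol/DMG-PEG): the cholesterol
percentage circulates in two variants (48.5 and 48.8) and 48.5 is adopted
because only it sums to 100 — kept as a validation note on the spec, not
silently corrected elsewhere.

## Pipeline and problem sizes

`run_pipeline` chains enumerate → describe → predict → simulate → analyze
deterministically from a single config (every stochastic stage takes an
explicit seed) and writes a manifest with library versions, the seed and
SHA-256 digests of all outputs; reruns are byte-identical. The default
config screens the two shipped library designs (44 unique candidates).
The test suite exercises the full 500-member factorial for conservation
laws, contour recovery and parameter recovery, 50 generator seeds for the
correlation-decoupling property, and 5 conformer seeds per molecule for
the packing ordering — sizes at which the whole suite runs in well under
a minute on one CPU apart from the conformer work.

## Known limitations

* Reaction modeling is formal: no yields, kinetics, regiochemical side
  products, or crude-vs-purified differences.
* The headgroup classifier knows only the three efficacious tertiary
  kinds; exotic but possibly efficacious headgroups are conservatively
  rejected.
* The structure-only (m, n) fallback is not implemented for arbitrary
  ester-containing molecules outside the x-m-n naming scheme; descriptors
  rely on enumeration provenance.
* Packing parameters are single-conformer estimates; they rank shapes
  under a fixed convention but are not converged ensemble properties.
* Amines 2–20 are fixture stand-ins (see above); conclusions specific to
  an individual amine's structure should be re-checked against a curated
  registry.
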