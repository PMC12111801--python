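# Methods

## Scope and data model

The package implements a staged triage of small molecules produced by gut
bacteria: chemical ingestion and filtering, permeability classification,
ligand-based target fishing by prediction frequency, pathway
over-representation, docking-score triage, and consensus-numbered
protein–ligand interaction fingerprints. External engines (target
prediction services, ADME web platforms, docking software, pathway
databases) are *not* reimplemented: their outputs are the pipeline's inputs,
read from plain-text dialects, and a synthetic-data module generates
statistically controlled stand-ins for all of them.

## Chemical stage

SMILES are parsed and canonicalized with RDKit; the canonical form is the
deduplication key, and the 200-character length rule is applied to the
canonical spelling (input spellings are not reproducible across sources).
The "four atoms or fewer" rule counts heavy atoms, since hydrogens are
implicit in SMILES and the upstream prediction platforms operate on
heavy-atom graphs. Unparseable records are logged and skipped, never fatal.

Descriptors are Wildman–Crippen atom-contribution logP (WLOGP) and Ertl
fragment-sum topological polar surface area with sulfur/phosphorus
contributions included (TPSA, Å²); the S/P terms are kept for parity with
the descriptor set the permeability model was calibrated on.

Permeability uses the BOILED-Egg two-ellipse classifier in (TPSA, WLOGP)
space. The source study delegates the boundary to the published model
without printing parameters, so the packaged defaults
(`src/metafunnel/data/ellipses.yaml`) transcribe the published best-fit
ellipses — white/GI: center (71.051 Å², 2.292), semi-axes (71.04 Å², 4.37),
rotation −0.0180 rad; yolk/BBB: center (38.117 Å², 3.177), semi-axes
(41.03 Å², 2.78), rotation −0.00465 rad — and are overridable via YAML.
Membership is a closed-region test. BBB permeation is reported only within
the GI-absorbed subset (funnel convention); the two regions themselves are
evaluated independently, so a user can recover the unconditional calls.
Funnel percentages are rounded to 2 decimals (GI) and 1 decimal
(BBB-of-GI), with an integer mode for whole-percent reporting.

## Target selection

Frequency counting is binary per metabolite–gene pair. The carbonic
anhydrase family (default pattern `^CA\d+[A-Z]?$`) is excluded *before*
thresholding (the narrative order of the upstream analysis); the opposite
order is available behind a flag. "Above 50% of the maximum frequency" is a
strict inequality; exact ties at the half-max line are excluded by default
and an inclusive mode exists because a dashed-line threshold on a frequency
plot is ambiguous at ties (the CLI warns whenever a tie occurs). Prediction
probabilities are carried but never filtered on — the procedure defines no
probability cutoff.

## Over-representation

One-sided upper-tail hypergeometric test only (over-representation), with
the tail sum evaluated in log-space (log-binomials via `gammaln`, combined
with `logsumexp`) so deep tails in large universes do not underflow; the
implementation is cross-checked in tests against exhaustive enumeration for
all universes N ≤ 25 and against an independent survival-function
implementation. The universe defaults to the union of annotated genes; an
optional universe file represents interactor-expanded backgrounds.
Multiple-testing control is Benjamini–Hochberg; the significance filter is
applied to the adjusted values by default (the defensible reading of a
"p ≤ 0.05, FDR-corrected" filter), with a raw-p mode. Ties are broken by a
stable sort on pathway id. Strength is log10(observed/expected), reported
as null when nothing is observed.

## Docking triage

Scores are unitless docking-engine values, more negative = stronger; no
unit conversion is attempted. The per-receptor cutoff is the
linear-interpolation quantile (the "type 7" convention, index q·(n−1) on
the ascending sort) at q = 0.05 — the boundary of the strongest 5%. The
convention is a package choice; the source procedure names no quantile
rule. Ties at the cutoff count as hits (affinity at least as strong as the
limit), and a ligand enters the hit report when it passes for any one
receptor while being brain-permeant. Missing cells in sparse score tables
are excluded pairwise, never imputed. Classes with fewer than 4 ligands
(ketone bodies and retinoids in the packaged panel) are dropped from
inferential comparisons, mirroring the small-sample exclusions of the
analysis being emulated.

Kruskal–Wallis uses midrank tie correction with the chi-square
approximation; Dunn's post-hoc z statistics use the pooled-rank variance
with tie correction, adjusted by Benjamini–Hochberg by default (the named
"Dunn's correction" does not pin a family-wise scheme; Bonferroni is a
flag). The chi-square approximation is validated against a permutation
oracle in tests. The parametric route is a two-way ANOVA
(class × receptor, type-II sums of squares) with Tukey HSD per factor;
empty design cells raise rather than silently unbalance, a constant
response reports F = 0, and single-level factors reduce to one-way ANOVA.

## Fingerprints and consensus numbering

Contacts from complex structures use a heavy-atom/heavy-atom cutoff,
default 4.0 Å, closed interval; the cutoff is a mandatory, documented
config value because the emulated workflow never states its distance.
Backbone/sidechain flags follow the N/CA/C/O atom-name convention.
Hydrogen-bond capability is flagged geometrically (polar–polar heavy-atom
distance ≤ 3.5 Å, no angle term) when coordinates exist; tabular contact
inputs carry categories as passthrough flags. Residue chemistry classes
(hydrophobic, aromatic, polar, charged) follow fixed lists that include
force-field protonation variants (HIE/HID/HIP, ASH, GLH, LYN, CYX, ARN);
variants fall back to their parent residue for the hydrophobic/aromatic
classes, while the explicit polar/charged lists are authoritative.

Consensus numbering maps the i-th non-gap position of each aligned receptor
sequence to its 1-based alignment column; maps from alignments are strictly
increasing and injective by construction (a round-trip property test).
Residue tables transcribed from printed sources are carried verbatim even
where the printed column order is internally inconsistent, so
fixture-derived maps are exempt from the monotonicity requirement. A
built-in Needleman–Wunsch global aligner with affine gaps (gap of length L
costs open + (L−1)·extend) and deterministic tie-breaking (diagonal, then
vertical, then horizontal) removes any dependence on an external alignment
service for tests; its scores are validated against brute-force enumeration
(lengths ≤ 6) and an independent aligner.

Fingerprint frequencies use the full analyzed ligand panel as denominator —
ligands with zero contacts still count. The >50% and >75% sets use strict
inequalities. Coincidence rates are directional: 100·|A∩B|/|A| with the
first-named receptor as reference; this is the only convention that
reproduces the printed 3/8 = 37.5% and 1/8 = 12.5% isoform overlaps, and
the asymmetry is asserted in tests. The corresponding RXR "co-identity"
percentages are not reproducible from the printed sets under any
intersection convention tried and are therefore reported as computed, not
matched. Pharmacology classes: agonist residues are those contacted by at
least one agonist-class ligand; antagonist-only residues are contacted by
antagonist-class and never agonist-class ligands; isoform-unique residues
appear in exactly one receptor's contacted set in consensus space.

## Synthetic data

The generators define the study conditions; they are not tuned per test.
Defaults: 500 metabolites with a planted permeability mix of 10% brain
permeant, 46% absorbed-only, 44% outside (emulating the ~56% absorbed /
~17%-of-absorbed-permeant funnel of the emulated study); 10 hot targets hit
with probability 0.6 against a background rate 0.1 over a 200-gene
universe; docking scores Normal(−5, 1) for the screen and Normal(−8, 1) for
the planted strong class, truncated to [−12, 0] (the reported bulk range is
−2 to −7, with strong binders beyond); a planted fingerprint of 8 consensus
columns contacted with probability 1.0 plus 2% noise contacts; one planted
pathway with a 10/15 overlap of the hot set among 50 pathways.

Molecules are assembled from a fragment vocabulary (alkyl chains, benzene,
indole, hydroxyl, amine, carboxyl, amide, sulfonamide, polyols), descriptor
annotated once, partitioned by BOILED-Egg region, and sampled without
replacement from the class-matched pool — so planted permeability classes
are correct by construction; an exhausted pool falls back to reuse with a
warning. Receptor sequences for the contact scenario are gapped slices of a
common 60-column consensus, so consensus numbering is exercised genuinely.
A single root seed expands into per-stage substreams keyed by a stable hash
(CRC-32) of the stage name: adding a stage never perturbs earlier streams,
and every generator is bit-reproducible given (seed, config).

What the synthetic data does *not* emulate: chemistry-aware docking (scores
are class-conditional Gaussians, not functions of the molecule), realistic
target-prediction correlation structure (hits are independent Bernoulli),
and the actual metabolite inventories of any organism. Green recovery tests
therefore demonstrate that the *statistical machinery* — thresholding,
testing, triage, fingerprint extraction — recovers planted truth at the
stated effect sizes, not that the upstream predictions themselves are
accurate.

## Problem sizes and numerics

Recovery properties are evaluated at the generator defaults (n = 500
metabolites, 20 seeds for target-selection and hit-purity rates; 10 seeds
in the acceptance script; 1000 draws for the null-calibration check). The
hypergeometric implementation is compared exhaustively for N ≤ 25 and spot
checked at larger N. Quantile and alignment operations are compared against
sort-based and exhaustive oracles on small instances. Degenerate inputs are
defined behaviors, not crashes: empty selections give p = 1, constant
score columns give equal order statistics, zero-GI funnels report a null
BBB percentage, and an empty reference set makes a coincidence rate an
error rather than 0/0.

## Known limitations

- The permeability model is a 2-descriptor classifier; ionization, efflux
  transport and active uptake are out of scope, as in the emulated
  workflow.
- Gene symbols are normalized only by case/whitespace; synonym resolution
  against a nomenclature service is out of scope.
- The transcribed residue tables inherit the printed sources' internal
  inconsistencies (a receptor row whose entry count differs from the prose,
  one non-monotone printed column pair); these are documented and carried,
  not silently corrected.
- Two-way ANOVA requires a complete class × receptor layout; severely
  unbalanced panels should use the rank-based route.
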