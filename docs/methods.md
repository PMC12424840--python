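# Methods

## Data model

The unit of analysis is the **formula**: one traditional-medicine
preparation with a set of ingredient species, free-text indication strings,
a medical-system label and a region code.  Compounds link to species
(species → compound membership), and a formula is taken to contain a
compound whenever *any* of its member species is linked to it.  Raw exports
rarely state how species-specific compound lists were flattened into
multi-species formulas; this any-member-species rule is the package's
documented choice and all statistics, oracles and generators use it
consistently.

Compound identity across sources is reconciled by identifier precedence:
records sharing an InChIKey merge; records without an InChIKey merge on a
shared CID; records with neither merge on case-folded,
punctuation-collapsed names.  InChIKey wins because it is the most
structure-specific identifier; conflicting lower-tier identifiers under one
InChIKey are kept (first value) and logged, never fatal.  The precedence
scheme makes reconciliation a partition of the input records and
order-independent, both of which are property-tested.

Species strings are reduced to `Genus epithet` binomials (authority strings
and infraspecific ranks stripped, an optional synonym table applied after
normalisation).  The genus *Piper* is the focal genus throughout; the
species record carries an `is_target_genus` flag that drives the
Piper/non-Piper splits.

## Indication dictionary

Four categories — Anxiety/Mood (18 terms), Movement/Seizure (15), Pain
(13), Sleep (9) — are shipped as a two-column CSV so users can extend them.
A term is a literal or carries one asterisk at either end: `depress*` fires
on any token starting with the stem, `*ache` on any token ending with it.
Matching is case-insensitive over tokens split on non-alphanumeric
boundaries, and **literal terms match whole tokens only**: "fits" must not
fire inside "benefits", nor "calm" inside "calmness".  The rationale is
that the asterisked forms are explicit truncations, implying that the
non-asterisked forms are exact; substring matching is available behind a
switch for sensitivity analysis, and the test suite pins the difference.  A
formula treating *k* categories counts once in each of them; no fractional
weighting is applied anywhere.

## Association statistics

Two percentage statistics with different denominators coexist and are never
interchanged:

* **association percentage** (per compound, per category): denominator is
  the compound's containing formulas.  The four percentages sum to at most
  400; the candidate filter keeps compounds with sum **strictly greater
  than 300** ("exceeding"), sorted by sum, then containing-formula count,
  then key, so listings are byte-stable.  A compound contained in no
  formula yields an explicitly flagged undefined profile rather than zeros.
* **compound index** (per compound): denominator is each category's
  treating formulas; the index is the arithmetic mean over the four
  categories.  A category no formula treats is excluded from the mean with
  a warning (or raises under strict mode).

Species–category **linkage counts** pair every member species of a formula
with every category the formula treats (a two-species, four-category
formula contributes 8 linkages).  The **enrichment ratio** for a species
divides its share of category-linked (formula, species) memberships by its
share of all memberships; 1 is neutral.  All four statistics are verified
exactly against an independent triple-loop brute-force oracle on 100 seeded
datasets.

## Composite metabolome

Per-source compound lists are merged with the same reconciliation rule; the
unit is the compound, so within-source duplicates count once.  Class
binning is a two-layer rule shipped as an editable CSV: identifier-level
overrides first, then case-insensitive keyword rules on the source-supplied
classification string (e.g. any string containing "terpen" → terpene);
anything unmatched is miscellaneous.  Keyword binning is deliberately
data-driven because source classifications are naming-convention-dependent.
The provenance table keeps one row per (extraction-study, compound) pair
with method and solvent; databases and literature compilations are
excluded from it.  The packaged fixture has eight class bins of sizes
29/31/39/28/10/35/17/79 (total 268), and assembly is source-order
invariant.

## Networks

The bipartite graph has one edge per distinct species–compound link;
compound nodes carry their class bin, species nodes their genus.  The
species projection connects pairs sharing at least `min_shared` compounds
(default 1) and weights each edge with the raw shared count and the Jaccard
fraction shared/|union|.  Both weights are reported because raw counts are
dominated by chemically over-studied species while Jaccard normalises that
away.  Exports (edge-list TSV, GraphML) rebuild the graph in sorted node
and edge order, so identical graphs serialise to identical bytes; layout
and rendering are left to external viewers.

## Druggability

Descriptors are computed with RDKit: molecular weight, H-bond
acceptors/donors (pharmacophore-style definitions by default, with a switch
to plain N+O / NH+OH counting), topological polar surface area, rotatable
bonds, Crippen logP, and a 2048-bit Morgan fingerprint of radius 2 (ECFP4).
"Polarizable surface area" in this feature family is read as TPSA, the
standard topological descriptor.

**Rule of Five** violations count breaches of MW > 500 Da, logP > 5,
donors > 5, acceptors > 10 — strict inequalities, so a molecule exactly at
a threshold does not violate it.

**Weighted QED** is the exponentially-weighted geometric mean
`exp(Σ wᵢ ln dᵢ / Σ wᵢ)` of eight property desirabilities (MW, ALOGP, HBA,
HBD, PSA, ROTB, aromatic rings, structural alerts), each an asymmetric
double sigmoid.  The canonical published desirability coefficients and
weights ship as `data/qed_params.csv` so alternative weight sets are a
configuration change; desirabilities are floored at 1e-10 before the log.
The raw properties are taken from RDKit's QED property calculator, and the
implementation is tested to agree with RDKit's own QED to 1e-6 — a genuine
dual route, since the combination rule and parameters here are independent
of the reference code.

**NP-likeness** ([−5, 5]) is an input column where observed; missing values
are imputed by a scikit-learn RandomForestRegressor with 150 trees, depth
cap 80, trained on an 85/15 random (unstratified) split of the labelled
records over the 2054-dimensional feature vector.  One seed governs split,
bootstrap and feature subsampling.  Observed values are never overwritten,
and the imputed fraction is reported in `evaluation.json`.  Records whose
descriptors cannot be computed are skipped with a log entry rather than
feature-imputed.

## Synthetic data: what it emulates and what it does not

The dataset generator draws, per formula: member species from a pool with a
configurable Piper fraction; an independent Bernoulli per category
(prevalence defaults 0.3 — roughly the share of neuro-relevant entries a
mixed pharmacopeia carries); indication phrases from a bank in which every
phrase matches exactly its intended category under the packaged dictionary,
plus decoy phrases (rate 0.3) crafted to match nothing ("benefits",
"calmness") that pin the whole-token semantics.  Compounds attach to
formulas two ways: a background species→compound membership layer (density
0.05) and formula-level attachments at `baseline_inclusion` (+ the largest
applicable per-(compound, category) uplift), routed through one member
species.  Because routed attachments are visible to other formulas sharing
that species, planted-association tests use the `dedicated_species` mode
(one private species per formula) when leakage must be zero.  All draws
come from one `numpy` PCG64 generator, so a fixed seed reproduces files
byte for byte.

The molecule panel enumerates ~2950 distinct valid structures from a
packaged fragment library (12 cores × 16 substituents at two sites,
RDKit-validated and canonicalised).  NP-likeness labels follow a fixed
documented linear function of descriptors plus seeded Gaussian noise
(default σ = 0.25), clipped to [−5, 5].  The non-zero coefficients
(+0.75·HBD, −0.28·rotatable bonds, intercept 0.4) sit on discrete
descriptors on purpose: the label function is then piecewise constant over
a few dozen descriptor combinations, each represented many times in the
library, which makes the ground truth recoverable essentially exactly by a
depth-capped forest — noise-free validation R² ≈ 0.999 at n = 2000 — so
imputer tests measure the pipeline, not interpolation luck.  At σ = 0.25
the protocol yields validation R² ≈ 0.91 and MSE ≈ 0.08 at n = 2000.

None of this mimics real pharmacopeia vocabulary distributions, real
co-occurrence structure, or real chemical space: passing tests demonstrate
that the statistics, reconciliation and imputation machinery are correct
under known ground truth, not that any particular real-world association
is reproduced.  Real-data figures (tens of thousands of compounds, filter
pass counts, imputed fractions) depend on proprietary source tables and
are out of scope.

## Numerical and design choices

* Percentages are plain `float` on the 0–100 scale; no rounding happens in
  memory, only in CSV exports (6 decimals).
* All sorted outputs document their tie-breaks; every writer emits rows in
  sorted order so re-runs are byte-identical (tested end to end through the
  CLI).
* The candidate-filter threshold comparison is strict; the RO5 thresholds
  are strict; band membership in the set comparison (wQED 0.4–0.7,
  NP-likeness 0.5–2.5) is inclusive.
* Empty inputs degrade explicitly: undefined-percentage flags, n = 0
  summary rows, empty provenance tables — never silent zeros where a value
  is genuinely undefined.
* Problem sizes in the scripted analysis (400 formulas, 2500 panel
  molecules, 100 oracle datasets of ≤ 50 formulas) were chosen as the
  smallest scales at which every statistic is exercised with comfortable
  statistical margins.

## Known limitations

* No taxonomic-backbone resolution beyond the user-supplied synonym table;
  vernacular names must be resolved upstream.
* No statistical significance testing of associations — the statistics are
  descriptive, matching their intended decision-support use.
* The Ertl NP-likeness fragment score is not computed from scratch;
  observed scores are inputs and the imputer only extends them.
* Classification into the eight bins is keyword-driven and inherits the
  naming conventions of the source tables; the override layer exists
  precisely to patch misclassifications compound by compound.
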