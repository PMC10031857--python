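# Methods

## The model

`rulenet` performs iterative reaction-network expansion. Enzymes are often
promiscuous: a catalytic mechanism that transforms one substrate will usually
transform chemically similar substrates too. Generalized reaction rules
capture that mechanism as a reaction SMARTS — a substructure pattern over the
reactants plus the bond rewiring that produces the products — together with
role tokens saying which reactant slots are filled from the growing network
("Any") and which are fixed coreactants (water, oxygen, ammonia, ...).

A run starts from a seed metabolite set (generation 0). Each generation
applies every selected rule to every ordered substrate assignment drawn from
the *frontier* — the compounds first seen in the previous generation that no
filter flagged — and merges the results into the network. Candidate reactions
are discarded unless every product structure sanitizes and the element
multiset of the reactants equals that of the products, hydrogens included
(counting hydrogen is the stricter choice; a rule that silently sheds H2
would otherwise go unnoticed). The loop ends after a fixed number of
generations or as soon as the frontier empties.

Compounds rediscovered later keep their original generation tag and are never
re-expanded; rediscovered reactions are not duplicated. Reaction membership
(`compound.reaction_ids`) is updated on both sides of every admitted
reaction.

## Identity

Identity is content-derived, so independent runs and processes agree:

- compound ID = `"C"` + SHA-1 of the structure's InChIKey. Any SMILES
  spelling of a structure canonicalizes to the same InChIKey, hence the same
  ID; this is what deduplicates the network.
- reaction ID = `"R"` + SHA-1 of a normalized formula string: each side's
  `(coefficient, cid)` pairs sorted by cid, sides joined with `=>`.
  Participant order is irrelevant; direction and stoichiometry are encoded.

SHA-1 is used purely as a stable content hash (no adversarial setting);
collisions are negligible at network scales of 10^7 entities.

## Standardization

Incoming structures are parsed, neutralized (RDKit Uncharger; centers with no
valence-legal neutral form, such as quaternary nitrogen, stay charged with a
warning), stripped of stereochemistry, and written as canonical SMILES.
Both normalization steps are defaults that can be disabled; the shipped rule
dialect is stereo-free, but user rules may retain stereo. Standardization is
idempotent. Multi-fragment SMILES (`A.B`) are rejected — a seed row must
describe one molecule. Formulas expand implicit hydrogens; monoisotopic
masses are summed from a pinned element-mass table
(`rulenet/data/monoisotopic_masses.csv`, proton mass 1.007276466 Da for
adduct arithmetic) so masses never drift with toolkit versions.

## Rule files and coverage-ordered subsetting

Rules load from a TSV (`rule_id`, `reactants` role tokens `;`-joined,
`smarts`, `products`, plus metadata: mapped-reaction count and optional
`|`-joined ID set, UniProt IDs, feature flags); column-name synonyms cover
the published-file layout. Rules are kept sorted by
`(-mapped_count, rule_id)` — the stable tie-break makes prefix subsetting
reproducible. Subsetting takes the first *n* rules, or the shortest prefix
whose cumulative coverage reaches a requested fraction; feature
include/exclude criteria compose with either and are applied after the
prefix. Coverage is the union of per-rule mapped-reaction ID sets when every
rule carries IDs, else a normalized count sum; `Ruleset.coverage_semantics`
records which was used, because the two differ whenever rules overlap.

## Filters

Each filter declares a phase:

- **pre-expansion** (similarity cutoff, similarity sampling): scored on the
  frontier *before* it is expanded. The cutoff filter drops compounds whose
  maximum Tanimoto similarity to any target is strictly below the threshold
  (a score equal to the cutoff survives); already-reached targets are exempt
  so a strict cutoff cannot discard the very compounds being sought. The
  sampling filter keeps `min(n, |frontier|)` compounds drawn without
  replacement with probability proportional to `score^k` (`k = 0` is
  uniform; all-zero weights fall back to uniform with a warning), which
  bounds per-generation growth at `n`.
- **post-expansion** (property, metabolomics, thermodynamics, feasibility):
  applied to the compounds and reactions the generation just produced.

Fingerprints are RDKit path-based bit vectors, 2048 bits; the parameters are
configuration, not constants, and are pinned in output metadata. Similarity
is Tanimoto over those bit sets. A molecule with no bond paths (methane) has
an empty fingerprint and scores 0 against everything.

Filter composition is survivor-set intersection: flags from all same-phase
filters are unioned before pruning, so order never changes the result.
Cofactors are exempt from compound-level filters.

**Pruning.** By default (`prune_on_filter`) flagged compounds are removed
together with every reaction referencing them; flagged reactions are removed
directly. A compound produced this generation whose every producing reaction
was pruned is removed with them — keeping it would claim a provenance the
network no longer contains (and matches the observed behaviour that
reaction-level filters shrink compound counts). Referential integrity (no
dangling cid/rid) is asserted after every run. A flag-only mode
(`prune_on_filter=False`) retains flagged entities unexpanded for audit.

**Metabolomics.** Candidate m/z values per compound are
`(multiplicity·M + mass_shift)/|charge|` over the adduct table (a small
curated default ships: [M+H]+, [M−H]−, [M+Na]+, [2M+H]+). A compound is kept
iff some adduct/peak pair matches within the tolerance — inclusive bound, Da
or ppm units (Da default). Every match is recorded in a compound–peak pair
table. Matching is strict per generation: non-matching intermediates are not
retained to bridge later matches.

**Thermodynamics.** ΔG of reaction comes from a provider interface
(`dg(reaction, registry, conditions) -> kJ/mol | None`). Conditions support
standard, physiological (pinned pH 7.5, ionic strength 0.25 M, concentrations
1 mM), and user-adjusted modes. A reaction is kept iff
`dg_min ≤ ΔG ≤ dg_max` (inclusive) *or* ΔG is unknown — the filter cannot
comment on reactions outside the estimator's scope, and provider errors are
treated as unknown (fail-open). The packaged default provider returns
unknown for everything, so the engine carries no mandatory dependency on an
external thermodynamics service.

**Feasibility.** A classifier interface over substrate→product pairs. A
reaction is reduced to its principal pair: the largest non-cofactor
substrate and product by heavy-atom count, ties broken by canonical SMILES
order. The reference predictor accepts everything; a deny-list predictor
serves as the test stub. Failures fail open, mirroring the thermodynamics
filter.

**Target efficiency.** For a run *i* and reference run *r* (conventionally
the strictest cutoff examined),
`TE = (Targets_i / Compounds_i) / (Targets_r / Compounds_r)` — how many
targets a run yields per compound generated, relative to the reference.
Undefined (raises) when a denominator is zero.

## Determinism and parallelism

All randomness flows through seeded NumPy generators; the sampling filter
derives a per-invocation stream from its seed plus an invocation counter, so
successive generations draw differently but the whole run is reproducible.
Candidate cids are sorted before seeded sampling so set-iteration order never
leaks into results. Correctness of rule application is defined serially;
within a generation, applications are order-independent, so a partitioned
execution must merge to the identical network. Writers emit sorted rows,
RFC 4180 quoting, UTF-8, `\n` newlines — identical runs give byte-identical
CSV and JSON Lines artifacts.

Multi-"Any" rules enumerate ordered substrate tuples from the frontier,
capped by `max_assignments_per_rule` (default 10,000) with logged truncation,
to bound the combinatorics.

## Persistence

Four surfaces, all agreeing on counts: CSV (compounds, reactions with both
cid-equations and SMILES equations, operators, targets when given); JSON
Lines document collections with a schema-version header per file, losslessly
reloadable; SBML Level 3 Version 1 (one species per compound, one
irreversible reaction per network reaction — rules are directional — with
ids coerced into SId grammar and deterministic suffixing on collision);
and pickle with a schema-version guard that refuses mismatched or corrupted
files outright rather than returning a partial network.

## What the toy fixtures emulate — and what they do not

The fixture module generates four hand-audited, atom-balanced rule families
(alcohol oxidation with an O2/H2O2 couple, ester hydrolysis, hemiformal
chain elongation, carbonyl amination), a ≤C8 compound pool, and synthetic
peak lists with planted true peaks (optionally Gaussian-noised) plus uniform
decoys. Mapped-reaction metadata uses disjoint ID blocks of sizes
{10, 5, 3, 2} over 20 IDs so coverage arithmetic has exact expected values.
Everything is a pure function of a seed and regenerates byte-identically.

These fixtures exercise the engine's contracts — balance, identity, dedup,
filter semantics, round trips — on networks small enough to enumerate by
hand or brute force. They do not emulate real enzymatic rule statistics
(overlapping mapped sets, thousands of rules, multi-substrate operators),
crowded MS1 spectra, isotope envelopes, or the combinatorial blow-up of
database-scale expansions; passing tests therefore certify the machinery,
not biological coverage. Problem sizes used throughout the suite and the
acceptance script: 1–8 seeds, 1–4 rules, 1–3 generations, networks well
under 500 compounds, 20 randomized oracle configurations, 10,000 sampler
draws, 1,000 planted metabolomics instances (20 compounds × 50 replicate
peak lists).

## Known limitations

- No tautomer canonicalization; distinct tautomers get distinct IDs.
- Stereo-aware SMARTS semantics are untested (the loader merely retains
  stereo on request).
- The ΔG provider and feasibility predictor ship as interfaces with null
  reference implementations; filter behaviour with real estimators is bound
  by the contracts tested here, not by their accuracy.
- Frontier-only substrate assignment means a rule is never applied across
  generations (e.g., one reactant from generation 1 and another from
  generation 3); within the no-re-expansion policy this is the standard
  breadth-first semantics, but it is a modelling choice.
- The published 1224-rule file is consumed, not derived; its metadata checks
  require the file to be supplied at `data/JN1224MIN_rules.tsv`.
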