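# rulenet

Reaction-rule network expansion for biochemistry: predict the novel
compounds and reactions reachable from a seed metabolite set by iteratively
applying generalized enzymatic reaction rules (reaction SMARTS), with
composable on-the-fly filters to keep the combinatorial growth pointed at
what you actually care about.

Who it is for: metabolic engineers enumerating promiscuity-derived pathways
to a target chemical, and metabolomics researchers generating candidate
structures for unannotated m/z peaks.

## The method

Starting from generation-0 seed compounds, each generation applies every
selected rule to the current frontier. A rule is a reaction SMARTS plus role
tokens marking which reactant slots come from the network ("Any") and which
are fixed coreactants (water, O2, ...). Products are standardized
(neutralized, stereo-stripped, canonicalized); candidates are admitted only
if every structure is valid and the reaction is atom-balanced, hydrogens
included. Identity is content-hashed — compound IDs hash the InChIKey,
reaction IDs hash the normalized formula string — so networks deduplicate
exactly and independent runs agree.

Rules carry mapped-reaction metadata and are applied most-mapped-first, so a
prefix of the sorted ruleset is the best coverage-per-rule subset of its
size; subsets can be requested by rule count or by covered fraction.

Between generations a filter stack prunes the network:

| filter | phase | keeps |
|---|---|---|
| property | post-expansion | compounds inside MW / element-count windows |
| similarity cutoff | pre-expansion | frontier compounds with max Tanimoto ≥ cutoff to a target set |
| similarity sampling | pre-expansion | a fixed-size sample, weight ∝ score^k |
| metabolomics | post-expansion | compounds whose adduct m/z matches an observed peak within tolerance |
| thermodynamics | post-expansion | reactions with ΔG_r in [dg_min, dg_max] (unknown ΔG is kept) |
| feasibility | post-expansion | reactions whose principal substrate→product pair a classifier accepts |

Composition is survivor-set intersection, independent of same-phase order.
Runs are fully deterministic under a seed. Networks persist as CSV, JSON
Lines document collections, SBML L3V1, or a versioned binary blob — all
agreeing on counts. The target-efficiency statistic
`(T_i/C_i) / (T_ref/C_ref)` compares how many targets a run produces per
compound generated, relative to a reference run.

## Worked example

Generate the built-in toy fixtures (4 hand-audited rules, 5 seed compounds)
and expand two generations with a carbon-count filter:

```bash
rulenet fixtures --out-dir fx
cat > run.yaml <<'EOF'
rules: fx/toy_rules.tsv
coreactants: fx/toy_coreactants.tsv
seeds: fx/toy_seeds.csv
generations: 2
seed: 7
filters:
  - kind: property
    element_ranges:
      C: [0, 11]
EOF
rulenet run --config run.yaml --out-dir out
```

prints

```
compounds: 31
reactions: 25
{'generation': 1, 'frontier_in': 5, 'frontier_expanded': 5, 'new_compounds': 8, 'new_reactions': 8, 'rejected_invalid': 0, 'rejected_unbalanced': 0, 'filtered_property': 0, 'survivors': 8}
{'generation': 2, 'frontier_in': 8, 'frontier_expanded': 8, 'new_compounds': 13, 'new_reactions': 17, 'rejected_invalid': 0, 'rejected_unbalanced': 0, 'filtered_property': 0, 'survivors': 13}
```

Reading this: the 5 seeds (plus 5 fixed coreactants) grew by 8 novel
compounds and 8 reactions in generation 1, then 13 and 17 in generation 2 —
31 compounds and 25 reactions total. Nothing was rejected for validity or
balance, and no compound exceeded 11 carbons, so the filter removed nothing.
`out/` now holds the CSV tables, JSON Lines collections
(`documents/*.jsonl`), an SBML model, and a pickled network that can be
resumed or re-exported (`rulenet export out/network.pkl --format sbml ...`).

The same run through the library:

```python
from rulenet import (RunConfig, load_compounds_csv, load_ruleset,
                     run_expansion)

ruleset = load_ruleset("fx/toy_rules.tsv", "fx/toy_coreactants.tsv")
seeds = load_compounds_csv("fx/toy_seeds.csv")
net = run_expansion(seeds, ruleset, RunConfig(generations=2))
len(net.compounds), len(net.reactions)   # (31, 25)
```

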