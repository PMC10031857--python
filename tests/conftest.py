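"""Shared fixtures: toy rulesets/seed pools and an independent breadth-first
enumerator used as the oracle for the expansion engine.

The oracle deliberately bypasses the package's rule/expansion machinery: it
drives RDKit directly on canonical-SMILES sets and checks balance by explicit
hydrogen counting, so agreement with ``run_expansion`` is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List, Set, Tuple

import pytest
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from rulenet.chem_core import StandardizationConfig
from rulenet.fixtures import (
    TOY_COREACTANTS,
    TOY_RULES,
    FixtureSpec,
    toy_compound_pool,
    toy_ruleset,
)
from rulenet.io_formats import load_compounds_csv
from rulenet.rule_engine import load_ruleset

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def toy_rule_paths(fixture_dir):
    return toy_ruleset(FixtureSpec(), fixture_dir)


@pytest.fixture(scope="session")
def toy_rules(toy_rule_paths):
    rules_path, co_path = toy_rule_paths
    return load_ruleset(rules_path, co_path)


@pytest.fixture(scope="session")
def toy_seeds(fixture_dir):
    path = toy_compound_pool(FixtureSpec(), fixture_dir)
    return load_compounds_csv(path, StandardizationConfig())


def _canon(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _element_counts(smiles: str) -> Counter:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    return Counter(atom.GetSymbol() for atom in mol.GetAtoms())


ReactionSig = Tuple[Tuple[Tuple[str, int], ...], Tuple[Tuple[str, int], ...]]


def naive_enumerate(
    seed_smiles: List[str],
    rule_rows: List[Dict[str, str]],
    generations: int,
) -> Tuple[Set[str], Set[ReactionSig]]:
    """Brute-force breadth-first expansion over canonical SMILES.

    Returns the final compound SMILES set (coreactants included) and the set
    of reaction signatures ``(sorted (smiles, coeff) reactants, sorted
    (smiles, coeff) products)``.  Unbalanced candidates are discarded, as the
    engine contract requires.
    """
    coreactants = {name: _canon(s) for name, s in TOY_COREACTANTS.items()}
    cofactor_smiles = set(coreactants.values())
    compounds: Set[str] = {_canon(s) for s in seed_smiles} | cofactor_smiles
    frontier: Set[str] = {_canon(s) for s in seed_smiles} - cofactor_smiles
    reactions: Set[ReactionSig] = set()

    compiled = [
        (
            row["reactants"].split(";"),
            AllChem.ReactionFromSmarts(row["smarts"]),
        )
        for row in rule_rows
    ]

    for _ in range(generations):
        new: Set[str] = set()
        for roles, rxn in compiled:
            any_slots = [i for i, r in enumerate(roles) if r == "Any"]
            for sub in sorted(frontier):
                mols = []
                for i, role in enumerate(roles):
                    smi = sub if i in any_slots else coreactants[role]
                    mols.append(Chem.MolFromSmiles(smi))
                lhs = Counter(
                    sub if i in any_slots else coreactants[role]
                    for i, role in enumerate(roles)
                )
                for products in rxn.RunReactants(tuple(mols)):
                    try:
                        prod_smiles = []
                        for p in products:
                            Chem.SanitizeMol(p)
                            prod_smiles.append(_canon(Chem.MolToSmiles(p)))
                    except Exception:
                        continue
                    rhs = Counter(prod_smiles)
                    balance = Counter()
                    for smi, c in lhs.items():
                        for el, n in _element_counts(smi).items():
                            balance[el] -= c * n
                    for smi, c in rhs.items():
                        for el, n in _element_counts(smi).items():
                            balance[el] += c * n
                    if any(v != 0 for v in balance.values()):
                        continue
                    sig = (
                        tuple(sorted(lhs.items())),
                        tuple(sorted(rhs.items())),
                    )
                    if sig in reactions:
                        continue
                    reactions.add(sig)
                    for smi in prod_smiles:
                        if smi not in compounds:
                            new.add(smi)
        compounds |= new
        frontier = new - cofactor_smiles
        if not frontier:
            break
    return compounds, reactions


def network_signatures(network) -> Set[ReactionSig]:
    """Map a network's reactions onto oracle-style SMILES signatures."""
    sigs: Set[ReactionSig] = set()
    for rxn in network.reactions.values():
        lhs = tuple(sorted(
            (network.compounds[cid].smiles, c) for c, cid in rxn.reactants
        ))
        rhs = tuple(sorted(
            (network.compounds[cid].smiles, c) for c, cid in rxn.products
        ))
        sigs.add((lhs, rhs))
    return sigs
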