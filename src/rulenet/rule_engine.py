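"""Loading, subsetting, and applying SMARTS reaction rules.

A rule file is a TSV with one generalized reaction SMARTS per row plus
reactant/product role tokens and mapping metadata (how many curated reactions
the rule generalizes, optionally which ones, and associated UniProt IDs).
Rules are kept sorted by mapped-reaction count, most to fewest, so a prefix of
the sorted list is the highest-coverage subset of that size.  Role tokens name
either ``Any`` (a slot filled from the expandable network) or a coreactant
(water, NAD, ...) injected from a fixed table and never expanded itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_core import (
    Compound,
    Reaction,
    StandardizationConfig,
    check_atom_balance,
    reaction_id,
    standardize_compound,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionRule",
    "Ruleset",
    "RuleFormatError",
    "ApplyResult",
    "load_ruleset",
    "select_rules",
    "cumulative_coverage",
    "apply_rule",
]

ANY_ROLE = "Any"


class RuleFormatError(ValueError):
    """A rule or coreactant file violates the expected TSV dialect."""


@dataclass
class ReactionRule:
    rule_id: str
    smarts: str
    reactant_roles: Tuple[str, ...]
    product_roles: Tuple[str, ...]
    mapped_count: int = 0
    mapped_reaction_ids: Optional[FrozenSet[str]] = None
    uniprot_ids: Tuple[str, ...] = ()
    features: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        self._rxn = AllChem.ReactionFromSmarts(self.smarts)
        if self._rxn is None:
            raise RuleFormatError(f"rule {self.rule_id}: SMARTS does not compile")
        if self._rxn.GetNumReactantTemplates() != len(self.reactant_roles):
            raise RuleFormatError(
                f"rule {self.rule_id}: {len(self.reactant_roles)} reactant roles "
                f"but SMARTS has {self._rxn.GetNumReactantTemplates()} templates"
            )
        if self._rxn.GetNumProductTemplates() != len(self.product_roles):
            raise RuleFormatError(
                f"rule {self.rule_id}: {len(self.product_roles)} product roles "
                f"but SMARTS has {self._rxn.GetNumProductTemplates()} templates"
            )

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        return self._rxn

    @property
    def n_any_slots(self) -> int:
        return sum(1 for r in self.reactant_roles if r == ANY_ROLE)


@dataclass
class Ruleset:
    """Rules sorted by ``(-mapped_count, rule_id)`` plus the coreactant table.

    ``coverage_semantics`` records whether coverage is computed as the union of
    per-rule mapped-reaction ID sets (preferred, requires IDs on every rule) or
    as a normalized sum of mapped counts.
    """

    rules: List[ReactionRule]
    coreactants: Dict[str, Compound]
    total_mapped: int
    coverage_semantics: str = "id_union"

    def __post_init__(self) -> None:
        self.rules = sorted(self.rules, key=lambda r: (-r.mapped_count, r.rule_id))
        for rule in self.rules:
            for role in tuple(rule.reactant_roles) + tuple(rule.product_roles):
                if role != ANY_ROLE and role not in self.coreactants:
                    raise RuleFormatError(
                        f"rule {rule.rule_id}: coreactant {role!r} missing from table"
                    )

    def __len__(self) -> int:
        return len(self.rules)


_RULE_COLUMN_SYNONYMS = {
    "rule_id": ("rule_id", "name", "rule"),
    "reactants": ("reactants",),
    "smarts": ("smarts",),
    "products": ("products",),
    "mapped_count": ("mapped_count", "map_count", "counts"),
    "mapped_reaction_ids": ("mapped_reaction_ids", "reaction_ids", "reactions"),
    "uniprot_ids": ("uniprot_ids", "uniprot"),
    "features": ("features", "feature_flags"),
}


def _resolve_columns(df: pd.DataFrame, required: Sequence[str]) -> Dict[str, Optional[str]]:
    lower = {c.lower().strip(): c for c in df.columns}
    resolved: Dict[str, Optional[str]] = {}
    for canon, synonyms in _RULE_COLUMN_SYNONYMS.items():
        resolved[canon] = next((lower[s] for s in synonyms if s in lower), None)
    missing = [c for c in required if resolved[c] is None]
    if missing:
        raise RuleFormatError(f"rule file missing required column(s): {missing}")
    return resolved


def _split_tokens(value: object, sep: str = ";") -> Tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return ()
    return tuple(t.strip() for t in str(value).split(sep) if t.strip())


def load_ruleset(
    rules_path: str,
    coreactants_path: str,
    *,
    skip_bad_rules: bool = False,
    cfg: StandardizationConfig = StandardizationConfig(),
) -> Ruleset:
    """Read the rules TSV and coreactants TSV into a sorted :class:`Ruleset`.

    Malformed rows abort the load with row-numbered diagnostics unless
    ``skip_bad_rules`` is set, in which case they are dropped with a warning.
    """
    co_df = pd.read_csv(coreactants_path, sep="\t")
    co_cols = {c.lower().strip(): c for c in co_df.columns}
    if "name" not in co_cols or "smiles" not in co_cols:
        raise RuleFormatError("coreactant file needs 'name' and 'smiles' columns")
    coreactants: Dict[str, Compound] = {}
    for _, row in co_df.iterrows():
        name = str(row[co_cols["name"]]).strip()
        coreactants[name] = standardize_compound(
            str(row[co_cols["smiles"]]), cfg, source_id=name, is_cofactor=True
        )

    df = pd.read_csv(rules_path, sep="\t", dtype=str)
    cols = _resolve_columns(df, required=["rule_id", "reactants", "smarts", "products"])

    rules: List[ReactionRule] = []
    for idx, row in df.iterrows():
        try:
            ids_tok = (
                _split_tokens(row[cols["mapped_reaction_ids"]], "|")
                if cols["mapped_reaction_ids"]
                else ()
            )
            count_raw = row[cols["mapped_count"]] if cols["mapped_count"] else None
            if count_raw is None or (isinstance(count_raw, float) and pd.isna(count_raw)):
                mapped_count = len(ids_tok)
            else:
                mapped_count = int(count_raw)
            rules.append(
                ReactionRule(
                    rule_id=str(row[cols["rule_id"]]).strip(),
                    smarts=str(row[cols["smarts"]]).strip(),
                    reactant_roles=_split_tokens(row[cols["reactants"]]),
                    product_roles=_split_tokens(row[cols["products"]]),
                    mapped_count=mapped_count,
                    mapped_reaction_ids=frozenset(ids_tok) if ids_tok else None,
                    uniprot_ids=_split_tokens(row[cols["uniprot_ids"]], "|")
                    if cols["uniprot_ids"]
                    else (),
                    features=frozenset(
                        _split_tokens(row[cols["features"]], "|")
                        if cols["features"]
                        else ()
                    ),
                )
            )
        except (RuleFormatError, ValueError) as exc:
            msg = f"row {idx + 2}: {exc}"  # +2: header line and 1-based count
            if skip_bad_rules:
                logger.warning("skipping bad rule (%s)", msg)
            else:
                raise RuleFormatError(msg) from exc

    if rules and all(r.mapped_reaction_ids is not None for r in rules):
        total = len(frozenset().union(*(r.mapped_reaction_ids for r in rules)))
        semantics = "id_union"
    else:
        total = sum(r.mapped_count for r in rules)
        semantics = "count_sum"
    return Ruleset(rules=rules, coreactants=coreactants, total_mapped=total,
                   coverage_semantics=semantics)


def cumulative_coverage(ruleset: Ruleset, n: int) -> float:
    """Fraction of all mapped curated reactions covered by the first ``n`` rules."""
    if not 0 <= n <= len(ruleset.rules):
        raise ValueError(f"n={n} outside [0, {len(ruleset.rules)}]")
    if n == 0 or ruleset.total_mapped == 0:
        return 0.0
    prefix = ruleset.rules[:n]
    if ruleset.coverage_semantics == "id_union":
        covered = len(frozenset().union(*(r.mapped_reaction_ids for r in prefix)))
    else:
        covered = sum(r.mapped_count for r in prefix)
    return covered / ruleset.total_mapped


def select_rules(
    ruleset: Ruleset,
    *,
    count: Optional[int] = None,
    coverage_fraction: Optional[float] = None,
    include_features: Optional[Iterable[str]] = None,
    exclude_features: Optional[Iterable[str]] = None,
) -> Ruleset:
    """Subset a ruleset by prefix size, target coverage, and/or feature flags.

    ``count=n`` keeps the first ``n`` rules of the coverage-sorted list;
    ``coverage_fraction=f`` keeps the shortest prefix whose cumulative coverage
    reaches ``f`` (the two are mutually exclusive).  Feature criteria compose
    with either and are applied after the prefix is taken.
    """
    if count is not None and coverage_fraction is not None:
        raise ValueError("give at most one of count / coverage_fraction")
    rules = list(ruleset.rules)
    if coverage_fraction is not None:
        if not 0 <= coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in [0, 1]")
        n = next(
            (k for k in range(len(rules) + 1)
             if cumulative_coverage(ruleset, k) >= coverage_fraction),
            len(rules),
        )
        rules = rules[:n]
    elif count is not None:
        if count < 0:
            raise ValueError("count must be non-negative")
        if count > len(rules):
            logger.warning("count=%d exceeds %d rules; clamping", count, len(rules))
            count = len(rules)
        rules = rules[:count]
    if include_features:
        wanted = set(include_features)
        rules = [r for r in rules if wanted & r.features]
    if exclude_features:
        banned = set(exclude_features)
        rules = [r for r in rules if not banned & r.features]
    return replace(ruleset, rules=rules)


@dataclass
class ApplyResult:
    """Candidate reactions from one rule application plus their product pool."""

    reactions: Dict[str, Reaction] = field(default_factory=dict)
    compounds: Dict[str, Compound] = field(default_factory=dict)
    n_invalid: int = 0
    n_unbalanced: int = 0


def _mol_of(compound: Compound) -> Chem.Mol:
    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:  # standardized SMILES should always parse
        raise ValueError(f"stored SMILES unparseable for {compound.cid}")
    return mol


def apply_rule(
    rule: ReactionRule,
    substrate_assignment: Sequence[str],
    registry: Mapping[str, Compound],
    coreactants: Mapping[str, Compound],
    *,
    cfg: StandardizationConfig = StandardizationConfig(),
    generation: int = 0,
) -> ApplyResult:
    """Apply one rule to one ordered assignment of substrates.

    ``substrate_assignment`` gives a cid for each ``Any`` reactant slot, in
    order; named slots are auto-filled from the coreactant table.  Each
    distinct product multiset becomes one candidate reaction (symmetric site
    matches collapse after standardization); candidates with an invalid product
    structure or a nonzero element delta are dropped and counted.
    """
    if len(substrate_assignment) != rule.n_any_slots:
        raise ValueError(
            f"rule {rule.rule_id} has {rule.n_any_slots} Any slot(s), "
            f"got {len(substrate_assignment)} substrate(s)"
        )
    any_iter = iter(substrate_assignment)
    reactant_compounds: List[Compound] = []
    for role in rule.reactant_roles:
        if role == ANY_ROLE:
            reactant_compounds.append(registry[next(any_iter)])
        else:
            reactant_compounds.append(coreactants[role])
    reactant_mols = tuple(_mol_of(c) for c in reactant_compounds)

    result = ApplyResult()
    lhs: Dict[str, int] = {}
    for comp in reactant_compounds:
        lhs[comp.cid] = lhs.get(comp.cid, 0) + 1

    for product_mols in rule.rxn.RunReactants(reactant_mols):
        product_compounds: List[Compound] = []
        try:
            for pmol, role in zip(product_mols, rule.product_roles):
                smiles = Chem.MolToSmiles(pmol)
                comp = standardize_compound(smiles, cfg, generation=generation,
                                            is_cofactor=(role != ANY_ROLE))
                product_compounds.append(comp)
        except ValueError:
            result.n_invalid += 1
            continue
        rhs: Dict[str, int] = {}
        for comp in product_compounds:
            rhs[comp.cid] = rhs.get(comp.cid, 0) + 1
        reactants = [(c, cid) for cid, c in sorted(lhs.items())]
        products = [(c, cid) for cid, c in sorted(rhs.items())]
        rid = reaction_id(reactants, products)
        if rid in result.reactions:
            continue  # symmetric match, same product multiset
        rxn = Reaction(rid=rid, reactants=reactants, products=products,
                       operator_id=rule.rule_id, generation=generation)
        local = dict(registry)
        local.update(coreactants_by_cid(coreactants))
        for comp in product_compounds:
            local.setdefault(comp.cid, comp)
        report = check_atom_balance(rxn, local)
        if not report.balanced:
            logger.debug("rule %s unbalanced on %s: %s", rule.rule_id,
                         substrate_assignment, report.deltas)
            result.n_unbalanced += 1
            continue
        result.reactions[rid] = rxn
        for comp in product_compounds:
            result.compounds.setdefault(comp.cid, comp)
    return result


def coreactants_by_cid(coreactants: Mapping[str, Compound]) -> Dict[str, Compound]:
    return {c.cid: c for c in coreactants.values()}
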