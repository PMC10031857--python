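"""The generation loop: iterative rule application over an expandable frontier.

A run starts from a seed set (generation 0).  Each generation applies every
selected rule to every substrate assignment drawn from the frontier — the
compounds first seen in the previous generation that no filter flagged — and
merges the novel compounds and reactions into the network.  Pre-expansion
filters (similarity cutoff / sampling) decide which frontier compounds are
worth reacting; post-expansion filters (property, metabolomics,
thermodynamics, feasibility) prune what the generation just produced.
Compounds rediscovered in a later generation keep their original generation
tag and are never re-expanded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .chem_core import (
    Compound,
    Reaction,
    StandardizationConfig,
    check_atom_balance,
    standardize_compound,
)
from .filters import PRE_EXPANSION, POST_EXPANSION, BaseFilter, FilterStack
from .rule_engine import Ruleset, apply_rule, coreactants_by_cid

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "RunConfig",
    "GenerationDelta",
    "expand_generation",
    "run_expansion",
    "mark_targets",
]


@dataclass
class Network:
    """The growing compound/reaction registries plus per-generation audit logs."""

    compounds: Dict[str, Compound] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    operators_used: Dict[str, int] = field(default_factory=dict)
    generation_log: List[Dict[str, object]] = field(default_factory=list)
    targets_hit: Set[str] = field(default_factory=set)
    target_cids: Set[str] = field(default_factory=set)

    def validate(self) -> None:
        """Assert referential integrity: no reaction references a missing cid."""
        for rxn in self.reactions.values():
            for _, cid in rxn.reactants + rxn.products:
                if cid not in self.compounds:
                    raise AssertionError(
                        f"dangling cid {cid} referenced by {rxn.rid}"
                    )
        for comp in self.compounds.values():
            for rid in comp.reaction_ids:
                if rid not in self.reactions:
                    raise AssertionError(
                        f"dangling rid {rid} referenced by {comp.cid}"
                    )

    def non_cofactor_compounds(self) -> Dict[str, Compound]:
        return {c: comp for c, comp in self.compounds.items() if not comp.is_cofactor}


@dataclass
class RunConfig:
    """Parameters of one expansion run.

    ``max_assignments_per_rule`` bounds the combinatorics of rules with more
    than one network-supplied reactant slot; truncation is logged.  With a
    fixed ``seed`` the whole run, including sampling filters, is
    deterministic.
    """

    generations: int = 1
    standardization: StandardizationConfig = field(default_factory=StandardizationConfig)
    seed: int = 0
    prune_on_filter: bool = True
    max_assignments_per_rule: int = 10000

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class GenerationDelta:
    """What one generation added: novel compounds and reactions."""

    new_compounds: Dict[str, Compound] = field(default_factory=dict)
    new_reactions: Dict[str, Reaction] = field(default_factory=dict)
    n_invalid: int = 0
    n_unbalanced: int = 0


def _substrate_assignments(
    rule_n_slots: int, frontier: Sequence[str], cap: int
) -> Iterable[Tuple[str, ...]]:
    """Ordered tuples of frontier cids for the rule's Any slots, capped."""
    assignments = itertools.product(frontier, repeat=rule_n_slots)
    for i, assignment in enumerate(assignments):
        if i >= cap:
            logger.warning("assignment enumeration truncated at %d tuples", cap)
            return
        yield assignment


def expand_generation(
    network: Network,
    ruleset: Ruleset,
    frontier: Set[str],
    *,
    generation: int,
    cfg: RunConfig = RunConfig(),
) -> GenerationDelta:
    """Apply every rule to every substrate assignment over the frontier.

    Novel structures are tagged with the current generation; rediscovered
    compounds and reactions are not duplicated (content-hash identity), but
    reaction membership is updated on both sides.
    """
    missing = frontier - set(network.compounds)
    if missing:
        raise ValueError(f"frontier cids not in network: {sorted(missing)[:3]}")
    frontier_sorted = sorted(
        c for c in frontier if not network.compounds[c].is_cofactor
    )
    delta = GenerationDelta()
    for rule in ruleset.rules:
        if rule.n_any_slots == 0:
            continue
        for assignment in _substrate_assignments(
            rule.n_any_slots, frontier_sorted, cfg.max_assignments_per_rule
        ):
            result = apply_rule(
                rule,
                assignment,
                network.compounds,
                ruleset.coreactants,
                cfg=cfg.standardization,
                generation=generation,
            )
            delta.n_invalid += result.n_invalid
            delta.n_unbalanced += result.n_unbalanced
            for rid, rxn in result.reactions.items():
                if rid in network.reactions or rid in delta.new_reactions:
                    continue
                for cid, comp in result.compounds.items():
                    if cid not in network.compounds and cid not in delta.new_compounds:
                        delta.new_compounds[cid] = comp
                delta.new_reactions[rid] = rxn
    # merge: registries first, then membership, so lookups resolve
    network.compounds.update(delta.new_compounds)
    for rid, rxn in delta.new_reactions.items():
        network.reactions[rid] = rxn
        network.operators_used[rxn.operator_id] = (
            network.operators_used.get(rxn.operator_id, 0) + 1
        )
        for _, cid in rxn.reactants + rxn.products:
            network.compounds[cid].reaction_ids.add(rid)
    return delta


def _prune(network: Network, drop_cids: Set[str], drop_rids: Set[str]) -> None:
    """Remove flagged entities and any reaction left referencing a removed cid."""
    orphaned = {
        rid
        for rid, rxn in network.reactions.items()
        if any(cid in drop_cids for _, cid in rxn.reactants + rxn.products)
    }
    for rid in orphaned | (drop_rids & set(network.reactions)):
        rxn = network.reactions.pop(rid)
        n = network.operators_used.get(rxn.operator_id, 0) - 1
        if n > 0:
            network.operators_used[rxn.operator_id] = n
        else:
            network.operators_used.pop(rxn.operator_id, None)
        for _, cid in rxn.reactants + rxn.products:
            if cid in network.compounds:
                network.compounds[cid].reaction_ids.discard(rid)
    for cid in drop_cids:
        network.compounds.pop(cid, None)


def mark_targets(network: Network, targets: Iterable[Compound]) -> Set[str]:
    """Record which target structures the network has produced (cid equality)."""
    network.target_cids = {t.cid for t in targets}
    network.targets_hit = network.target_cids & set(network.compounds)
    return network.targets_hit


def run_expansion(
    seeds: Iterable[Compound],
    ruleset: Ruleset,
    cfg: RunConfig,
    filters: Optional[FilterStack] = None,
    targets: Optional[Sequence[Compound]] = None,
) -> Network:
    """Run the full generation loop with a filter stack.

    Per generation: pre-expansion filters thin the frontier, the frontier is
    expanded, post-expansion filters prune the newly produced compounds and
    reactions, and the survivors become the next frontier.  With
    ``prune_on_filter`` (the default) flagged entities are removed from the
    network together with orphaned reactions; otherwise they are merely kept
    out of the frontier.  A newly produced compound whose every producing
    reaction was pruned is removed with them.  The run ends early when the
    frontier empties.
    """
    filters = filters or FilterStack()
    network = Network()
    # private copies: the network owns its registry and mutates membership
    for comp in seeds:
        if comp.cid not in network.compounds:
            network.compounds[comp.cid] = replace(
                comp, generation=0, reaction_ids=set())
    for comp in ruleset.coreactants.values():
        network.compounds.setdefault(
            comp.cid, replace(comp, reaction_ids=set()))
    targets = list(targets or [])
    if targets:
        mark_targets(network, targets)

    frontier: Set[str] = set(network.non_cofactor_compounds())
    for g in range(1, cfg.generations + 1):
        log: Dict[str, object] = {"generation": g, "frontier_in": len(frontier)}
        flagged_pre: Set[str] = set()
        frontier_compounds = {c: network.compounds[c] for c in frontier}
        for f in filters.phase(PRE_EXPANSION):
            decision = f(frontier_compounds, {}, network.compounds)
            flagged_pre |= decision.flagged_compounds
            log[f"filtered_{f.name}"] = len(decision.flagged_compounds)
        frontier -= flagged_pre
        if cfg.prune_on_filter and flagged_pre:
            _prune(network, flagged_pre - network.targets_hit, set())
        log["frontier_expanded"] = len(frontier)
        if not frontier:
            log["note"] = "empty frontier; run ended early"
            network.generation_log.append(log)
            logger.info("generation %d: empty frontier, stopping", g)
            break

        delta = expand_generation(network, ruleset, frontier, generation=g, cfg=cfg)
        log["new_compounds"] = len(delta.new_compounds)
        log["new_reactions"] = len(delta.new_reactions)
        log["rejected_invalid"] = delta.n_invalid
        log["rejected_unbalanced"] = delta.n_unbalanced

        flagged_cids: Set[str] = set()
        flagged_rids: Set[str] = set()
        for f in filters.phase(POST_EXPANSION):
            decision = f(delta.new_compounds, delta.new_reactions, network.compounds)
            flagged_cids |= decision.flagged_compounds
            flagged_rids |= decision.flagged_reactions
            log[f"filtered_{f.name}"] = len(
                decision.flagged_compounds | decision.flagged_reactions
            )
        survivors = {
            c for c in delta.new_compounds if c not in flagged_cids
        }
        if cfg.prune_on_filter and (flagged_cids or flagged_rids):
            _prune(network, flagged_cids, flagged_rids)
            # a new compound whose every producing reaction was pruned goes too
            unsupported = {
                c
                for c in survivors
                if c in network.compounds
                and not (network.compounds[c].reaction_ids & set(network.reactions))
            }
            _prune(network, unsupported, set())
            survivors -= unsupported
        survivors &= set(network.compounds)
        if targets:
            mark_targets(network, targets)
        log["survivors"] = len(survivors)
        network.generation_log.append(log)
        frontier = survivors
        if not frontier:
            logger.info("generation %d: no survivors, stopping", g)
            break
    network.validate()
    return network
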