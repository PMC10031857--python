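"""Persistence surfaces: seed/target CSV input, CSV/JSON Lines/SBML output,
and full-fidelity binary serialization of a network.

All writers emit deterministic, byte-stable artifacts (sorted row order,
RFC 4180 CSV quoting, UTF-8, ``\\n`` newlines) so identical runs produce
identical files.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import pickle
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .chem_core import Compound, Reaction, StandardizationConfig, standardize_compound
from .expansion import Network

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SCHEMA_VERSION",
    "load_compounds_csv",
    "write_csv",
    "write_documents",
    "load_documents",
    "write_sbml",
    "serialize",
    "deserialize",
]

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """An input file violates the expected layout."""


def load_compounds_csv(
    path,
    cfg: StandardizationConfig = StandardizationConfig(),
    *,
    skip_bad: bool = False,
) -> List[Compound]:
    """Read a two-column ``id,smiles`` CSV into standardized compounds.

    Duplicate structures collapse to one compound; the first source id wins
    and later ones are logged.  Bad SMILES abort the load with per-row
    diagnostics unless ``skip_bad`` is set.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected an 'id,smiles' header")
        fields = {f.lower().strip(): f for f in reader.fieldnames}
        if "id" not in fields or "smiles" not in fields:
            raise FormatError(f"{path}: need 'id' and 'smiles' columns, "
                              f"got {reader.fieldnames}")
        compounds: Dict[str, Compound] = {}
        errors: List[str] = []
        n_rows = 0
        for i, row in enumerate(reader, start=2):
            n_rows += 1
            source_id = (row[fields["id"]] or "").strip()
            smiles = (row[fields["smiles"]] or "").strip()
            try:
                comp = standardize_compound(smiles, cfg, source_id=source_id)
            except ValueError as exc:
                msg = f"row {i}: {exc}"
                if skip_bad:
                    logger.warning("skipping compound (%s)", msg)
                    continue
                errors.append(msg)
                continue
            if comp.cid in compounds:
                logger.info("duplicate structure at row %d (%s); keeping id %r",
                            i, source_id, compounds[comp.cid].source_id)
                continue
            compounds[comp.cid] = comp
    if errors:
        raise FormatError(f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors))
    if n_rows == 0:
        logger.warning("%s: no compound rows (header only)", path)
    return list(compounds.values())


# --------------------------------------------------------------------------
# CSV output
# --------------------------------------------------------------------------

def _open_w(path: Path):
    return path.open("w", newline="", encoding="utf-8")


def _reaction_equation(rxn: Reaction) -> str:
    lhs = " + ".join(f"({c}) {cid}" for c, cid in rxn.reactants)
    rhs = " + ".join(f"({c}) {cid}" for c, cid in rxn.products)
    return f"{lhs} => {rhs}"


def _reaction_smiles_equation(rxn: Reaction, network: Network) -> str:
    def side(parts):
        return " + ".join(
            f"({c}) {network.compounds[cid].smiles}" for c, cid in parts
        )

    return f"{side(rxn.reactants)} => {side(rxn.products)}"


def write_csv(network: Network, out_dir) -> Dict[str, Path]:
    """Write compounds/reactions/operators(/targets) CSVs with sorted rows.

    ``targets.csv`` is only written when the run was given targets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    p = out_dir / "compounds.csv"
    with _open_w(p) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["cid", "smiles", "source_id", "generation", "is_cofactor",
                    "mono_mass", "formula", "n_reactions"])
        for cid in sorted(network.compounds):
            c = network.compounds[cid]
            w.writerow([c.cid, c.smiles, c.source_id, c.generation,
                        int(c.is_cofactor), f"{c.mono_mass:.6f}",
                        json.dumps(c.formula, sort_keys=True),
                        len(c.reaction_ids)])
    written["compounds"] = p

    p = out_dir / "reactions.csv"
    with _open_w(p) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["rid", "equation", "smiles_equation", "operator_id",
                    "generation"])
        for rid in sorted(network.reactions):
            r = network.reactions[rid]
            w.writerow([r.rid, _reaction_equation(r),
                        _reaction_smiles_equation(r, network),
                        r.operator_id, r.generation])
    written["reactions"] = p

    p = out_dir / "operators.csv"
    with _open_w(p) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["rule_id", "reactions_produced"])
        for rule_id in sorted(network.operators_used):
            w.writerow([rule_id, network.operators_used[rule_id]])
    written["operators"] = p

    if network.target_cids:
        p = out_dir / "targets.csv"
        with _open_w(p) as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["cid", "hit"])
            for cid in sorted(network.target_cids):
                w.writerow([cid, int(cid in network.targets_hit)])
        written["targets"] = p
    return written


# --------------------------------------------------------------------------
# JSON Lines document collections
# --------------------------------------------------------------------------

def _compound_doc(c: Compound) -> Dict[str, object]:
    return {
        "cid": c.cid,
        "smiles": c.smiles,
        "source_id": c.source_id,
        "generation": c.generation,
        "is_cofactor": c.is_cofactor,
        "mono_mass": round(c.mono_mass, 9),
        "formula": dict(sorted(c.formula.items())),
        "reaction_ids": sorted(c.reaction_ids),
    }


def _reaction_doc(r: Reaction) -> Dict[str, object]:
    return {
        "rid": r.rid,
        "reactants": [[c, cid] for c, cid in r.reactants],
        "products": [[c, cid] for c, cid in r.products],
        "operator_id": r.operator_id,
        "generation": r.generation,
    }


def write_documents(
    network: Network, out_dir, ruleset=None
) -> Dict[str, Path]:
    """Write the four document collections as JSON Lines (one object/line).

    Operator records carry the usage count and, when a ruleset is supplied,
    the mapped-reaction count and UniProt IDs.  Every file starts with a
    schema-version header object.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rules_by_id = {r.rule_id: r for r in (ruleset.rules if ruleset else [])}
    header = {"schema_version": SCHEMA_VERSION}
    written: Dict[str, Path] = {}

    def dump(name: str, docs: Iterable[Dict[str, object]]) -> None:
        p = out_dir / f"{name}.jsonl"
        with _open_w(p) as fh:
            fh.write(json.dumps({**header, "collection": name}, sort_keys=True) + "\n")
            for doc in docs:
                fh.write(json.dumps(doc, sort_keys=True) + "\n")
        written[name] = p

    dump("compounds", (_compound_doc(network.compounds[c])
                       for c in sorted(network.compounds)))
    dump("reactions", (_reaction_doc(network.reactions[r])
                       for r in sorted(network.reactions)))

    def operator_docs():
        for rule_id in sorted(network.operators_used):
            doc: Dict[str, object] = {
                "rule_id": rule_id,
                "reactions_produced": network.operators_used[rule_id],
            }
            rule = rules_by_id.get(rule_id)
            if rule is not None:
                doc["smarts"] = rule.smarts
                doc["mapped_count"] = rule.mapped_count
                doc["uniprot_ids"] = list(rule.uniprot_ids)
            yield doc

    dump("operators", operator_docs())
    dump("targets", ({"cid": cid, "hit": cid in network.targets_hit}
                     for cid in sorted(network.target_cids)))
    return written


def load_documents(in_dir) -> Network:
    """Rebuild a network from the JSON Lines collections written above."""
    in_dir = Path(in_dir)
    network = Network()

    def read(name: str):
        p = in_dir / f"{name}.jsonl"
        with p.open() as fh:
            header = json.loads(fh.readline())
            if header.get("schema_version") != SCHEMA_VERSION:
                raise FormatError(
                    f"{p}: schema version {header.get('schema_version')} "
                    f"!= {SCHEMA_VERSION}"
                )
            for line in fh:
                yield json.loads(line)

    for doc in read("compounds"):
        network.compounds[doc["cid"]] = Compound(
            cid=doc["cid"],
            smiles=doc["smiles"],
            source_id=doc["source_id"],
            generation=doc["generation"],
            reaction_ids=set(doc["reaction_ids"]),
            is_cofactor=doc["is_cofactor"],
            mono_mass=doc["mono_mass"],
            formula={k: int(v) for k, v in doc["formula"].items()},
        )
    for doc in read("reactions"):
        network.reactions[doc["rid"]] = Reaction(
            rid=doc["rid"],
            reactants=[(int(c), cid) for c, cid in doc["reactants"]],
            products=[(int(c), cid) for c, cid in doc["products"]],
            operator_id=doc["operator_id"],
            generation=doc["generation"],
        )
        op = network.reactions[doc["rid"]].operator_id
        network.operators_used[op] = network.operators_used.get(op, 0)
    for doc in read("operators"):
        network.operators_used[doc["rule_id"]] = doc["reactions_produced"]
    for doc in read("targets"):
        network.target_cids.add(doc["cid"])
        if doc["hit"]:
            network.targets_hit.add(doc["cid"])
    network.validate()
    return network


# --------------------------------------------------------------------------
# SBML
# --------------------------------------------------------------------------

def _sanitize_sid(raw: str, taken: Set[str]) -> str:
    """Coerce an id into SBML SId grammar, deterministically de-colliding."""
    sid = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "x_" + sid
    base, i = sid, 1
    while sid in taken:
        i += 1
        sid = f"{base}_{i}"
        logger.info("SBML id collision for %r; using %r", raw, sid)
    taken.add(sid)
    return sid


def write_sbml(network: Network, path) -> None:
    """Write the network as an SBML Level 3 Version 1 model.

    One species per compound (cid kept in the species name and annotation-safe
    sanitized SId), one irreversible reaction per network reaction with
    stoichiometries.  The document is checked for internal consistency before
    writing.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("rulenet_network")
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    taken: Set[str] = {"cell", "rulenet_network"}
    sid_of: Dict[str, str] = {}
    for cid in sorted(network.compounds):
        c = network.compounds[cid]
        sid = _sanitize_sid(cid, taken)
        sid_of[cid] = sid
        sp = model.createSpecies()
        sp.setId(sid)
        sp.setName(c.smiles)
        sp.setMetaId(f"meta_{sid}")
        sp.setCompartment("cell")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for rid in sorted(network.reactions):
        r = network.reactions[rid]
        sid = _sanitize_sid(rid, taken)
        rxn = model.createReaction()
        rxn.setId(sid)
        rxn.setReversible(False)
        rxn.setFast(False)
        for coeff, cid in r.reactants:
            ref = rxn.createReactant()
            ref.setSpecies(sid_of[cid])
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for coeff, cid in r.products:
            ref = rxn.createProduct()
            ref.setSpecies(sid_of[cid])
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)

    doc.checkInternalConsistency()
    n_errors = doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR)
    if n_errors:
        raise FormatError(
            f"SBML document has {n_errors} consistency error(s): "
            + doc.getErrorLog().toString()
        )
    libsbml.writeSBMLToFile(doc, str(path))


# --------------------------------------------------------------------------
# binary serialization
# --------------------------------------------------------------------------

def serialize(network: Network, path) -> None:
    """Pickle the full network (registries, logs, audit trail) with a
    schema-version guard."""
    payload = {"schema_version": SCHEMA_VERSION, "network": network}
    with Path(path).open("wb") as fh:
        pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)


def deserialize(path) -> Network:
    """Inverse of :func:`serialize`; refuses version mismatches and
    corrupted files without returning a partial network."""
    try:
        with Path(path).open("rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise FormatError(f"{path}: not a valid serialized network ({exc})") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise FormatError(f"{path}: missing schema version header")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: schema version {payload['schema_version']} != {SCHEMA_VERSION}"
        )
    network = payload["network"]
    network.validate()
    return network
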