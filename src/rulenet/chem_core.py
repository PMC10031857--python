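"""Structure standardization, identity hashing, and atom-balance checks.

Every compound entering a network passes through :func:`standardize_compound`,
which canonicalizes the SMILES, optionally neutralizes formal charges and
strips stereochemistry, and attaches a formula and monoisotopic mass computed
from a pinned element-mass table.  Identities are content hashes: compound IDs
hash the InChIKey (so any SMILES spelling of a structure maps to one ID across
runs and processes) and reaction IDs hash a normalized reaction formula
string.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "Reaction",
    "StandardizationConfig",
    "BalanceReport",
    "SmilesParseError",
    "ValidityError",
    "IdentityError",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "standardize_compound",
    "compound_id",
    "reaction_id",
    "check_atom_balance",
    "formula_of_mol",
    "monoisotopic_mass",
]


def _load_mass_table() -> Dict[str, float]:
    with resources.files("rulenet.data").joinpath("monoisotopic_masses.csv").open() as fh:
        return {row["element"]: float(row["mass"]) for row in csv.DictReader(fh)}


#: Pinned monoisotopic masses (Da) used for every mass computation in the package.
MONOISOTOPIC_MASS: Dict[str, float] = _load_mass_table()

#: Mass of a proton (Da), used for adduct m/z arithmetic.
PROTON_MASS: float = 1.007276466


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed. Carries the offending string."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


class ValidityError(ValueError):
    """A parsed structure failed sanitization (e.g. illegal valence)."""

    def __init__(self, smiles: str, reason: str):
        self.smiles = smiles
        super().__init__(f"invalid structure {smiles!r}: {reason}")


class IdentityError(ValueError):
    """InChIKey generation failed; the compound cannot receive a stable ID."""


@dataclass(frozen=True)
class StandardizationConfig:
    """How incoming structures are normalized.

    Defaults neutralize charges and remove stereochemistry; the shipped rule
    format is stereo-free, but ``strip_stereo=False`` retains stereo for
    user-defined stereo-aware rules.
    """

    neutralize: bool = True
    strip_stereo: bool = True


@dataclass
class Compound:
    """A standardized structure with a run-stable content-derived ID."""

    cid: str
    smiles: str
    source_id: str = ""
    generation: int = 0
    reaction_ids: Set[str] = field(default_factory=set)
    is_cofactor: bool = False
    mono_mass: float = 0.0
    formula: Dict[str, int] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Compound) and self.cid == other.cid

    def __hash__(self) -> int:
        return hash(self.cid)


@dataclass
class Reaction:
    """A stoichiometric reaction with operator provenance.

    ``reactants`` and ``products`` are lists of ``(coefficient, cid)`` with
    positive integer coefficients.
    """

    rid: str
    reactants: List[Tuple[int, str]]
    products: List[Tuple[int, str]]
    operator_id: str
    generation: int = 0


@dataclass(frozen=True)
class BalanceReport:
    balanced: bool
    deltas: Mapping[str, int]  # element -> products minus reactants


_UNCHARGER = rdMolStandardize.Uncharger()


def _parse_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(smiles)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitization subclasses
        raise ValidityError(smiles, str(exc)) from exc
    return mol


def formula_of_mol(mol: Chem.Mol) -> Dict[str, int]:
    """Element -> count map with implicit hydrogens expanded."""
    counts: Counter[str] = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    if counts["H"] == 0:
        del counts["H"]
    return dict(counts)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Sum of pinned monoisotopic element masses over a formula."""
    try:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:
        raise ValidityError(str(dict(formula)), f"no pinned mass for element {exc}") from exc


def standardize_compound(
    smiles: str,
    cfg: StandardizationConfig = StandardizationConfig(),
    *,
    source_id: str = "",
    generation: int = 0,
    is_cofactor: bool = False,
) -> Compound:
    """Parse, neutralize, strip stereo, canonicalize; populate formula and mass.

    Multi-fragment SMILES (``A.B``) are rejected: a seed row must describe one
    molecule.  Charged centers with no valence-legal neutral form (quaternary
    nitrogen) are kept charged with a log warning.
    """
    mol = _parse_smiles(smiles)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValidityError(smiles, "multi-fragment SMILES not allowed")
    if cfg.neutralize:
        mol = _UNCHARGER.uncharge(mol)
        if Chem.GetFormalCharge(mol) != 0:
            logger.warning("could not fully neutralize %r (net charge %d)",
                           smiles, Chem.GetFormalCharge(mol))
    if cfg.strip_stereo:
        Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol)
    formula = formula_of_mol(mol)
    comp = Compound(
        cid="",
        smiles=canonical,
        source_id=source_id,
        generation=generation,
        is_cofactor=is_cofactor,
        mono_mass=monoisotopic_mass(formula),
        formula=formula,
    )
    comp.cid = compound_id(comp)
    return comp


def compound_id(compound: Compound) -> str:
    """``"C" + SHA-1(InChIKey)`` — stable across processes and SMILES spellings."""
    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        raise IdentityError(f"stored SMILES no longer parses: {compound.smiles!r}")
    inchikey = Chem.MolToInchiKey(mol)
    if not inchikey:
        raise IdentityError(f"InChIKey generation failed for {compound.smiles!r}")
    return "C" + hashlib.sha1(inchikey.encode("utf-8")).hexdigest()


def _formula_string(side: Sequence[Tuple[int, str]]) -> str:
    return " + ".join(f"({c}) {cid}" for c, cid in sorted(side, key=lambda p: (p[1], p[0])))


def reaction_id(
    reactants: Sequence[Tuple[int, str]], products: Sequence[Tuple[int, str]]
) -> str:
    """``"R" + SHA-1`` of the normalized reaction-formula string.

    Participant order within a side is irrelevant (sides are sorted by cid);
    swapping the two sides changes the ID, so direction is encoded.
    """
    if not reactants or not products:
        raise ValueError("reaction must have non-empty reactant and product sides")
    for coeff, _ in list(reactants) + list(products):
        if coeff < 1:
            raise ValueError("stoichiometric coefficients must be >= 1")
    formula = _formula_string(reactants) + " => " + _formula_string(products)
    return "R" + hashlib.sha1(formula.encode("utf-8")).hexdigest()


def check_atom_balance(
    reaction: Reaction, registry: Mapping[str, Compound]
) -> BalanceReport:
    """Compare element multisets (hydrogen included) of the two sides."""
    deltas: Counter[str] = Counter()
    for sign, side in ((-1, reaction.reactants), (+1, reaction.products)):
        for coeff, cid in side:
            try:
                comp = registry[cid]
            except KeyError:
                raise KeyError(f"unresolvable compound id {cid!r} in {reaction.rid}")
            for el, n in comp.formula.items():
                deltas[el] += sign * coeff * n
    deltas = Counter({el: d for el, d in deltas.items() if d != 0})
    return BalanceReport(balanced=not deltas, deltas=dict(deltas))
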