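"""Deterministic toy fixtures: small rulesets, compound pools, and synthetic
m/z peak lists.

Every generator is a pure function of its :class:`FixtureSpec` (and seed), so
fixture files are byte-identical across regenerations and golden files never
need hand edits.  The toy SMARTS are intentionally unambiguous — single-match
on the test substrates except for deliberately symmetric sites — so expected
networks are hand-enumerable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem_core import Compound
from .filters import AdductSpec, default_adducts
from .rule_engine import Ruleset, load_ruleset

__all__ = [
    "FixtureSpec",
    "TOY_RULES",
    "TOY_COREACTANTS",
    "toy_ruleset",
    "toy_compound_pool",
    "synthetic_peaklist",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the toy fixture generators.

    ``planted_fraction`` of the compound pool gets a true peak in the
    synthetic peak list (with Gaussian m/z noise of ``noise_sigma`` Da);
    ``n_decoys`` unrelated peaks are drawn uniformly over the observed range.
    """

    seed: int = 7
    n_compounds: int = 5
    rule_families: Tuple[str, ...] = (
        "oxidation",
        "hydrolysis",
        "chain_elongation",
        "amination",
    )
    planted_fraction: float = 0.5
    n_decoys: int = 10
    noise_sigma: float = 0.0


#: name -> canonical SMILES of the toy coreactant pool
TOY_COREACTANTS: Dict[str, str] = {
    "WATER": "O",
    "OXYGEN": "O=O",
    "PEROXIDE": "OO",
    "AMMONIA": "N",
    "FORMALDEHYDE": "C=O",
}

# Hand-audited, atom-balanced toy rules.  Mapped-reaction ID sets are
# disjoint blocks of sizes {10, 5, 3, 2} over 20 IDs so coverage arithmetic
# has easily enumerable expected values and the sort order is total.
TOY_RULES: List[Dict[str, str]] = [
    {
        "rule_id": "tox01",
        "family": "oxidation",
        "reactants": "Any;OXYGEN",
        "smarts": "[C;H2:1][O;H1:2].[O;H0:3]=[O;H0:4]>>[C;H1:1]=[O:2].[O;H1:3][O;H1:4]",
        "products": "Any;PEROXIDE",
        "mapped_reaction_ids": "|".join(f"M{i:02d}" for i in range(1, 11)),
        "uniprot_ids": "P00001|P00002",
        "features": "oxygen_dependent",
    },
    {
        "rule_id": "thy01",
        "family": "hydrolysis",
        "reactants": "Any;WATER",
        "smarts": "[C:1](=[O:2])[O:3][C:4].[O;H2:5]>>[C:1](=[O:2])[O;H1:5].[C:4][O;H1:3]",
        "products": "Any;Any",
        "mapped_reaction_ids": "|".join(f"M{i:02d}" for i in range(11, 16)),
        "uniprot_ids": "P00003",
        "features": "hydrolytic",
    },
    {
        "rule_id": "tce01",
        "family": "chain_elongation",
        "reactants": "Any;FORMALDEHYDE",
        "smarts": "[C:1][O;H1:2].[C;H2:3]=[O:4]>>[C:1][O:2][C;H2:3][O;H1:4]",
        "products": "Any",
        "mapped_reaction_ids": "|".join(f"M{i:02d}" for i in range(16, 19)),
        "uniprot_ids": "",
        "features": "",
    },
    {
        "rule_id": "tam01",
        "family": "amination",
        "reactants": "Any;AMMONIA",
        "smarts": "[C:1]=[O:2].[N;H3:3]>>[C:1]=[N;H1:3].[O;H2:2]",
        "products": "Any;WATER",
        "mapped_reaction_ids": "M19|M20",
        "uniprot_ids": "P00004",
        "features": "nitrogen_addition",
    },
]


def toy_ruleset(
    spec: FixtureSpec, out_dir
) -> Tuple[Path, Path]:
    """Write the toy rules and coreactants TSVs; returns their paths.

    Only families named in ``spec.rule_families`` are emitted; at least one
    must be selected.
    """
    families = set(spec.rule_families)
    if not families:
        raise ValueError("select at least one rule family")
    unknown = families - {r["family"] for r in TOY_RULES}
    if unknown:
        raise ValueError(f"unknown rule families: {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rules_path = out_dir / "toy_rules.tsv"
    co_path = out_dir / "toy_coreactants.tsv"

    columns = ["rule_id", "reactants", "smarts", "products",
               "mapped_count", "mapped_reaction_ids", "uniprot_ids", "features"]
    with rules_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for rule in TOY_RULES:
            if rule["family"] not in families:
                continue
            ids = rule["mapped_reaction_ids"]
            w.writerow([
                rule["rule_id"], rule["reactants"], rule["smarts"],
                rule["products"], len(ids.split("|")) if ids else 0,
                ids, rule["uniprot_ids"], rule["features"],
            ])
    with co_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "smiles"])
        for name in sorted(TOY_COREACTANTS):
            w.writerow([name, TOY_COREACTANTS[name]])
    return rules_path, co_path


def toy_ruleset_loaded(spec: FixtureSpec, out_dir) -> Ruleset:
    """Convenience: write the toy TSVs and load them back."""
    rules_path, co_path = toy_ruleset(spec, out_dir)
    return load_ruleset(rules_path, co_path)


# Small aliphatic/aromatic molecules (<= C8) with well-known formulas.
_POOL_CANDIDATES: List[Tuple[str, str]] = [
    ("ethanol", "CCO"),
    ("propan-1-ol", "CCCO"),
    ("butan-1-ol", "CCCCO"),
    ("methanol", "CO"),
    ("acetic_acid", "CC(=O)O"),
    ("propionic_acid", "CCC(=O)O"),
    ("ethyl_acetate", "CCOC(C)=O"),
    ("methyl_formate", "COC=O"),
    ("acetaldehyde", "CC=O"),
    ("propanal", "CCC=O"),
    ("acetone", "CC(C)=O"),
    ("glycine", "NCC(=O)O"),
    ("alanine", "CC(N)C(=O)O"),
    ("glycerol", "OCC(O)CO"),
    ("phenol", "Oc1ccccc1"),
    ("benzaldehyde", "O=Cc1ccccc1"),
    ("pyruvic_acid", "CC(=O)C(=O)O"),
    ("ethylene_glycol", "OCCO"),
    ("lactic_acid", "CC(O)C(=O)O"),
    ("butanone", "CCC(C)=O"),
]


def toy_compound_pool(spec: FixtureSpec, out_dir) -> Path:
    """Write an ``id,smiles`` seed CSV of ``n_compounds`` molecules.

    Membership and order are a deterministic function of the seed.
    """
    if not 1 <= spec.n_compounds <= len(_POOL_CANDIDATES):
        raise ValueError(
            f"n_compounds must be in [1, {len(_POOL_CANDIDATES)}]"
        )
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(_POOL_CANDIDATES), size=spec.n_compounds, replace=False)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "toy_seeds.csv"
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["id", "smiles"])
        for i in sorted(idx):
            w.writerow(_POOL_CANDIDATES[i])
    return path


def synthetic_peaklist(
    compounds: Sequence[Compound],
    spec: FixtureSpec,
    out_dir,
    adducts: Optional[Sequence[AdductSpec]] = None,
) -> Tuple[Path, List[Tuple[float, str, str]]]:
    """Plant true peaks for a fraction of the compounds and add decoys.

    Each planted compound gets one peak at its m/z under a randomly chosen
    adduct plus ``N(0, noise_sigma)`` Da of noise; ``n_decoys`` peaks are
    drawn uniformly over the observed m/z range (padded by 10 Da when only
    decoys are requested).  Returns the peak-file path and the ground truth
    as ``(peak m/z, cid, adduct name)`` rows.
    """
    adducts = list(adducts) if adducts is not None else default_adducts()
    if not adducts:
        raise ValueError("adduct table must be non-empty")
    pool = sorted(
        (c for c in compounds if not c.is_cofactor), key=lambda c: c.cid
    )
    rng = np.random.default_rng(spec.seed)
    n_planted = int(round(spec.planted_fraction * len(pool)))
    planted_idx = rng.choice(len(pool), size=n_planted, replace=False) if pool else []

    truth: List[Tuple[float, str, str]] = []
    peaks: List[float] = []
    for i in sorted(planted_idx):
        comp = pool[i]
        adduct = adducts[rng.integers(len(adducts))]
        mz = adduct.mz(comp.mono_mass) + rng.normal(0.0, spec.noise_sigma)
        peaks.append(mz)
        truth.append((mz, comp.cid, adduct.name))

    if peaks:
        lo, hi = min(peaks), max(peaks)
        if lo == hi:
            lo, hi = lo - 10.0, hi + 10.0
    else:
        lo, hi = 50.0, 500.0
    peaks.extend(float(x) for x in rng.uniform(lo, hi, size=spec.n_decoys))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "toy_peaks.txt"
    with path.open("w", encoding="utf-8") as fh:
        for mz in peaks:
            fh.write(f"{mz:.6f}\n")
    return path, truth
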