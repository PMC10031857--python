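"""On-the-fly network pruning: property, similarity, metabolomics,
thermodynamics, and feasibility filters, plus the target-efficiency statistic.

Filters are composable predicates with a declared phase.  Pre-expansion
filters (the two similarity filters) decide which frontier compounds are
worth reacting before a generation is expanded; post-expansion filters
(property, metabolomics, thermodynamics, feasibility) prune the compounds and
reactions a generation just produced.  Composing filters keeps the
intersection of each filter's survivors, so same-phase order never changes
the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import (
    Callable,
    Dict,
    Iterable,
    List,
    Mapping,
    Optional,
    Protocol,
    Sequence,
    Set,
    Tuple,
)

import numpy as np
from rdkit import Chem, DataStructs

from .chem_core import Compound, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "PRE_EXPANSION",
    "POST_EXPANSION",
    "FilterDecision",
    "BaseFilter",
    "FilterStack",
    "CompoundPropertyFilterConfig",
    "PropertyFilter",
    "FingerprintConfig",
    "SimilarityCutoffFilter",
    "SimilaritySampleFilter",
    "AdductSpec",
    "MetabolomicsFilterConfig",
    "MetabolomicsFilter",
    "ThermoConditions",
    "ThermodynamicsFilter",
    "NullDGProvider",
    "ConstantDGProvider",
    "FeasibilityFilter",
    "AlwaysFeasiblePredictor",
    "DenyListPredictor",
    "EfficiencyRecord",
    "property_filter",
    "max_similarity_scores",
    "similarity_cutoff_filter",
    "similarity_sample_filter",
    "mz_candidates",
    "metabolomics_filter",
    "thermodynamics_filter",
    "feasibility_filter",
    "target_efficiency",
    "load_adducts_csv",
    "default_adducts",
]

PRE_EXPANSION = "pre_expansion"
POST_EXPANSION = "post_expansion"


@dataclass
class FilterDecision:
    """What one filter wants removed (cids / rids) from the set it examined."""

    flagged_compounds: Set[str] = field(default_factory=set)
    flagged_reactions: Set[str] = field(default_factory=set)


class BaseFilter:
    """A pluggable predicate with a declared phase and audit counters."""

    name: str = "base"
    phase: str = POST_EXPANSION

    def __init__(self) -> None:
        self.total_flagged_compounds = 0
        self.total_flagged_reactions = 0

    def examine(
        self,
        compounds: Mapping[str, Compound],
        reactions: Mapping[str, Reaction],
        registry: Mapping[str, Compound],
    ) -> FilterDecision:
        raise NotImplementedError

    def __call__(self, compounds, reactions, registry) -> FilterDecision:
        decision = self.examine(compounds, reactions, registry)
        self.total_flagged_compounds += len(decision.flagged_compounds)
        self.total_flagged_reactions += len(decision.flagged_reactions)
        return decision


class FilterStack:
    """An ordered, composable stack of filters, split by phase on demand."""

    def __init__(self, filters: Sequence[BaseFilter] = ()):
        self.filters: List[BaseFilter] = list(filters)

    def append(self, f: BaseFilter) -> "FilterStack":
        self.filters.append(f)
        return self

    def phase(self, phase: str) -> List[BaseFilter]:
        return [f for f in self.filters if f.phase == phase]

    def __iter__(self):
        return iter(self.filters)

    def __len__(self) -> int:
        return len(self.filters)


# --------------------------------------------------------------------------
# compound property filter
# --------------------------------------------------------------------------

@dataclass
class CompoundPropertyFilterConfig:
    """Molecular-weight window and per-element count windows (Da, counts)."""

    mw_min: Optional[float] = None
    mw_max: Optional[float] = None
    element_ranges: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    exempt_cofactors: bool = True

    def __post_init__(self) -> None:
        if self.mw_min is not None and self.mw_max is not None:
            if self.mw_min > self.mw_max:
                raise ValueError("mw_min > mw_max")
        for el, (lo, hi) in self.element_ranges.items():
            if lo > hi:
                raise ValueError(f"element range for {el}: min > max")


def property_filter(
    compounds: Iterable[Compound], cfg: CompoundPropertyFilterConfig
) -> Set[str]:
    """Flag compounds outside the MW window or any element-count window.

    Cofactors are exempt when configured (the windows constrain the chemistry
    being explored, not the fixed coreactant pool).
    """
    flagged: Set[str] = set()
    for comp in compounds:
        if cfg.exempt_cofactors and comp.is_cofactor:
            continue
        if cfg.mw_min is not None and comp.mono_mass < cfg.mw_min:
            flagged.add(comp.cid)
            continue
        if cfg.mw_max is not None and comp.mono_mass > cfg.mw_max:
            flagged.add(comp.cid)
            continue
        for el, (lo, hi) in cfg.element_ranges.items():
            if not lo <= comp.formula.get(el, 0) <= hi:
                flagged.add(comp.cid)
                break
    return flagged


class PropertyFilter(BaseFilter):
    name = "property"
    phase = POST_EXPANSION

    def __init__(self, cfg: CompoundPropertyFilterConfig):
        super().__init__()
        self.cfg = cfg

    def examine(self, compounds, reactions, registry) -> FilterDecision:
        return FilterDecision(
            flagged_compounds=property_filter(compounds.values(), self.cfg)
        )


# --------------------------------------------------------------------------
# similarity filters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintConfig:
    """Path-based bit fingerprint parameters (pinned in run metadata)."""

    kind: str = "rdkit"
    n_bits: int = 2048


def _fingerprint(smiles: str, cfg: FingerprintConfig):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot fingerprint unparseable SMILES {smiles!r}")
    if cfg.kind != "rdkit":
        raise ValueError(f"unknown fingerprint kind {cfg.kind!r}")
    return Chem.RDKFingerprint(mol, fpSize=cfg.n_bits)


def max_similarity_scores(
    frontier: Iterable[Compound],
    targets: Sequence[Compound],
    fp_cfg: FingerprintConfig = FingerprintConfig(),
) -> Dict[str, float]:
    """Per-compound maximum Tanimoto similarity against the target set."""
    targets = list(targets)
    if not targets:
        raise ValueError("similarity scoring requires at least one target")
    target_fps = [_fingerprint(t.smiles, fp_cfg) for t in targets]
    scores: Dict[str, float] = {}
    for comp in frontier:
        fp = _fingerprint(comp.smiles, fp_cfg)
        scores[comp.cid] = max(
            DataStructs.TanimotoSimilarity(fp, tfp) for tfp in target_fps
        )
    return scores


def similarity_cutoff_filter(
    scores: Mapping[str, float],
    cutoff: float,
    *,
    exempt: Iterable[str] = (),
) -> Set[str]:
    """Flag compounds whose maximum similarity is strictly below the cutoff.

    Score equal to the cutoff survives; ``exempt`` cids (reached targets) are
    never flagged.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    exempt = set(exempt)
    return {cid for cid, s in scores.items() if s < cutoff and cid not in exempt}


def similarity_sample_filter(
    scores: Mapping[str, float],
    n: int,
    k: float,
    seed: int,
) -> Set[str]:
    """Keep ``min(n, |pool|)`` compounds sampled without replacement with
    weight proportional to ``score**k`` (``k=0`` is uniform)."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if k < 0:
        raise ValueError("weight power must be >= 0")
    cids = sorted(scores)  # deterministic order before seeding
    if n >= len(cids):
        return set(cids)
    weights = np.array([scores[c] for c in cids], dtype=float) ** k
    total = weights.sum()
    if total <= 0:
        logger.warning("all sampling weights zero; falling back to uniform")
        weights = np.ones(len(cids))
        total = weights.sum()
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(cids), size=n, replace=False, p=weights / total)
    return {cids[i] for i in picked}


class SimilarityCutoffFilter(BaseFilter):
    """Pre-expansion: drop frontier compounds dissimilar to every target."""

    name = "similarity_cutoff"
    phase = PRE_EXPANSION

    def __init__(
        self,
        targets: Sequence[Compound],
        cutoff: float,
        fp_cfg: FingerprintConfig = FingerprintConfig(),
    ):
        super().__init__()
        if not targets:
            raise ValueError("similarity filter requires a non-empty target set")
        if not 0 <= cutoff <= 1:
            raise ValueError("cutoff must be in [0, 1]")
        self.targets = list(targets)
        self.target_cids = {t.cid for t in targets}
        self.cutoff = cutoff
        self.fp_cfg = fp_cfg

    def examine(self, compounds, reactions, registry) -> FilterDecision:
        pool = {c: comp for c, comp in compounds.items() if not comp.is_cofactor}
        scores = max_similarity_scores(pool.values(), self.targets, self.fp_cfg)
        flagged = similarity_cutoff_filter(scores, self.cutoff,
                                           exempt=self.target_cids)
        return FilterDecision(flagged_compounds=flagged)


class SimilaritySampleFilter(BaseFilter):
    """Pre-expansion: keep a fixed-size sample weighted by similarity^k."""

    name = "similarity_sample"
    phase = PRE_EXPANSION

    def __init__(
        self,
        targets: Sequence[Compound],
        sample_size: int,
        weight_power: float,
        seed: int,
        fp_cfg: FingerprintConfig = FingerprintConfig(),
    ):
        super().__init__()
        if not targets:
            raise ValueError("similarity filter requires a non-empty target set")
        self.targets = list(targets)
        self.sample_size = sample_size
        self.weight_power = weight_power
        self.seed = seed
        self.fp_cfg = fp_cfg
        self._call_count = 0

    def examine(self, compounds, reactions, registry) -> FilterDecision:
        pool = {c: comp for c, comp in compounds.items() if not comp.is_cofactor}
        if not pool:
            return FilterDecision()
        scores = max_similarity_scores(pool.values(), self.targets, self.fp_cfg)
        # vary the stream per invocation but stay deterministic under the seed
        kept = similarity_sample_filter(
            scores, self.sample_size, self.weight_power,
            seed=self.seed + self._call_count,
        )
        self._call_count += 1
        return FilterDecision(flagged_compounds=set(pool) - kept)


# --------------------------------------------------------------------------
# metabolomics filter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductSpec:
    """An MS adduct: m/z = (multiplicity * M + mass_shift) / |charge|."""

    name: str
    mass_shift: float
    charge: int
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")
        if self.multiplicity < 1:
            raise ValueError("adduct multiplicity must be >= 1")

    def mz(self, mono_mass: float) -> float:
        return (self.multiplicity * mono_mass + self.mass_shift) / abs(self.charge)


def load_adducts_csv(path) -> List[AdductSpec]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        AdductSpec(str(r["name"]), float(r["mass_shift"]), int(r["charge"]),
                   int(r["multiplicity"]))
        for _, r in df.iterrows()
    ]


def default_adducts() -> List[AdductSpec]:
    from importlib import resources

    with resources.files("rulenet.data").joinpath("default_adducts.csv").open() as fh:
        import pandas as pd

        df = pd.read_csv(fh)
    return [
        AdductSpec(str(r["name"]), float(r["mass_shift"]), int(r["charge"]),
                   int(r["multiplicity"]))
        for _, r in df.iterrows()
    ]


@dataclass
class MetabolomicsFilterConfig:
    peaks: List[float]
    adducts: List[AdductSpec]
    tolerance: float = 0.005
    tolerance_unit: str = "Da"  # "Da" or "ppm"

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("metabolomics filter requires a non-empty peak list")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.tolerance_unit not in ("Da", "ppm"):
            raise ValueError("tolerance unit must be 'Da' or 'ppm'")


def mz_candidates(
    compound: Compound, adducts: Sequence[AdductSpec]
) -> List[Tuple[str, float]]:
    """All (adduct name, m/z) the compound could present as."""
    return [(a.name, a.mz(compound.mono_mass)) for a in adducts]


def metabolomics_filter(
    new_compounds: Iterable[Compound], cfg: MetabolomicsFilterConfig
) -> Tuple[Set[str], List[Tuple[str, str, float, float]]]:
    """Keep compounds whose m/z under some adduct matches a peak.

    Returns the kept cid set and the full match table of
    ``(cid, adduct name, peak m/z, computed m/z)`` rows; the tolerance bound
    is inclusive.
    """
    kept: Set[str] = set()
    pairs: List[Tuple[str, str, float, float]] = []
    peaks = sorted(cfg.peaks)
    for comp in new_compounds:
        for name, mz in mz_candidates(comp, cfg.adducts):
            for p in peaks:
                tol = cfg.tolerance if cfg.tolerance_unit == "Da" else p * cfg.tolerance * 1e-6
                if abs(mz - p) <= tol:
                    kept.add(comp.cid)
                    pairs.append((comp.cid, name, p, mz))
    return kept, pairs


class MetabolomicsFilter(BaseFilter):
    """Post-expansion: keep only compounds annotating an observed peak."""

    name = "metabolomics"
    phase = POST_EXPANSION

    def __init__(self, cfg: MetabolomicsFilterConfig):
        super().__init__()
        self.cfg = cfg
        self.pair_table: List[Tuple[str, str, float, float]] = []

    def examine(self, compounds, reactions, registry) -> FilterDecision:
        pool = {c: comp for c, comp in compounds.items() if not comp.is_cofactor}
        kept, pairs = metabolomics_filter(pool.values(), self.cfg)
        self.pair_table.extend(pairs)
        return FilterDecision(flagged_compounds=set(pool) - kept)


# --------------------------------------------------------------------------
# thermodynamics filter
# --------------------------------------------------------------------------

@dataclass
class ThermoConditions:
    """Aqueous-phase conditions for the Gibbs free energy of reaction.

    ``physiological`` mode pins pH 7.5, ionic strength 0.25 M, and 1 mM
    concentrations; ``adjusted`` mode takes user values.
    """

    mode: str = "physiological"
    pH: float = 7.5
    ionic_strength: float = 0.25
    concentration: float = 1e-3
    dg_min: float = float("-inf")
    dg_max: float = float("inf")

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "physiological", "adjusted"):
            raise ValueError(f"unknown thermo mode {self.mode!r}")
        if self.mode == "physiological":
            self.pH, self.ionic_strength, self.concentration = 7.5, 0.25, 1e-3


class DGProvider(Protocol):
    """Maps a reaction under given conditions to ΔG_r (kJ/mol) or None."""

    def dg(
        self,
        reaction: Reaction,
        registry: Mapping[str, Compound],
        conditions: ThermoConditions,
    ) -> Optional[float]:
        ...


class NullDGProvider:
    """Knows nothing: every ΔG is unknown, so every reaction is retained.

    The engine has no mandatory dependency on an external thermodynamics
    service; plug in a real provider to activate the filter.
    """

    def dg(self, reaction, registry, conditions) -> Optional[float]:
        return None


class ConstantDGProvider:
    """Test/override provider: fixed per-rid values, default for the rest."""

    def __init__(self, values: Mapping[str, float], default: Optional[float] = None):
        self.values = dict(values)
        self.default = default

    def dg(self, reaction, registry, conditions) -> Optional[float]:
        return self.values.get(reaction.rid, self.default)


def thermodynamics_filter(
    new_reactions: Iterable[Reaction],
    dg_provider: DGProvider,
    cond: ThermoConditions,
    registry: Mapping[str, Compound] = {},
) -> Set[str]:
    """Keep reactions with dg_min <= ΔG <= dg_max (inclusive) or unknown ΔG.

    A reaction the provider cannot score is retained — the filter cannot
    comment on its feasibility.  Provider errors are treated as unknown.
    """
    kept: Set[str] = set()
    for rxn in new_reactions:
        try:
            dg = dg_provider.dg(rxn, registry, cond)
        except Exception as exc:
            logger.warning("ΔG provider failed for %s (%s); keeping", rxn.rid, exc)
            dg = None
        if dg is None or cond.dg_min <= dg <= cond.dg_max:
            kept.add(rxn.rid)
    return kept


class ThermodynamicsFilter(BaseFilter):
    name = "thermodynamics"
    phase = POST_EXPANSION

    def __init__(self, provider: DGProvider, conditions: ThermoConditions):
        super().__init__()
        self.provider = provider
        self.conditions = conditions

    def examine(self, compounds, reactions, registry) -> FilterDecision:
        kept = thermodynamics_filter(reactions.values(), self.provider,
                                     self.conditions, registry)
        return FilterDecision(flagged_reactions=set(reactions) - kept)


# --------------------------------------------------------------------------
# feasibility filter
# --------------------------------------------------------------------------

class FeasibilityPredictor(Protocol):
    """Classifies a substrate→product compound pair as feasible or not."""

    def feasible(self, substrate: Compound, product: Compound) -> bool:
        ...


class AlwaysFeasiblePredictor:
    """Reference stub: accepts everything (filter becomes a no-op)."""

    def feasible(self, substrate: Compound, product: Compound) -> bool:
        return True


class DenyListPredictor:
    """Test stub: a set of (substrate SMILES, product SMILES) pairs to reject."""

    def __init__(self, denied: Iterable[Tuple[str, str]]):
        self.denied = set(denied)

    def feasible(self, substrate: Compound, product: Compound) -> bool:
        return (substrate.smiles, product.smiles) not in self.denied


def principal_pair(
    reaction: Reaction, registry: Mapping[str, Compound]
) -> Optional[Tuple[Compound, Compound]]:
    """The (largest substrate, largest product) non-cofactor pair.

    Size is heavy-atom count (total atoms minus hydrogens), ties broken by
    canonical SMILES order.  Falls back to cofactors only when a side has no
    non-cofactor participant.
    """

    def heavy(comp: Compound) -> int:
        return sum(n for el, n in comp.formula.items() if el != "H")

    def pick(side: Sequence[Tuple[int, str]]) -> Optional[Compound]:
        comps = [registry[cid] for _, cid in side if cid in registry]
        pool = [c for c in comps if not c.is_cofactor] or comps
        if not pool:
            return None
        return max(pool, key=lambda c: (heavy(c), c.smiles))

    sub, prod = pick(reaction.reactants), pick(reaction.products)
    if sub is None or prod is None:
        return None
    return sub, prod


def feasibility_filter(
    new_reactions: Iterable[Reaction],
    predictor: FeasibilityPredictor,
    registry: Mapping[str, Compound],
) -> Set[str]:
    """Keep reactions whose principal substrate→product pair is feasible.

    Predictor failures keep the reaction (fail-open, mirroring the
    thermodynamics filter's unknown-ΔG behaviour).
    """
    kept: Set[str] = set()
    for rxn in new_reactions:
        try:
            pair = principal_pair(rxn, registry)
            ok = True if pair is None else predictor.feasible(*pair)
        except Exception as exc:
            logger.warning("feasibility predictor failed for %s (%s); keeping",
                           rxn.rid, exc)
            ok = True
        if ok:
            kept.add(rxn.rid)
    return kept


class FeasibilityFilter(BaseFilter):
    name = "feasibility"
    phase = POST_EXPANSION

    def __init__(self, predictor: FeasibilityPredictor):
        super().__init__()
        self.predictor = predictor

    def examine(self, compounds, reactions, registry) -> FilterDecision:
        kept = feasibility_filter(reactions.values(), self.predictor, registry)
        return FilterDecision(flagged_reactions=set(reactions) - kept)


# --------------------------------------------------------------------------
# target efficiency
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficiencyRecord:
    """Target/compound counts for one run and for the reference run."""

    targets_count: int
    compounds_count: int
    reference_targets: int
    reference_compounds: int


def target_efficiency(rec: EfficiencyRecord) -> float:
    """Targets-per-compound of a run relative to the reference run:
    ``(T_i/C_i) / (T_ref/C_ref)``."""
    if rec.compounds_count <= 0 or rec.reference_compounds <= 0:
        raise ValueError("compound counts must be positive")
    if rec.reference_targets <= 0:
        raise ValueError("reference target count must be positive")
    return (rec.targets_count / rec.compounds_count) / (
        rec.reference_targets / rec.reference_compounds
    )
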