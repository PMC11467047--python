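"""Exhaustive chain-mapping search maximizing the global score.

Model chains are matched to reference chains only within equivalence
groups (same subunit sequence, or same ligand component). Every valid
assignment is enumerated; interface scores are memoized per chain-pair
quadruple since they do not depend on the rest of the mapping, and
candidate evaluation may be spread over worker threads without changing
the result.
"""

from __future__ import annotations

import itertools
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterator, Optional

from .constants import DEFAULT_CONSTANTS, ScoringConstants
from .correspondence import (
    ChainGroup,
    MappingMode,
    ResidueCorrespondence,
    align_sequences,
    alignment_identity,
    group_equivalent_chains,
    map_residues,
)
from .errors import ComplexQAError, IncompatibleGroupsError
from .scoring import InterfaceResult, find_contacts, score_interface
from .small_molecule import LigandResult, pocket_aligned_lrmsd
from .structures import MoleculeClass, Structure

__all__ = [
    "ChainMapping",
    "GlobalResult",
    "ScoreCache",
    "match_groups",
    "count_mappings",
    "enumerate_mappings",
    "global_dockq",
    "find_optimal_mapping",
]

DEFAULT_N_WORKERS = 8
DEFAULT_CHUNK_SIZE = 512


@dataclass(frozen=True)
class ChainMapping:
    """(Possibly partial) injective assignment model chain -> ref chain."""

    assignment: tuple[tuple[str, str], ...]

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "ChainMapping":
        return cls(assignment=tuple(sorted(mapping.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    def inverse(self) -> dict[str, str]:
        return {r: m for m, r in self.assignment}

    def __len__(self) -> int:
        return len(self.assignment)


@dataclass
class GlobalResult:
    """Outcome of scoring one chain mapping (or of the full search)."""

    mapping: ChainMapping
    global_dockq: Optional[float]
    per_interface: dict[str, object]  # key "X:Y" (reference chain pair)
    n_evaluated: int = 1
    objective: float = 0.0  # search objective; includes ligand surrogate

    def to_dict(self) -> dict:
        return {
            "mapping": self.mapping.as_dict(),
            "global_dockq": self.global_dockq,
            "n_evaluated": self.n_evaluated,
            "interfaces": {
                key: (res.to_dict() if hasattr(res, "to_dict") else res)
                for key, res in self.per_interface.items()
            },
        }


def match_groups(
    model_groups: list[ChainGroup],
    ref_groups: list[ChainGroup],
    identity_threshold: float = DEFAULT_CONSTANTS.identity_threshold,
) -> list[tuple[ChainGroup, ChainGroup]]:
    """Pair each model group with its equivalent reference group.

    Model groups with no reference counterpart are dropped (their chains
    stay unmapped). Raises :class:`IncompatibleGroupsError` when no model
    group matches any reference group.
    """
    matched: list[tuple[ChainGroup, ChainGroup]] = []
    used_ref = set()
    for mg in model_groups:
        best: Optional[tuple[float, int]] = None
        for i, rg in enumerate(ref_groups):
            if i in used_ref:
                continue
            if (mg.molecule_class is MoleculeClass.SMALL_MOLECULE) != (
                rg.molecule_class is MoleculeClass.SMALL_MOLECULE
            ):
                continue
            if mg.molecule_class is MoleculeClass.SMALL_MOLECULE:
                if mg.representative_sequence == rg.representative_sequence:
                    best = (1.0, i)
                    break
                continue
            if mg.molecule_class.is_amino != rg.molecule_class.is_amino:
                continue
            identity = alignment_identity(
                *align_sequences(
                    mg.representative_sequence, rg.representative_sequence
                )
            )
            if identity >= identity_threshold and (
                best is None or identity > best[0]
            ):
                best = (identity, i)
        if best is not None:
            used_ref.add(best[1])
            matched.append((mg, ref_groups[best[1]]))
    if not matched:
        raise IncompatibleGroupsError(
            "no model chain group matches any reference group"
        )
    return matched


def _group_injection_count(n_model: int, n_ref: int) -> int:
    k = min(n_model, n_ref)
    n = max(n_model, n_ref)
    return math.factorial(n) // math.factorial(n - k)


def count_mappings(
    model_groups: list[ChainGroup],
    ref_groups: list[ChainGroup],
    identity_threshold: float = DEFAULT_CONSTANTS.identity_threshold,
) -> int:
    """Number of candidate chain mappings (product of per-group injections)."""
    matched = match_groups(model_groups, ref_groups, identity_threshold)
    total = 1
    for mg, rg in matched:
        total *= _group_injection_count(len(mg), len(rg))
    return total


def _group_assignments(
    mg: ChainGroup, rg: ChainGroup
) -> Iterator[tuple[tuple[str, str], ...]]:
    model_ids = list(mg.member_chain_ids)
    ref_ids = list(rg.member_chain_ids)
    if len(model_ids) <= len(ref_ids):
        for perm in itertools.permutations(ref_ids, len(model_ids)):
            yield tuple(zip(model_ids, perm))
    else:
        for chosen in itertools.permutations(model_ids, len(ref_ids)):
            yield tuple(zip(chosen, ref_ids))


def enumerate_mappings(
    model_groups: list[ChainGroup],
    ref_groups: list[ChainGroup],
    identity_threshold: float = DEFAULT_CONSTANTS.identity_threshold,
    fixed: Optional[dict[str, str]] = None,
) -> Iterator[ChainMapping]:
    """Yield every valid chain mapping exactly once, deterministically.

    ``fixed`` pins some model->reference assignments; only the remaining
    chains are permuted.
    """
    fixed = fixed or {}
    matched = match_groups(model_groups, ref_groups, identity_threshold)
    reduced: list[tuple[ChainGroup, ChainGroup]] = []
    for mg, rg in matched:
        m_ids = [c for c in mg.member_chain_ids if c not in fixed]
        fixed_refs = set(fixed.values())
        r_ids = [c for c in rg.member_chain_ids if c not in fixed_refs]
        reduced.append(
            (
                ChainGroup(m_ids, mg.representative_sequence, mg.molecule_class),
                ChainGroup(r_ids, rg.representative_sequence, rg.molecule_class),
            )
        )
    fixed_items = tuple(sorted(fixed.items()))
    per_group = [
        list(_group_assignments(mg, rg)) if mg.member_chain_ids else [()]
        for mg, rg in reduced
    ]
    for combo in itertools.product(*per_group):
        assignment = dict(fixed_items)
        for part in combo:
            assignment.update(part)
        yield ChainMapping.from_dict(assignment)


@dataclass
class _RefInterface:
    chain_a: str  # reference chain order; for ligand interfaces the
    chain_b: str  # receptor comes first
    kind: str  # "polymer" | "small_molecule"

    @property
    def key(self) -> str:
        return f"{self.chain_a}:{self.chain_b}"


def _reference_interfaces(
    ref: Structure, constants: ScoringConstants
) -> list[_RefInterface]:
    interfaces = []
    chains = list(ref)
    for i, ca in enumerate(chains):
        for cb in chains[i + 1:]:
            polymer_a = ca.molecule_class.is_polymer
            polymer_b = cb.molecule_class.is_polymer
            if not polymer_a and not polymer_b:
                continue  # ligand-ligand pairs are not scored
            if polymer_a and polymer_b:
                peptide = (
                    ca.molecule_class is MoleculeClass.PEPTIDE
                    or cb.molecule_class is MoleculeClass.PEPTIDE
                )
                cutoff = (
                    constants.contact_cutoff_peptide
                    if peptide
                    else constants.contact_cutoff
                )
                if find_contacts(ca, cb, cutoff):
                    interfaces.append(
                        _RefInterface(ca.chain_id, cb.chain_id, "polymer")
                    )
            else:
                receptor, ligand = (ca, cb) if polymer_a else (cb, ca)
                if find_contacts(receptor, ligand, constants.contact_cutoff):
                    interfaces.append(
                        _RefInterface(
                            receptor.chain_id, ligand.chain_id, "small_molecule"
                        )
                    )
    return interfaces


class ScoreCache:
    """Memoizes correspondences and per-chain-pair interface scores.

    An interface score depends only on the two model chains assigned to
    the two reference chains, never on the rest of the mapping, so it is
    cached under the quadruple ``(model_a, model_b, ref_a, ref_b)``.
    Plain-dict memoization is thread-safe under the GIL: a rare duplicate
    computation returns an identical value.
    """

    def __init__(
        self,
        model: Structure,
        ref: Structure,
        constants: ScoringConstants = DEFAULT_CONSTANTS,
        residue_mode: MappingMode = MappingMode.ALIGNMENT,
    ) -> None:
        self.model = model
        self.ref = ref
        self.constants = constants
        self.residue_mode = residue_mode
        self._corr: dict[tuple[str, str], ResidueCorrespondence] = {}
        self._scores: dict[tuple, InterfaceResult] = {}
        self._ligand_scores: dict[tuple, LigandResult] = {}
        self.ref_interfaces = _reference_interfaces(ref, constants)
        self.n_score_calls = 0  # diagnostics: actual (uncached) computations

    def correspondence(
        self, model_chain_id: str, ref_chain_id: str
    ) -> ResidueCorrespondence:
        key = (model_chain_id, ref_chain_id)
        if key not in self._corr:
            self._corr[key] = map_residues(
                self.model[model_chain_id],
                self.ref[ref_chain_id],
                self.residue_mode,
            )
        return self._corr[key]

    def score(
        self, model_a: str, model_b: str, ref_a: str, ref_b: str
    ) -> InterfaceResult:
        key = (model_a, model_b, ref_a, ref_b)
        if key not in self._scores:
            self.n_score_calls += 1
            self._scores[key] = score_interface(
                self.model[model_a],
                self.model[model_b],
                self.ref[ref_a],
                self.ref[ref_b],
                self.correspondence(model_a, ref_a),
                self.correspondence(model_b, ref_b),
                self.constants,
            )
        return self._scores[key]

    def ligand_score(
        self, model_rec: str, model_lig: str, ref_rec: str, ref_lig: str
    ) -> LigandResult:
        key = (model_rec, model_lig, ref_rec, ref_lig)
        if key not in self._ligand_scores:
            self.n_score_calls += 1
            result = pocket_aligned_lrmsd(
                self.model[model_rec],
                self.ref[ref_rec],
                self.model[model_lig],
                self.ref[ref_lig],
                self.correspondence(model_rec, ref_rec),
                self.constants,
            )
            result.clashes = 0
            self._ligand_scores[key] = result
        return self._ligand_scores[key]


def global_dockq(
    model: Structure,
    ref: Structure,
    mapping: ChainMapping,
    cache: Optional[ScoreCache] = None,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> GlobalResult:
    """Score one chain mapping: per-interface results and their mean.

    The reported global score is the arithmetic mean of DockQ over all
    reference polymer-polymer interfaces; interfaces whose chains are
    unmapped contribute 0. Small-molecule interfaces are reported via
    their pocket-aligned LRMSD and excluded from the mean; they enter the
    search objective through the surrogate ``1/(1+(LRMSD/b)^2)`` so that
    equivalent ligand copies are assigned optimally.
    """
    if cache is None:
        cache = ScoreCache(model, ref, constants)
    if not cache.ref_interfaces:
        raise ComplexQAError("reference structure has no interfaces")
    inverse = mapping.inverse()
    per_interface: dict[str, object] = {}
    polymer_sum = 0.0
    n_polymer = 0
    objective = 0.0
    for iface in cache.ref_interfaces:
        model_a = inverse.get(iface.chain_a)
        model_b = inverse.get(iface.chain_b)
        if iface.kind == "polymer":
            n_polymer += 1
            if model_a is None or model_b is None:
                per_interface[iface.key] = {
                    "kind": "polymer",
                    "ref_pair": [iface.chain_a, iface.chain_b],
                    "unmapped": True,
                    "dockq": 0.0,
                }
                continue
            result = cache.score(model_a, model_b, iface.chain_a, iface.chain_b)
            per_interface[iface.key] = result
            polymer_sum += result.dockq
            objective += result.dockq
        else:
            if model_a is None or model_b is None:
                per_interface[iface.key] = {
                    "kind": "small_molecule",
                    "ref_pair": [iface.chain_a, iface.chain_b],
                    "unmapped": True,
                }
                continue
            lig_result = cache.ligand_score(
                model_a, model_b, iface.chain_a, iface.chain_b
            )
            per_interface[iface.key] = lig_result
            objective += 1.0 / (1.0 + (lig_result.lrmsd / constants.b) ** 2)
    global_score = polymer_sum / n_polymer if n_polymer else None
    return GlobalResult(
        mapping=mapping,
        global_dockq=global_score,
        per_interface=per_interface,
        n_evaluated=1,
        objective=objective,
    )


def _objective(
    mapping: ChainMapping, cache: ScoreCache, constants: ScoringConstants
) -> float:
    inverse = mapping.inverse()
    total = 0.0
    for iface in cache.ref_interfaces:
        model_a = inverse.get(iface.chain_a)
        model_b = inverse.get(iface.chain_b)
        if model_a is None or model_b is None:
            continue
        if iface.kind == "polymer":
            total += cache.score(
                model_a, model_b, iface.chain_a, iface.chain_b
            ).dockq
        else:
            lrmsd = cache.ligand_score(
                model_a, model_b, iface.chain_a, iface.chain_b
            ).lrmsd
            total += 1.0 / (1.0 + (lrmsd / constants.b) ** 2)
    return total


def find_optimal_mapping(
    model: Structure,
    ref: Structure,
    constraints: Optional[dict[str, str]] = None,
    ref_subset: Optional[set[str]] = None,
    n_workers: int = DEFAULT_N_WORKERS,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
    residue_mode: MappingMode = MappingMode.ALIGNMENT,
    cache: Optional[ScoreCache] = None,
) -> GlobalResult:
    """Exhaustive search for the chain mapping with the best global score.

    ``constraints`` pins model->reference assignments; ``ref_subset``
    restricts mapping targets (and scored interfaces) to a subset of
    reference chains. The result is independent of ``n_workers`` and
    ``chunk_size``: ties are broken by enumeration order.
    """
    if cache is None:
        cache = ScoreCache(model, ref, constants, residue_mode)
    if ref_subset is not None:
        cache.ref_interfaces = [
            i
            for i in cache.ref_interfaces
            if i.chain_a in ref_subset and i.chain_b in ref_subset
        ]
    if not cache.ref_interfaces:
        raise ComplexQAError("reference structure has no interfaces to score")

    model_groups = group_equivalent_chains(model, constants.identity_threshold)
    ref_groups = group_equivalent_chains(ref, constants.identity_threshold)
    if ref_subset is not None:
        ref_groups = [
            ChainGroup(
                [c for c in g.member_chain_ids if c in ref_subset],
                g.representative_sequence,
                g.molecule_class,
            )
            for g in ref_groups
        ]
        ref_groups = [g for g in ref_groups if g.member_chain_ids]

    candidates = list(
        enumerate_mappings(
            model_groups,
            ref_groups,
            constants.identity_threshold,
            fixed=constraints,
        )
    )
    if not candidates:
        raise ComplexQAError("no candidate chain mappings to evaluate")

    def eval_chunk(chunk: list[tuple[int, ChainMapping]]):
        return [
            (idx, _objective(mapping, cache, constants))
            for idx, mapping in chunk
        ]

    indexed = list(enumerate(candidates))
    if n_workers <= 1 or len(indexed) <= chunk_size:
        scored = eval_chunk(indexed)
    else:
        chunks = [
            indexed[i:i + chunk_size]
            for i in range(0, len(indexed), chunk_size)
        ]
        scored = []
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            for part in pool.map(eval_chunk, chunks):
                scored.extend(part)

    best_idx, _ = max(scored, key=lambda item: (item[1], -item[0]))
    result = global_dockq(
        model, ref, candidates[best_idx], cache=cache, constants=constants
    )
    result.n_evaluated = len(candidates)
    return result
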