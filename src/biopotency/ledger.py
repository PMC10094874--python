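"""Purification-tree data model and total-bioactivity (TBA) arithmetic.

TBA of a material = EDV50 (L/g) x solid weight (g), in liters: the volume
of water the material could be diluted into while still producing
half-maximal activity.  Because TBA is linear in weight it admits mass-
balance bookkeeping: summing child TBAs against a parent's measures how
much bioactivity survived a purification step, and comparing bioactivity
recovery to mass recovery distinguishes additive mixtures (the two match)
from ones that lost synergy or suffered degradation (bioactivity recovery
falls short).

Stored values are never rounded.  :class:`RoundingPolicy` exists purely to
reproduce published tables, which round EDV50/TBA entries before summing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from biopotency.errors import DomainError, NotComputableError, TreeStructureError
from biopotency.potency import Censoring, PotencyEstimate, potency_uncertainty_to_edv50

__all__ = [
    "MaterialRole",
    "MaterialNode",
    "PurificationTree",
    "TBAResult",
    "RecoveryReport",
    "InteractionClass",
    "InteractionCall",
    "RoundingPolicy",
    "ReportRow",
    "SiblingGroupSummary",
    "CampaignReport",
    "compute_tba",
    "tba_per_gram",
    "sum_tba",
    "recovery",
    "classify_interaction",
    "campaign_report",
]


class MaterialRole(str, Enum):
    PLANT = "plant"
    EXTRACT = "extract"
    FRACTION = "fraction"
    COMPOUND = "compound"


@dataclass(frozen=True)
class MaterialNode:
    """One physical material: plant batch, solvent extract, HPLC fraction or compound.

    ``weight_g`` is the canonical solid mass in grams (mg is converted at the
    IO boundary); ``dry_source_mass_g`` is the dry starting plant mass used
    for per-gram normalization.
    """

    id: str
    label: str = ""
    role: MaterialRole = MaterialRole.EXTRACT
    solvent: Optional[str] = None
    weight_g: Optional[float] = None
    dry_source_mass_g: Optional[float] = None
    potency: Optional[PotencyEstimate] = None
    retention_time_min: Optional[float] = None
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise DomainError("node id must be a non-empty token")
        if not isinstance(self.role, MaterialRole):
            object.__setattr__(self, "role", MaterialRole(self.role))
        if self.weight_g is not None and (not math.isfinite(self.weight_g) or self.weight_g < 0):
            raise DomainError(f"weight must be >= 0, got {self.weight_g!r} for node {self.id!r}")
        if self.dry_source_mass_g is not None and self.dry_source_mass_g <= 0:
            raise DomainError(
                f"dry_source_mass_g must be > 0 when present, got {self.dry_source_mass_g!r}"
            )
        if self.retention_time_min is not None and self.retention_time_min <= 0:
            raise DomainError("retention_time_min must be > 0 when present")


class PurificationTree:
    """Rooted tree of :class:`MaterialNode`, edges implied by ``parent_id``.

    Guarantees on construction: every ``parent_id`` resolves, there is
    exactly one root, and the graph is acyclic.  Node insertion order is
    preserved and used for deterministic traversal.
    """

    def __init__(self, nodes: Iterable[MaterialNode] = ()):
        self._nodes: Dict[str, MaterialNode] = {}
        for node in nodes:
            self.add(node, validate=False)
        if self._nodes:
            self.validate()

    def add(self, node: MaterialNode, validate: bool = True) -> None:
        if node.id in self._nodes:
            raise TreeStructureError(f"duplicate node id {node.id!r}")
        self._nodes[node.id] = node
        if validate:
            self.validate()

    def validate(self) -> None:
        roots = [n for n in self._nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise TreeStructureError(
                f"tree must have exactly one root, found {len(roots)}: "
                f"{[n.id for n in roots]}"
            )
        for node in self._nodes.values():
            if node.parent_id is not None and node.parent_id not in self._nodes:
                raise TreeStructureError(
                    f"node {node.id!r} references unknown parent {node.parent_id!r}"
                )
        # cycle check by walking each node to the root
        for node in self._nodes.values():
            seen = {node.id}
            cur = node
            while cur.parent_id is not None:
                if cur.parent_id in seen:
                    raise TreeStructureError(f"cycle detected through node {cur.parent_id!r}")
                seen.add(cur.parent_id)
                cur = self._nodes[cur.parent_id]

    @property
    def nodes(self) -> Dict[str, MaterialNode]:
        return dict(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __getitem__(self, node_id: str) -> MaterialNode:
        return self._nodes[node_id]

    def __iter__(self):
        return iter(self._nodes.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, PurificationTree):
            return NotImplemented
        return list(self._nodes.items()) == list(other._nodes.items())

    @property
    def root(self) -> MaterialNode:
        for n in self._nodes.values():
            if n.parent_id is None:
                return n
        raise TreeStructureError("empty tree has no root")

    def children(self, node_id: str) -> List[MaterialNode]:
        """Children of ``node_id`` in insertion order."""
        return [n for n in self._nodes.values() if n.parent_id == node_id]

    def depth_first(self) -> List[MaterialNode]:
        """Depth-first node order; siblings keep input order."""
        if not self._nodes:
            return []
        out: List[MaterialNode] = []

        def visit(n: MaterialNode) -> None:
            out.append(n)
            for ch in self.children(n.id):
                visit(ch)

        visit(self.root)
        return out


@dataclass(frozen=True)
class TBAResult:
    """Total bioactivity of one node, with provenance.

    ``tba`` is None when the node's TBA is not computable (no potency, or a
    censored potency without override); ``reason`` then says why.
    """

    node_id: str
    tba: Optional[float]  # L
    tba_sd: Optional[float] = None  # L
    tba_per_gram_source: Optional[float] = None  # L/g
    reason: Optional[str] = None
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def computable(self) -> bool:
        return self.tba is not None


def compute_tba(node: MaterialNode, allow_censored: bool = False) -> TBAResult:
    """TBA(node) = EDV50 x weight, in liters.

    A node without potency, or with a right-censored potency and
    ``allow_censored=False``, yields an explicit non-computable result.
    With ``allow_censored=True`` the censoring bound is used as a
    conservative EDV50 upper estimate.  ``tba_sd`` is propagated from the
    IC50 SD by the delta method when available.
    """
    if node.weight_g is None:
        return TBAResult(node.id, None, reason="node has no weight")
    if node.potency is None:
        return TBAResult(node.id, None, reason="node has no potency estimate")
    p = node.potency
    if p.censored is Censoring.RIGHT and not allow_censored:
        return TBAResult(
            node.id, None,
            reason="potency is right-censored (IC50 above highest tested "
                   "concentration); pass allow_censored=True to use the bound",
        )
    edv50 = p.edv50
    tba = edv50 * node.weight_g
    tba_sd = None
    if p.ic50_sd is not None:
        unc = potency_uncertainty_to_edv50(p)
        tba_sd = unc.edv50_sd * node.weight_g if unc.edv50_sd is not None else None
    per_gram = tba / node.dry_source_mass_g if node.dry_source_mass_g else None
    return TBAResult(
        node_id=node.id,
        tba=tba,
        tba_sd=tba_sd,
        tba_per_gram_source=per_gram,
        provenance={
            "ic50_g_per_l": p.ic50,
            "edv50_l_per_g": edv50,
            "weight_g": node.weight_g,
            "censored": p.censored.value,
        },
    )


def tba_per_gram(result: TBAResult, dry_source_mass_g: float) -> float:
    """Normalize a TBA to per-gram-of-dry-starting-material, L/g."""
    if dry_source_mass_g <= 0:
        raise DomainError(f"dry_source_mass_g must be > 0, got {dry_source_mass_g!r}")
    if result.tba is None:
        raise NotComputableError(f"TBA of node {result.node_id!r} is not computable: {result.reason}")
    return result.tba / dry_source_mass_g


def sum_tba(results: Sequence[TBAResult], rounding: Optional[int] = None) -> float:
    """Sum TBAs in liters.

    ``rounding=d`` rounds every addend to ``d`` decimals before summing —
    needed only to reproduce published table totals that were computed from
    rounded entries.  Non-computable results contribute 0.  Empty input
    sums to 0.
    """
    total = 0.0
    for r in results:
        if r.tba is None:
            continue
        total += round(r.tba, rounding) if rounding is not None else r.tba
    return total


class InteractionClass(str, Enum):
    EQUIVALENT = "equivalent"
    REDUCED = "reduced"
    INCREASED = "increased"


# the method cannot distinguish the alternative mechanisms within a class,
# so every classification carries both candidate interpretations
_INTERPRETATIONS = {
    InteractionClass.EQUIVALENT: (
        "additive interaction among the separated materials",
        "the reference solvent captures all compounds responsible for the bioactivity",
    ),
    InteractionClass.REDUCED: (
        "loss of bioactivity by degradation of an active component during purification",
        "loss of synergistic interaction between the separated compounds",
    ),
    InteractionClass.INCREASED: (
        "antagonistic interaction present in the original mixture",
        "the reference solvent does not capture all compounds responsible for the bioactivity",
    ),
}


@dataclass(frozen=True)
class InteractionCall:
    interaction_class: InteractionClass
    ratio_pct: float  # 100 * b / a
    tolerance_pct: float
    interpretations: Tuple[str, str]


def classify_interaction(
    tba_a_per_gram: float,
    tba_b_per_gram: float,
    tolerance_pct: float = 10.0,
) -> InteractionCall:
    """Compare per-gram TBA of a reference process (a) against an alternative (b).

    ``equivalent`` when |b - a| / a <= tolerance; ``reduced`` when b falls
    short beyond tolerance; ``increased`` when b exceeds beyond tolerance.
    Both candidate mechanisms for each class are reported because the
    balance alone cannot separate them.
    """
    if tba_a_per_gram < 0 or tba_b_per_gram < 0 or tolerance_pct < 0:
        raise DomainError("per-gram TBAs and tolerance must be >= 0")
    if tba_a_per_gram == 0:
        raise DomainError("reference per-gram TBA is zero; comparison undefined")
    rel = (tba_b_per_gram - tba_a_per_gram) / tba_a_per_gram
    if abs(rel) <= tolerance_pct / 100.0:
        cls = InteractionClass.EQUIVALENT
    elif rel < 0:
        cls = InteractionClass.REDUCED
    else:
        cls = InteractionClass.INCREASED
    return InteractionCall(
        interaction_class=cls,
        ratio_pct=100.0 * tba_b_per_gram / tba_a_per_gram,
        tolerance_pct=tolerance_pct,
        interpretations=_INTERPRETATIONS[cls],
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Mass and bioactivity balance of one purification step."""

    parent_id: str
    child_ids: Tuple[str, ...]
    mass_recovery_pct: float
    tba_recovery_pct: Optional[float]
    interaction_class: Optional[InteractionClass]
    tolerance_band_pct: float
    censored_child_ids: Tuple[str, ...] = ()
    notes: Tuple[str, ...] = ()


def recovery(
    parent: MaterialNode,
    children: Sequence[MaterialNode],
    tba_addend_decimals: Optional[int] = None,
    tolerance_band_pct: float = 25.0,
    allow_censored: bool = False,
) -> RecoveryReport:
    """Mass and TBA recovery of ``children`` against ``parent``.

    ``mass_recovery_pct = 100 x sum(child weight) / parent weight`` and
    ``tba_recovery_pct = 100 x sum(child TBA) / parent TBA`` (child addends
    rounded to ``tba_addend_decimals`` first when given, to reproduce
    published totals).  Censored-potency children contribute 0 to the TBA
    sum and are listed in ``censored_child_ids``.

    The interaction class compares bioactivity recovery against mass
    recovery: when they agree within ``tolerance_band_pct`` (relative) the
    step behaved additively; bioactivity falling short beyond the band
    indicates degradation or synergy loss, exceeding it indicates
    antagonism relief or assay nonlinearity.
    """
    if parent.weight_g is None or parent.weight_g <= 0:
        raise DomainError(f"parent {parent.id!r} needs a positive weight for recovery")
    if not children:
        raise DomainError("recovery needs at least one child")

    mass_recovery = 100.0 * sum(c.weight_g or 0.0 for c in children) / parent.weight_g

    notes: List[str] = []
    censored: List[str] = []
    parent_tba = compute_tba(parent, allow_censored=allow_censored)
    tba_recovery: Optional[float] = None
    interaction: Optional[InteractionClass] = None
    if parent_tba.tba is None:
        notes.append(f"parent TBA not computable: {parent_tba.reason}")
    elif parent_tba.tba == 0:
        raise DomainError(f"parent {parent.id!r} has zero TBA; recovery undefined")
    else:
        child_results = []
        for c in children:
            r = compute_tba(c, allow_censored=allow_censored)
            if (
                r.tba is None
                and c.potency is not None
                and c.potency.censored is Censoring.RIGHT
            ):
                censored.append(c.id)
            elif r.tba is None:
                notes.append(f"child {c.id!r} skipped: {r.reason}")
            child_results.append(r)
        tba_recovery = (
            100.0 * sum_tba(child_results, rounding=tba_addend_decimals) / parent_tba.tba
        )
        interaction = classify_interaction(
            mass_recovery, tba_recovery, tolerance_pct=tolerance_band_pct
        ).interaction_class
    if censored:
        notes.append(
            "censored-potency children contributed 0 to the TBA sum: " + ", ".join(censored)
        )
    return RecoveryReport(
        parent_id=parent.id,
        child_ids=tuple(c.id for c in children),
        mass_recovery_pct=mass_recovery,
        tba_recovery_pct=tba_recovery,
        interaction_class=interaction,
        tolerance_band_pct=tolerance_band_pct,
        censored_child_ids=tuple(censored),
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class RoundingPolicy:
    """Presentation-layer rounding used to reproduce published tables.

    ``edv50_decimals``/``tba_decimals`` control rendered table entries;
    ``round_edv50_before_tba`` makes table TBA entries use the rounded EDV50
    (some published tables multiply the printed EDV50 by the weight);
    ``round_tba_before_sum`` makes totals sum the rounded entries.  None of
    this ever touches stored analytic values.
    """

    edv50_decimals: Optional[int] = 2
    tba_decimals: Optional[int] = 2
    per_gram_decimals: Optional[int] = 2
    mass_pct_decimals: Optional[int] = 2
    tba_pct_decimals: Optional[int] = 1
    round_edv50_before_tba: bool = False
    round_tba_before_sum: bool = False

    @classmethod
    def analytic(cls) -> "RoundingPolicy":
        """No rounding anywhere; full-precision values."""
        return cls(
            edv50_decimals=None, tba_decimals=None, per_gram_decimals=None,
            mass_pct_decimals=None, tba_pct_decimals=None,
        )

    @classmethod
    def extract_table(cls) -> "RoundingPolicy":
        """Gram-scale solvent-extract tables: 2-dp EDV50/TBA/per-gram."""
        return cls()

    @classmethod
    def fraction_table(cls) -> "RoundingPolicy":
        """mg-scale fraction tables: 3-dp TBA entries, rounded before the
        total, and TBA entries formed from the 2-dp EDV50."""
        return cls(
            tba_decimals=3,
            round_edv50_before_tba=True,
            round_tba_before_sum=True,
        )

    def round_edv50(self, x: float) -> float:
        return round(x, self.edv50_decimals) if self.edv50_decimals is not None else x

    def round_tba(self, x: float) -> float:
        return round(x, self.tba_decimals) if self.tba_decimals is not None else x

    def round_per_gram(self, x: float) -> float:
        return round(x, self.per_gram_decimals) if self.per_gram_decimals is not None else x

    def table_tba(self, node: MaterialNode) -> Optional[float]:
        """TBA entry as the table prints it (may use rounded EDV50)."""
        if node.potency is None or node.weight_g is None:
            return None
        edv = node.potency.edv50
        if self.round_edv50_before_tba:
            edv = self.round_edv50(edv)
        return self.round_tba(edv * node.weight_g)


@dataclass(frozen=True)
class ReportRow:
    node_id: str
    label: str
    role: str
    solvent: Optional[str]
    ic50_g_per_l: Optional[float]
    edv50_l_per_g: Optional[float]
    weight_g: Optional[float]
    tba_l: Optional[float]
    dry_source_mass_g: Optional[float]
    tba_per_gram: Optional[float]
    retention_time_min: Optional[float]
    censored: bool
    reason: Optional[str]  # why TBA is absent, when it is


@dataclass(frozen=True)
class SiblingGroupSummary:
    parent_id: str
    child_ids: Tuple[str, ...]
    total_weight_g: float
    total_tba_l: Optional[float]
    total_tba_per_gram: Optional[float]
    recovery: Optional[RecoveryReport]


@dataclass(frozen=True)
class CampaignReport:
    rows: Tuple[ReportRow, ...]
    groups: Tuple[SiblingGroupSummary, ...]
    policy: RoundingPolicy


def campaign_report(
    tree: PurificationTree,
    policy: Optional[RoundingPolicy] = None,
    tolerance_band_pct: float = 25.0,
    allow_censored: bool = False,
) -> CampaignReport:
    """Per-node TBA table plus per-sibling-group totals and recoveries.

    Node order is depth-first with siblings in input order.  Nodes lacking
    potency appear with the reason instead of a number.  For every parent
    with children, a totals row and (when the parent's own TBA is
    computable) a :class:`RecoveryReport` are produced.  Rounding follows
    ``policy`` (analytic by default: no rounding).
    """
    policy = policy or RoundingPolicy.analytic()
    rows: List[ReportRow] = []
    for node in tree.depth_first():
        result = compute_tba(node, allow_censored=allow_censored)
        p = node.potency
        tba_display = policy.table_tba(node) if result.tba is not None else None
        per_gram = None
        if result.tba is not None and node.dry_source_mass_g:
            per_gram = policy.round_per_gram(result.tba / node.dry_source_mass_g)
        rows.append(
            ReportRow(
                node_id=node.id,
                label=node.label,
                role=node.role.value,
                solvent=node.solvent,
                ic50_g_per_l=p.ic50 if p else None,
                edv50_l_per_g=policy.round_edv50(p.edv50) if p else None,
                weight_g=node.weight_g,
                tba_l=tba_display,
                dry_source_mass_g=node.dry_source_mass_g,
                tba_per_gram=per_gram,
                retention_time_min=node.retention_time_min,
                censored=bool(p and p.censored is Censoring.RIGHT),
                reason=result.reason,
            )
        )

    groups: List[SiblingGroupSummary] = []
    for node in tree.depth_first():
        children = tree.children(node.id)
        if not children:
            continue
        child_results = [compute_tba(c, allow_censored=allow_censored) for c in children]
        addend_decimals = policy.tba_decimals if policy.round_tba_before_sum else None
        if policy.round_edv50_before_tba:
            totals = [policy.table_tba(c) for c in children]
            total_tba = sum(t for t in totals if t is not None) if any(
                t is not None for t in totals
            ) else None
        else:
            computable = [r for r in child_results if r.tba is not None]
            total_tba = sum_tba(computable, rounding=addend_decimals) if computable else None
        total_weight = sum(c.weight_g or 0.0 for c in children)
        per_gram_total = None
        masses = {c.dry_source_mass_g for c in children if c.dry_source_mass_g}
        if total_tba is not None and len(masses) == 1:
            per_gram_total = policy.round_per_gram(total_tba / masses.pop())
        rec: Optional[RecoveryReport] = None
        if node.weight_g and node.potency is not None:
            try:
                rec = recovery(
                    node, children,
                    tba_addend_decimals=addend_decimals,
                    tolerance_band_pct=tolerance_band_pct,
                    allow_censored=allow_censored,
                )
            except DomainError:
                rec = None
        groups.append(
            SiblingGroupSummary(
                parent_id=node.id,
                child_ids=tuple(c.id for c in children),
                total_weight_g=total_weight,
                total_tba_l=total_tba,
                total_tba_per_gram=per_gram_total,
                recovery=rec,
            )
        )
    return CampaignReport(rows=tuple(rows), groups=tuple(groups), policy=policy)
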