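"""Ground-truth simulator for mixtures, fractionation campaigns and plates.

The additivity model is mass-fraction-weighted EDV50 (dose addition):

    EDV50(mix) = (1 + s) * sum_i w_i * EDV50(i)

with mass fractions ``w_i`` and a single synergy factor ``s`` (0 = additive,
s > 0 synergy, -1 < s < 0 antagonism).  Under s = 0 total bioactivity is
exactly conserved when a mixture is split — which is what makes "additive"
an operational, testable statement rather than an interpretation.  This is
a modeling choice of the simulator, not a measured fact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from biopotency.errors import DomainError
from biopotency.ledger import MaterialNode, MaterialRole, PurificationTree
from biopotency.potency import DoseResponsePlate, PotencyEstimate

__all__ = [
    "TrueCompound",
    "MixtureSpec",
    "mixture_potency",
    "simulate_fractionation",
    "simulate_plate",
    "random_compounds",
]


@dataclass(frozen=True)
class TrueCompound:
    """A compound with known true potency — the simulator's ground truth."""

    id: str
    true_ic50: float  # g/L
    mass: float  # g

    def __post_init__(self) -> None:
        if not math.isfinite(self.true_ic50) or self.true_ic50 <= 0:
            raise DomainError(f"true_ic50 must be > 0, got {self.true_ic50!r}")
        if self.mass < 0:
            raise DomainError(f"mass must be >= 0, got {self.mass!r}")

    @property
    def true_edv50(self) -> float:
        return 1.0 / self.true_ic50


@dataclass(frozen=True)
class MixtureSpec:
    """A mixture of compounds with mass fractions summing to 1."""

    components: Tuple[Tuple[TrueCompound, float], ...]
    synergy_factor: float = 0.0  # s >= -1; 0 = additive
    loss_fraction: float = 0.0  # material lost per split step, 0..1

    def __post_init__(self) -> None:
        if not self.components:
            raise DomainError("mixture needs at least one component")
        if self.synergy_factor < -1.0:
            raise DomainError(f"synergy_factor must be >= -1, got {self.synergy_factor!r}")
        if not 0.0 <= self.loss_fraction < 1.0:
            raise DomainError(f"loss_fraction must be in [0, 1), got {self.loss_fraction!r}")
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"mass fractions must sum to 1 within 1e-9, got {total!r}")

    @classmethod
    def from_compounds(
        cls, compounds: Sequence[TrueCompound], synergy_factor: float = 0.0,
        loss_fraction: float = 0.0,
    ) -> "MixtureSpec":
        """Mass fractions taken from the compounds' own masses."""
        total = sum(c.mass for c in compounds)
        if total <= 0:
            raise DomainError("total compound mass must be > 0")
        return cls(
            components=tuple((c, c.mass / total) for c in compounds),
            synergy_factor=synergy_factor,
            loss_fraction=loss_fraction,
        )


def mixture_potency(spec: MixtureSpec) -> PotencyEstimate:
    """Dose-additive mixture potency: EDV50(mix) = (1+s) * sum w_i EDV50(i)."""
    edv50 = (1.0 + spec.synergy_factor) * sum(
        w / c.true_ic50 for c, w in spec.components
    )
    if edv50 <= 0:
        raise DomainError("mixture EDV50 is non-positive (synergy_factor = -1 with no activity)")
    return PotencyEstimate(ic50=1.0 / edv50, assay_label="simulated mixture")


AssignmentRule = Callable[[Sequence[TrueCompound], int, np.random.Generator], List[int]]


def _one_to_one_rule(
    compounds: Sequence[TrueCompound], n_fractions: int, rng: np.random.Generator
) -> List[int]:
    """Default rule: each compound lands in exactly one random fraction."""
    return list(rng.integers(0, n_fractions, size=len(compounds)))


def simulate_fractionation(
    compounds: Sequence[TrueCompound],
    n_fractions: int,
    loss_fraction: float = 0.0,
    synergy_factor: float = 0.0,
    assignment_rule: Optional[AssignmentRule] = None,
    seed: int = 0,
) -> PurificationTree:
    """Simulate a parent mixture split into ``n_fractions`` measured fractions.

    The parent carries the mixture potency of all compounds (including the
    synergy factor); each fraction holds the compounds the assignment rule
    sends there, with masses scaled by ``1 - loss_fraction``, and its
    measured potency is the dose-additive mixture of its own compounds
    (synergy is a property of the intact parent mixture only, so s = 0
    inside fractions).  Empty fractions are emitted with zero weight and no
    potency.  Deterministic for a fixed seed.
    """
    if n_fractions < 1:
        raise DomainError(f"n_fractions must be >= 1, got {n_fractions}")
    if not 0.0 <= loss_fraction < 1.0:
        raise DomainError(f"loss_fraction must be in [0, 1), got {loss_fraction!r}")
    if synergy_factor < -1.0:
        raise DomainError(f"synergy_factor must be >= -1, got {synergy_factor!r}")
    if not compounds:
        raise DomainError("need at least one compound")

    rng = np.random.default_rng(seed)
    rule = assignment_rule or _one_to_one_rule
    assignment = rule(compounds, n_fractions, rng)
    if len(assignment) != len(compounds) or any(not 0 <= a < n_fractions for a in assignment):
        raise DomainError("assignment rule must map every compound to a fraction index")

    parent_spec = MixtureSpec.from_compounds(compounds, synergy_factor=synergy_factor)
    parent = MaterialNode(
        id="parent",
        label=f"simulated mixture (seed={seed}, s={synergy_factor}, loss={loss_fraction})",
        role=MaterialRole.EXTRACT,
        weight_g=sum(c.mass for c in compounds),
        potency=mixture_potency(parent_spec),
    )
    nodes = [parent]
    keep = 1.0 - loss_fraction
    for idx in range(n_fractions):
        members = [c for c, a in zip(compounds, assignment) if a == idx]
        weight = keep * sum(c.mass for c in members)
        potency = None
        if members and weight > 0:
            potency = mixture_potency(MixtureSpec.from_compounds(members))
        nodes.append(
            MaterialNode(
                id=f"frac{idx + 1:02d}",
                label=f"fraction {idx + 1}",
                role=MaterialRole.FRACTION,
                weight_g=weight,
                potency=potency,
                parent_id="parent",
            )
        )
    return PurificationTree(nodes)


def simulate_plate(
    true_ic50: float,
    hill_slope: float = 1.0,
    dilution_start: float = 1.0,
    dilution_factor: float = 2.0,
    n_dilutions: int = 8,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    top: float = 100.0,
    bottom: float = 0.0,
) -> DoseResponsePlate:
    """Simulate a serial-dilution inhibition plate.

    Responses follow the 4PL mean ``bottom + (top-bottom)/(1+(c/ic50)^h)``
    plus Gaussian noise of SD ``noise_sd`` (percentage points), clipped to
    [-10, 110]%.  Deterministic for a fixed seed.
    """
    if true_ic50 <= 0 or hill_slope <= 0 or dilution_start <= 0:
        raise DomainError("true_ic50, hill_slope and dilution_start must be > 0")
    if dilution_factor <= 1.0:
        raise DomainError(f"dilution_factor must be > 1, got {dilution_factor!r}")
    if n_dilutions < 1 or n_replicates < 1:
        raise DomainError("n_dilutions and n_replicates must be >= 1")
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd!r}")

    rng = np.random.default_rng(seed)
    concs = dilution_start / dilution_factor ** np.arange(n_dilutions)
    points = []
    for rep in range(n_replicates):
        mean = bottom + (top - bottom) / (1.0 + (concs / true_ic50) ** hill_slope)
        noisy = mean + (rng.normal(0.0, noise_sd, size=concs.size) if noise_sd > 0 else 0.0)
        noisy = np.clip(noisy, -10.0, 110.0)
        points.extend(
            (float(c), float(r), f"rep{rep + 1}") for c, r in zip(concs, noisy)
        )
    return DoseResponsePlate(
        points=tuple(points),
        max_tested_concentration=float(dilution_start),
        dilution_note=(
            f"{n_dilutions}-point 1:{dilution_factor:g} serial dilution from "
            f"{dilution_start:g} g/L, seed={seed}"
        ),
    )


def random_compounds(
    n: int,
    seed: int = 0,
    ic50_log10_range: Tuple[float, float] = (-3.0, 0.0),
    mass_range: Tuple[float, float] = (0.1, 10.0),
) -> List[TrueCompound]:
    """Draw ``n`` compounds with log-uniform IC50s and uniform masses (seeded)."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ic50s = 10.0 ** rng.uniform(*ic50_log10_range, size=n)
    masses = rng.uniform(*mass_range, size=n)
    return [
        TrueCompound(id=f"c{i + 1:03d}", true_ic50=float(ic), mass=float(m))
        for i, (ic, m) in enumerate(zip(ic50s, masses))
    ]
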