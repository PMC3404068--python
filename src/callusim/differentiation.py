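"""Substrate- and oxygen-regulated stem cell differentiation rules.

The regulatory hypothesis: mechanical loading acts on stem cell fate only
indirectly, by gating angiogenesis and hence the local oxygen tension.  Per
element and per day:

* **Chondrogenesis** — oxygen tension below the hypoxia threshold, regardless
  of substrate or supply; cartilage forms in situ.
* **Osteogenesis** — sufficient oxygen, a blood supply, and a face-adjacent
  fully formed bony element (stiff substrate): an osteogenic front crosses
  the element at the tissue formation rate ``TFR``.
* **Adipogenesis** — sufficient oxygen, a blood supply, and a face-adjacent
  fully formed marrow element (soft substrate): the marrow front advances
  the same way.
* **Fibrogenesis** — in all other cases; fibrous tissue forms in situ.

A blood supply is a prerequisite for osteogenesis and adipogenesis.  The
front mechanism records how "full" of new tissue each element is;
``fill`` rises at ``TFR * substrate_face_area / element_volume`` per day and
the next element cannot sense the substrate until the adjoining element is
full, which makes front propagation independent of element size.  Front
integration is event-driven inside each day (the exact limit of per-day
sub-iterations): when an element fills, its neighbours are re-sensed with
the remaining fraction of the day.

Cartilage face-adjacent to bone calcifies (stiffening factor two) and, once
vascularised, is replaced by bone through the osteogenic front
(endochondral ossification).  Bone whose octahedral shear strain falls
below the resorption threshold is resorbed; immature bone matures after ten
days.  The classic comparator model (octahedral shear strain + relative
fluid velocity stimulus) is provided by :func:`prendergast_classify`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence, Tuple

import numpy as np

from .geometry import Mesh
from .materials import BONE_PHENOTYPES, Phenotype

__all__ = [
    "Lineage",
    "RuleParams",
    "TissueState",
    "classify_element",
    "classify",
    "advance_front",
    "advance_fronts",
    "calcify_cartilage",
    "resorb_and_mature",
    "PrendergastParams",
    "PrendergastBand",
    "prendergast_classify",
]

_BONE_CODES = np.array([int(p) for p in BONE_PHENOTYPES])
_FILL_FULL = 1.0 - 1e-12


class Lineage(IntEnum):
    NONE = 0
    CHONDROGENIC = 1
    OSTEOGENIC = 2
    ADIPOGENIC = 3
    FIBROGENIC = 4


@dataclass
class RuleParams:
    """Differentiation-rule constants.

    ``tfr`` is the maximum tissue formation rate in mm^3 of new tissue per
    mm^2 of substrate per day; ``gamma_resorption`` the percent octahedral
    shear strain below which bone is resorbed; ``o2_cartilage_mmhg`` the
    hypoxia threshold for chondrogenesis; ``maturation_days`` the age at
    which immature bone becomes mature bone.
    """

    tfr: float = 1.0
    gamma_resorption: float = 0.005
    o2_cartilage_mmhg: float = 22.8
    maturation_days: int = 10
    calcification_stiffening: float = 2.0
    #: days a chondrogenic/fibrogenic stimulus must persist before the
    #: in-situ tissue change takes effect — the temporal-smoothing delay
    #: between a stimulus first acting on cells and the tissue changing.
    #: Front-driven lineages carry their own delay through the fill rate.
    in_situ_delay_days: int = 10

    def __post_init__(self) -> None:
        for name in ("tfr", "gamma_resorption", "o2_cartilage_mmhg",
                     "calcification_stiffening"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.maturation_days < 1:
            raise ValueError("maturation_days must be >= 1")
        if self.in_situ_delay_days < 0:
            raise ValueError("in_situ_delay_days must be >= 0")


@dataclass
class TissueState:
    """Per-element tissue bookkeeping carried between iterations.

    ``fill`` is 1 for a fully formed tissue; while a front lineage is active
    it is the fraction of the element occupied by the incoming tissue.
    """

    phenotype: np.ndarray
    fill: np.ndarray
    lineage: np.ndarray
    days_immature: np.ndarray
    #: strain-shielded since last resorption: osteogenic re-entry suppressed
    #: until local strain rises back above the resorption threshold, so a
    #: resorbed region is not refilled the next day by the same front and
    #: the marrow front can recanalise it
    resorbed: Optional[np.ndarray] = None

    @classmethod
    def initial(cls, mesh: Mesh) -> "TissueState":
        """All-granulation callus, marrow body and cortex per region label."""
        from .geometry import REGION_CORTICAL, REGION_MARROW

        phen = np.full(mesh.n_elems, int(Phenotype.GRANULATION), dtype=np.int64)
        phen[mesh.region == REGION_CORTICAL] = int(Phenotype.CORTICAL_BONE)
        phen[mesh.region == REGION_MARROW] = int(Phenotype.MARROW)
        return cls(
            phenotype=phen,
            fill=np.ones(mesh.n_elems),
            lineage=np.full(mesh.n_elems, int(Lineage.NONE), dtype=np.int64),
            days_immature=np.zeros(mesh.n_elems, dtype=np.int64),
        )

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        self.fill = np.asarray(self.fill, dtype=float)
        self.lineage = np.asarray(self.lineage, dtype=np.int64)
        self.days_immature = np.asarray(self.days_immature, dtype=np.int64)
        if self.resorbed is None:
            self.resorbed = np.zeros(self.phenotype.shape[0], dtype=bool)
        else:
            self.resorbed = np.asarray(self.resorbed, dtype=bool)
        if np.any(self.fill < -1e-12) or np.any(self.fill > 1.0 + 1e-12):
            raise ValueError("fill outside [0, 1]")
        if np.any(self.days_immature < 0):
            raise ValueError("negative maturation counter")

    def copy(self) -> "TissueState":
        return TissueState(
            self.phenotype.copy(),
            self.fill.copy(),
            self.lineage.copy(),
            self.days_immature.copy(),
            self.resorbed.copy(),
        )


# ----------------------------------------------------------------------
def classify_element(
    phenotype: Phenotype,
    o2_mmhg: float,
    supplied: bool,
    neighbors: Sequence[Tuple[Phenotype, float]],
    params: RuleParams,
    resorbed: bool = False,
) -> Lineage:
    """Lineage decision for a single element.

    ``neighbors`` lists (phenotype, fill) of the face-adjacent elements.
    Hypoxia selects chondrogenesis regardless of substrate; osteogenesis and
    adipogenesis additionally require a blood supply and a completed stiff
    (bone) or soft (marrow) substrate neighbour.  Already differentiated
    tissue (bone, marrow, cartilage awaiting calcification, cortex) returns
    ``NONE``; vascularised calcified cartilage next to bone is eligible for
    osteogenic replacement (endochondral ossification).

    ``resorbed`` marks an element that lost bone to strain-threshold
    resorption and is still strain-shielded: osteogenic re-entry is
    suppressed there (bone formed would be resorbed again immediately),
    which lets the marrow front recanalise resorbed endosteal regions.
    """
    phenotype = Phenotype(phenotype)
    osteo_ok = not resorbed
    bone_nb = any(
        Phenotype(p) in BONE_PHENOTYPES and f >= _FILL_FULL for p, f in neighbors
    )
    marrow_nb = any(
        Phenotype(p) == Phenotype.MARROW and f >= _FILL_FULL for p, f in neighbors
    )
    if phenotype == Phenotype.CALCIFIED_CARTILAGE:
        if supplied and bone_nb and osteo_ok:
            return Lineage.OSTEOGENIC
        return Lineage.NONE
    if phenotype not in (Phenotype.GRANULATION, Phenotype.FIBROUS):
        return Lineage.NONE
    if o2_mmhg < params.o2_cartilage_mmhg:
        return Lineage.CHONDROGENIC
    if supplied and bone_nb and osteo_ok:
        return Lineage.OSTEOGENIC
    if supplied and marrow_nb:
        return Lineage.ADIPOGENIC
    return Lineage.FIBROGENIC


def _neighbor_masks(state: TissueState, mesh: Mesh):
    nb = mesh.neighbors
    valid = nb >= 0
    nb_safe = np.where(valid, nb, 0)
    nb_phen = state.phenotype[nb_safe]
    nb_full = state.fill[nb_safe] >= _FILL_FULL
    bone = valid & nb_full & np.isin(nb_phen, _BONE_CODES)
    marrow = valid & nb_full & (nb_phen == int(Phenotype.MARROW))
    return bone, marrow  # (E, 4) per-face masks


def classify(
    state: TissueState,
    mesh: Mesh,
    o2_elem: np.ndarray,
    supplied: np.ndarray,
    params: RuleParams,
) -> np.ndarray:
    """Vectorised daily lineage assignment for every element."""
    bone_f, marrow_f = _neighbor_masks(state, mesh)
    bone_nb = bone_f.any(axis=1)
    marrow_nb = marrow_f.any(axis=1)
    hypoxic = np.asarray(o2_elem) < params.o2_cartilage_mmhg
    supplied = np.asarray(supplied, dtype=bool)
    osteo_ok = ~state.resorbed
    phen = state.phenotype

    lineage = np.full(mesh.n_elems, int(Lineage.NONE), dtype=np.int64)
    undiff = np.isin(phen, [int(Phenotype.GRANULATION), int(Phenotype.FIBROUS)])
    lineage[undiff] = int(Lineage.FIBROGENIC)
    lineage[undiff & supplied & marrow_nb] = int(Lineage.ADIPOGENIC)
    lineage[undiff & supplied & bone_nb & osteo_ok] = int(Lineage.OSTEOGENIC)
    lineage[undiff & hypoxic] = int(Lineage.CHONDROGENIC)
    calc = phen == int(Phenotype.CALCIFIED_CARTILAGE)
    lineage[calc & supplied & bone_nb & osteo_ok] = int(Lineage.OSTEOGENIC)
    return lineage


# ----------------------------------------------------------------------
def advance_front(
    fill: float,
    substrate_face_area: float,
    element_volume: float,
    params: RuleParams,
    dt: float,
) -> float:
    """Fill increment of a single front element over ``dt`` days."""
    if element_volume <= 0.0:
        raise ValueError("element volume must be positive")
    return min(1.0, fill + params.tfr * substrate_face_area * dt / element_volume)


def _front_rates(state: TissueState, mesh: Mesh, front_mask: np.ndarray) -> np.ndarray:
    """Per-element fill rate (1/day) from completed substrate faces."""
    bone_f, marrow_f = _neighbor_masks(state, mesh)
    osteo = state.lineage == int(Lineage.OSTEOGENIC)
    adipo = state.lineage == int(Lineage.ADIPOGENIC)
    area = np.zeros(mesh.n_elems)
    area[osteo] = (mesh.face_area * bone_f)[osteo].sum(axis=1)
    area[adipo] = (mesh.face_area * marrow_f)[adipo].sum(axis=1)
    rates = np.zeros(mesh.n_elems)
    rates[front_mask] = area[front_mask] / mesh.volume[front_mask]
    return rates


def advance_fronts(
    state: TissueState,
    mesh: Mesh,
    o2_elem: np.ndarray,
    supplied: np.ndarray,
    params: RuleParams,
    dt: float = 1.0,
) -> int:
    """Event-driven daily integration of the osteogenic and marrow fronts.

    Elements whose lineage is osteogenic or adipogenic gain fill at
    ``TFR * (completed substrate face area) / volume``.  When an element
    completes, its phenotype switches (immature bone or marrow), and
    unsaturated eligible neighbours are re-sensed immediately so that the
    front can cross several elements per day; this removes the element-size
    dependence of the front speed.  Returns the number of completions.
    """
    supplied = np.asarray(supplied, dtype=bool)
    hypoxic = np.asarray(o2_elem) < params.o2_cartilage_mmhg
    osteo_ok = ~state.resorbed
    undiff = np.isin(
        state.phenotype, [int(Phenotype.GRANULATION), int(Phenotype.FIBROUS)]
    )
    calc = state.phenotype == int(Phenotype.CALCIFIED_CARTILAGE)
    # a newly assigned front starts from an empty fill: fill == 1 on an
    # unconverted element is the stale value of the previous tissue
    front0 = np.isin(
        state.lineage, [int(Lineage.OSTEOGENIC), int(Lineage.ADIPOGENIC)]
    )
    state.fill[front0 & (state.fill >= _FILL_FULL)] = 0.0
    completions = 0
    t_rem = dt
    guard = 0
    while t_rem > 1e-12:
        guard += 1
        if guard > mesh.n_elems + 100:
            raise RuntimeError("front integration failed to terminate")
        front_mask = np.isin(
            state.lineage, [int(Lineage.OSTEOGENIC), int(Lineage.ADIPOGENIC)]
        )
        rates = params.tfr * _front_rates(state, mesh, front_mask)
        active = front_mask & (rates > 0.0)
        if not active.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            t_complete = np.where(active, (1.0 - state.fill) / rates, np.inf)
        step = min(t_rem, float(t_complete.min()))
        state.fill[active] = np.minimum(1.0, state.fill[active] + rates[active] * step)
        t_rem -= step
        done = active & (state.fill >= _FILL_FULL)
        if not done.any():
            continue
        for e in np.nonzero(done)[0]:
            new_phen = (
                Phenotype.IMMATURE_BONE
                if state.lineage[e] == int(Lineage.OSTEOGENIC)
                else Phenotype.MARROW
            )
            state.phenotype[e] = int(new_phen)
            state.fill[e] = 1.0
            state.lineage[e] = int(Lineage.NONE)
            state.days_immature[e] = 0
            completions += 1
            # re-sense: the completed element is now a substrate its
            # neighbours can respond to within the remaining day fraction
            target = (
                Lineage.OSTEOGENIC
                if new_phen == Phenotype.IMMATURE_BONE
                else Lineage.ADIPOGENIC
            )
            for nb in mesh.neighbors[e]:
                if nb < 0:
                    continue
                if state.lineage[nb] in (
                    int(Lineage.OSTEOGENIC),
                    int(Lineage.ADIPOGENIC),
                    int(Lineage.CHONDROGENIC),
                ):
                    continue
                if not supplied[nb] or hypoxic[nb]:
                    continue
                if target == Lineage.OSTEOGENIC and not osteo_ok[nb]:
                    continue
                eligible = undiff[nb] or (
                    calc[nb] and target == Lineage.OSTEOGENIC
                )
                if eligible:
                    state.lineage[nb] = int(target)
                    state.fill[nb] = 0.0
        undiff = np.isin(
            state.phenotype, [int(Phenotype.GRANULATION), int(Phenotype.FIBROUS)]
        )
        calc = state.phenotype == int(Phenotype.CALCIFIED_CARTILAGE)
    return completions


# ----------------------------------------------------------------------
def calcify_cartilage(state: TissueState, mesh: Mesh) -> int:
    """Stiffen cartilage face-adjacent to completed bone; returns count."""
    bone_f, _ = _neighbor_masks(state, mesh)
    target = (state.phenotype == int(Phenotype.CARTILAGE)) & bone_f.any(axis=1)
    state.phenotype[target] = int(Phenotype.CALCIFIED_CARTILAGE)
    state.fill[target] = 1.0
    return int(target.sum())


def resorb_and_mature(
    state: TissueState,
    gamma_pct: np.ndarray,
    params: RuleParams,
    mesh: Mesh,
    r_endosteal: float,
) -> Tuple[int, int]:
    """Strain-threshold bone resorption and 10-day maturation.

    Bone (immature or mature, never cortical) with octahedral shear strain
    below ``gamma_resorption`` reverts: endosteal elements (centroid radius
    inside ``r_endosteal``) become granulation, re-colonisable by the marrow
    front (recanalisation of the medullary cavity); periosteal and gap
    elements become fibrous background.  Surviving immature bone ages by one
    day and matures at ``maturation_days``.  Returns (resorbed, matured).
    """
    gamma_pct = np.asarray(gamma_pct)
    bone = np.isin(
        state.phenotype, [int(Phenotype.IMMATURE_BONE), int(Phenotype.MATURE_BONE)]
    )
    resorb = bone & (gamma_pct < params.gamma_resorption)
    endo = mesh.centroid[:, 0] < r_endosteal
    state.phenotype[resorb & endo] = int(Phenotype.GRANULATION)
    state.phenotype[resorb & ~endo] = int(Phenotype.FIBROUS)
    state.fill[resorb] = 1.0
    state.lineage[resorb] = int(Lineage.NONE)
    state.days_immature[resorb] = 0
    # the resorbed flag persists while the element stays strain-shielded
    state.resorbed[gamma_pct >= params.gamma_resorption] = False
    state.resorbed[resorb] = True

    immature = state.phenotype == int(Phenotype.IMMATURE_BONE)
    state.days_immature[immature] += 1
    mature = immature & (state.days_immature >= params.maturation_days)
    state.phenotype[mature] = int(Phenotype.MATURE_BONE)
    state.days_immature[mature] = 0
    return int(resorb.sum()), int(mature.sum())


# ----------------------------------------------------------------------
class PrendergastBand(IntEnum):
    RESORPTION = 0
    BONE = 1
    CARTILAGE = 2
    FIBROUS = 3


@dataclass
class PrendergastParams:
    """Constants of the shear-strain / fluid-velocity comparator stimulus.

    ``S = gamma/a + v/b`` with gamma in percent and v in um/s.  The band
    thresholds are external inputs from the classic mechano-regulation
    literature, not fitted here.  A stimulus exactly on a band edge belongs
    to the lower-stimulus band.
    """

    a: float = 3.75
    b: float = 3.0
    s_resorption: float = 0.01
    s_cartilage: float = 1.0
    s_fibrous: float = 3.0

    def __post_init__(self) -> None:
        if self.a <= 0.0 or self.b <= 0.0:
            raise ValueError("stimulus normalisers a, b must be positive")
        if not (0.0 < self.s_resorption < self.s_cartilage < self.s_fibrous):
            raise ValueError("band thresholds must be increasing and positive")


def prendergast_classify(
    gamma_pct: np.ndarray,
    v_um_s: np.ndarray,
    params: PrendergastParams,
) -> np.ndarray:
    """Band assignment of the combined biophysical stimulus (vectorised)."""
    S = np.asarray(gamma_pct) / params.a + np.asarray(v_um_s) / params.b
    out = np.full(np.shape(S), int(PrendergastBand.RESORPTION), dtype=np.int64)
    out = np.where(S > params.s_resorption, int(PrendergastBand.BONE), out)
    out = np.where(S > params.s_cartilage, int(PrendergastBand.CARTILAGE), out)
    out = np.where(S > params.s_fibrous, int(PrendergastBand.FIBROUS), out)
    return out
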