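# Methods

## Model overview and assumptions

The simulated system is a transverse mid-diaphyseal fracture of a long bone
with a 3 mm gap, an external callus, and axial weight-bearing. The domain
is axisymmetric in (r, z), with z = 0 at the fracture mid-plane and a
symmetric half-model (the full-gap problem is mirror-symmetric about the
mid-plane). Cortex: internal Ø 14 mm, external Ø 20 mm; external callus
Ø 28 mm. The callus — fracture gap, endosteal (intramedullary) callus and
external callus ring — starts as granulation tissue; the marrow body and
cortex are pre-existing, pre-vascularised tissue.

Core hypothesis: mechanics never acts on stem cell fate directly. The
daily load event only gates angiogenesis (no vessel progression through
elements whose octahedral shear strain exceeds `γ_angio`), which in turn
shapes the oxygen field; phenotype is decided by oxygen tension and by
adjacency to completed bone or marrow tissue (the "substrate").
Small-strain linear kinematics, isotropic linear-elastic solid skeleton,
intrinsically incompressible constituents with a small storage term, and
one quasi-static load event per day are assumed throughout.

## Tunable parameters

| parameter | symbol | unit | default | role |
|---|---|---|---|---|
| angiogenic diffusion coefficient | `H` | mm²/day | 0.5 | speed of vessel progression |
| angiogenic strain threshold | `γ_angio` | % | 6 | gate: no vessel progression above it |
| oxygen diffusion coefficient | `G` | m²/s | 2.2e-9 | oxygen in blood/tissue |
| oxygen consumption rate | `Q` | fmol/cell/hr | 98 | constant per-cell consumption |
| maximum cell density | `n_max` | cells/mm³ | 5e3 | scales consumption |
| initial oxygen tension | `O2_init` | mmHg | 74.1 | initial field and vascular Dirichlet value |
| hypoxia threshold | `O2_cartilage` | % atm | 3 (= 22.8 mmHg) | chondrogenesis trigger |
| tissue formation rate | `TFR` | mm³/mm²/day | 1 | bone/marrow front speed |
| resorption strain limit | `γ_res` | % | 0.005 | bone below it is resorbed |
| maturation age | — | days | 10 | immature → mature bone |
| peak load / ramp | — | N, s | 300, 0.5 | daily weight-bearing event |
| cell motility / proliferation | `D_cell`, `p` | mm²/day, 1/day | 0.34, 0.6 | Fisher–KPP colonisation |
| smoothing window | `W` | days | 10 | material-update delay |

Biphasic material properties per phenotype (Young's modulus 0.2–20 000 MPa,
permeability 1e-17–1e-11 mm², Poisson ratio 0.167/0.3, porosity 0.8 except
cortical 0.04, fluid viscosity 1e-9 N·s/mm²) follow the standard
poroelastic fracture-healing property set; calcified cartilage is cartilage
stiffened by a factor two (E = 20 MPa). The working unit system is
mm–N–s–MPa: the printed viscosity is read as N·s/mm², which makes the
Darcy mobility k/μ of granulation tissue 1e-14 m⁴/(N·s), the value used
throughout the poroelastic callus-model literature.

The oxygen solubility α = 1.0268 µmol/(L·mmHg) (Henry's law, aqueous medium
at 37 °C) converts consumption to tension units; 1 µmol/L = 1000 fmol/mm³,
so the sink is `Q·24·n·n_max/(1000·α)` ≈ 1.15e4 mmHg/day at full cell
density. Dissolved oxygen therefore turns over in minutes and the oxygen
field is quasi-steady on the daily time scale, with an anoxic penetration
depth of ≈ 1.6 mm around vascularised tissue — hypoxia develops wherever
colonised tissue is more than a couple of millimetres from a supply.

## Geometry choices

The callus outline is not fully dimensioned by the physiology, so its
shape is a modelling choice: an elliptical arc from the 28 mm callus
diameter at the fracture plane back to the cortex surface at
`callus_axial_extent` = 14 mm, with a blunt tip (15% of the maximal ring
width) so every element keeps positive width; the endosteal callus extends
`endosteal_extent` = 5 mm into the medullary cavity; 15 mm of cortical
shaft is modelled beyond the gap. The axial extents were chosen so that
under the initial all-granulation compliance the upper periosteal callus
lies below the 6% angiogenic gate while the gap region lies far above it —
the mechanical precondition for the observed healing cascade (early
periosteal ossification away from the gap, inhibition near it). Linear
kinematics exaggerate the early-callus strains (the day-1 cortex-end
displacement exceeds the physical gap), which a large-displacement solver
would cap; the extended callus compensates within the linear framework.

## Numerical methods

**Biphasic FE.** u–p mixed formulation on quadrilaterals: biquadratic
(9-node) displacements, bilinear (4-node) pressure (Taylor–Hood, inf-sup
stable), 3×3 Gauss quadrature with 2πr weighting, monolithic backward
Euler over the 0.5 s ramp in 10 steps (halving the step changes γ by
< 1%, tested). Storage = porosity / K_water (K = 2300 MPa). Stimuli are
evaluated at element centroids at the end of the ramp: octahedral shear
strain `γ_oct = (2/3)√Σ(εᵢ−εⱼ)²` from principal strains, relative fluid
velocity as the Darcy flux magnitude `(k/μ)|∇p|`. The solver reproduces
the Terzaghi consolidation series to < 0.2% on a 50-element column.

**Transport.** All three scalar fields share an axisymmetric bilinear FE
kernel with lumped (row-sum) mass and implicit Euler substeps — monotone
(discrete maximum principle) on near-unit-aspect meshes; thin elements at
the callus tip can violate monotonicity marginally, and the field updates
clamp to physical bounds. The angiogenic gate is a hard on/off diffusivity
(a sigmoidal gate is available behind `smooth_gate`). The oxygen floor
O2 ≥ 0 is enforced as a discrete obstacle problem by an active-set
iteration (nodes that would go negative are clamped at zero and the step
re-solved), which keeps the diffusion–consumption balance correct next to
sources instead of letting the constant sink drive the far field to large
negative values. Cell dynamics use implicit diffusion with an explicit
logistic source; the travelling front speed matches 2√(D·p) within ~11%
at the test discretisation.

**Tissue fronts.** Front fill is integrated event-driven within each day:
all active elements advance at `TFR·A_substrate/V` until the first
completion, the completed element converts and its neighbours are
re-sensed with the remaining fraction of the day. This is the exact limit
of per-day sub-iterations and makes the crossing time of a strip exactly
`length/TFR`, independent of discretisation. A newly assigned front
lineage starts from zero fill; a lineage change aborts an unfinished front
(fill resets).

**Delays.** Front-driven lineages (bone, marrow) are delayed intrinsically
by the fill rate. In-situ conversions (cartilage, fibrous tissue) take
effect only after the stimulus persists for the temporal-smoothing delay
(10 days, tied to the smoothing window) — representing the lag between a
stimulus first acting on cells and the tissue type changing. Without this
delay cartilage would appear on day 1, before any bone.

**Material update.** Per day and element,
`P_day = n·P_phenotype + (1−n)·P_granulation` (rule of mixtures in the
normalised cell density), averaged over the trailing 10-day window —
arithmetically for modulus, Poisson ratio and porosity, geometrically for
permeability, which spans six orders of magnitude and would otherwise be
dominated by a single stiff day. Cortical bone keeps fixed properties.

**Resorption re-entry.** Bone below `γ_res` is resorbed: endosteal
elements (centroid inside the medullary radius) revert to granulation and
are re-colonisable by the marrow front (recanalisation); periosteal and
gap elements revert to fibrous tissue. A resorbed element is flagged while
it remains strain-shielded and the osteogenic pathway cannot re-enter it
(bone formed there would resorb again immediately); the flag clears if the
local strain rises back above `γ_res`. Without this rule the osteogenic
front re-captures resorbed elements in a two-day limit cycle and the
marrow cavity is never restored. In the zero-load limit the model then
behaves as the rules dictate: vessels pervade the callus unhindered, the
fronts form bone, and every bone element is resorbed as it forms.

**Stopping rule.** A run ends when the phenotype map has been unchanged
for 14 consecutive days or at `max_days` = 126; healing is the first day
the whole gap is completed bone, anything else is a non-union.

**Model B (comparator).** The same daily loop with phenotype set in situ
from `S = γ/a + v/b` (a = 3.75%, b = 3 µm/s; band edges 0.01 / 1 / 3
belong to the lower-stimulus band). The band constants are external
inputs from the classic mechano-regulation literature, not calibrated
here.

## Problem sizes

The package's reduced runs use 0.75 mm elements for the baseline cascade
(~400 elements, ~20 s for 126 days) and 1.0 mm elements for sensitivity
sweeps (~240 elements); the default configuration meshes at 0.25 mm. The
staged-cascade results are stable across 1.0/0.75/0.6 mm (healing day
54–55, identical event ordering).

## What the reduced runs do and do not show

The runs demonstrate the qualitative content of the hypothesis: the staged
healing cascade and its ordering, non-union under a lowered angiogenic
threshold or an overload, monotone-saturating response to the angiogenic
diffusivity and the tissue formation rate, and the dip-and-recovery oxygen
time course. Exact healing days are implementation- and
discretisation-sensitive (they shift by a few days between resolutions)
and are not comparable at day-level precision to any particular animal
experiment. Real calluses also grow (the external boundary here is fixed),
carry bending/torsion loads, contain haematopoietic marrow, and regulate
chondrocyte fate through factors beyond oxygen — none of which is
modelled.

## Known limitations

Linear small-strain kinematics overestimate early-callus strains
(documented above); consumption kinetics are zeroth-order in oxygen above
the floor; angiogenesis is a continuum diffusion surrogate for discrete
sprouting; cell populations are a single normalised density; healed-state
strains sit close to the resorption threshold, so late remodelling
proceeds as sustained element-level resorption/recanalisation activity
rather than wholesale removal of the periosteal callus within the
simulated window.
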