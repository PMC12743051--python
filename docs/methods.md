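# Model description and methods

`redoxbox` is a zero-dimensional (box) model of the coupled carbon,
phosphorus, sulfur, and oxygen cycles of the Precambrian ocean–atmosphere
system, built to simulate the redox aftermath of a snowball-Earth
deglaciation: the super-greenhouse climate, the weathering and nutrient
pulse, the transient rise of atmospheric O₂ and oceanic sulfate, and the
sulfur-isotope anomalies recorded by buried pyrite.

## Reservoirs and structure

Fourteen molar inventories are integrated: O₂ in a combined
atmosphere–surface-ocean box (O_AS) and in the deep ocean (O_D); total
inorganic carbon in the atmosphere–surface box (A); atmospheric CH₄ (M);
phosphate in surface and deep boxes (P_S, P_D); sulfate in surface and deep
boxes (S_S, S_D); whole-ocean Ca²⁺ and surface alkalinity (ALK); and four
crustal reservoirs — organic carbon (G), carbonate (C), pyrite (PYR), and
gypsum (GYP).  Six isotope deltas (δ³⁴S of seawater sulfate, gypsum, and
pyrite; δ¹³C of A, G, and C) are carried with linear (per-mil mixing)
arithmetic, which is accurate to ≪ 0.1‰ for |δ| < 60‰.

The surface box holds 3% of a 1.37 × 10¹⁸ m³ ocean; the deep box exchanges
with it on a 1000-yr ventilation timescale.  Both volumes and the
ventilation time are configurable; none is observationally pinned for the
Paleoproterozoic, and the results are insensitive to factor-of-two changes
because all sulfur sources and sinks act on the surface box.

Gas partitioning is diagnostic: pO₂ is the atmosphere-column equivalent of
O_AS (dissolved O₂ is < 0.1% of the pool at all simulated states); pCO₂
follows from A by a linear Henry-law + bicarbonate partition in which
surface alkalinity is constant (carbonate burial is slaved to the
alkalinity supplied by silicate and carbonate weathering, the usual
instantaneous-compensation closure).  Carbonate-ion speciation is neglected
— the simulated ocean is acidic at every state of interest.

## Climate

Global mean surface temperature balances absorbed shortwave,
(1 − α) L S₀ / 4 with α = 0.3, against a linearised OLR:

    OLR = a + b (T − 288 K) − RF_CO₂ − RF_CH₄
    RF_CO₂ = c₁ ln(p/p*) + c₂ ln²(p/p*),   RF_CH₄ = c_m ln(1 + p_CH₄/p_m0)

c₁ = 7.72 W m⁻² per e-fold is the standard modern CO₂ forcing slope; the
quadratic term captures the super-logarithmic forcing of thick CO₂
atmospheres.  `a` closes the modern reference (288 K at 280 ppm, full
luminosity); b = 0.973 W m⁻² K⁻¹ (≈ 5.5 K per doubling, appropriate for a
paleo-calibrated sensitivity) and c₂ = 0.305 W m⁻² are set so that a
0.7-atm CO₂ atmosphere under 83% luminosity equilibrates near 330 K.
Ice–albedo feedback is omitted: the simulator only ever runs on the
deglaciated branch.  Because the OLR is linear in T the balance inverts in
closed form; the public `surface_temperature` additionally offers a
bracketed root solve with explicit out-of-range failures.

## Weathering, phosphorus, and productivity

Silicate and carbonate weathering follow the Walker feedback,
F ∝ weatherability · f_a · (pCO₂/pCO₂*)^0.3 · exp((T − T*)/13.7 K), with
relative land area f_a = 0.48.  Weatherability (the biotic/soil
enhancement factor relative to today) is calibrated to 0.1098 — "roughly
12% of present" — so that the spin-up equilibrium sits at the reported
~0.087 atm of CO₂; CO₂ degassing is fixed at the modern 6 Tmol C/yr scaled
by the carbonate reservoir.

Riverine reactive-P input scales with the silicate weathering flux, with
two Paleoproterozoic factors:

* a delivery efficiency of 0.088 relative to modern at equal weathering
  flux, representing the weak P yield of unvegetated crust.  This number
  is the single most consequential calibration in the model: it sets the
  pre-glacial organic burial flux (~1.3 Tmol C/yr) and thereby the net
  biospheric O₂ source, which must sit marginally below the reductant sink
  (below) for a stable Archean-like low-O₂ state to exist at
  F_red = 0.075 Tmol O₂-eq/yr;
* a super-linear response (exponent 1.4) of P delivery to *transient*
  weathering pulses, representing the disproportionate nutrient yield of
  finely ground post-glacial regolith.  It controls how strongly a given
  CO₂ perturbation translates into an O₂ overshoot and was calibrated
  against the reported overshoot thresholds (~0.15 atm for > 0.01 PAL,
  ~0.5 atm for > 0.1 PAL).

Export production is P-limited (uptake of surface P at 0.5 yr⁻¹,
Redfield C:P = 106; modern reference 400 Tmol C/yr); organic burial scales
with the square of relative export production (the COPSE convention) and is
normalised to 4.5 Tmol C/yr today.  P burial follows the redox-dependent
C/P ratio: CP_sea = k_anox·k_oxic / ((1−anox)·k_anox + anox·k_oxic) with
k_anox = 200, k_oxic = 60, and the ocean anoxic fraction
anox = max(1 − k1 (pO₂/pO₂*)/(F_pp/F_pp*), 0), k1 = 0.997527.  A fixed
CP_sea = 60 is available as a configuration switch for the low
C_org/P_reac sensitivity case.

## Oxygen, methane, and the reductant budget

O₂ is produced by the burial of organic carbon and of pyrite (2 mol O₂ per
mol pyrite-S) and consumed by oxidative weathering of organic carbon and
pyrite, organic-carbon degassing, photochemical CH₄ oxidation, hydrogen
escape bookkeeping, and the oxidised fraction of the interior reductant
flux F_red.  Oxidative weathering of organic carbon uses the same Monod
form in pO₂ as the pyrite law (half-saturation 0.017 of present) scaled by
weatherability and land area.

Methane is produced as a fixed fraction (10%) of anaerobic deep-ocean
remineralisation, oxidised photochemically at a rate proportional to
pO₂/(pO₂ + 10⁻⁴ PAL), and lost to space by diffusion-limited hydrogen
escape (2.8 × 10⁻⁷ yr⁻¹ of the CH₄ column).  At the low-O₂ state this
yields ~35 ppm of CH₄, a few W m⁻² of greenhouse forcing, and an escape
flux of a few 10⁻³ Tmol/yr.  Reductants from the interior are oxidised by
O₂ with a Monod efficiency (half-saturation 3.6 × 10⁻⁷ PAL); the
unoxidised remainder is assumed lost as H₂ to space.

The stable pre-glacial state emerges from this budget rather than being
imposed: net biospheric O₂ production (burial margin plus escape) is
balanced by the oxidised reductant flux at pO₂ ≈ 10⁻⁶ PAL for
F_red = 0.075 Tmol O₂-eq/yr, and at ≈ 10⁻⁷ PAL — with a
correspondingly CH₄-richer atmosphere — for F_red = 0.3.

### Why "permanent" oxidation is possible

A strict fixed point of the full system (crustal reservoirs included)
cannot stay oxidised: conservation forces the crust to bury reductants at
the rate F_red forever.  The model resolves this the way the ~10⁸-yr
spin-up design implies: the crustal organic and carbonate reservoirs relax
over ~10⁹ yr and are therefore *boundary reservoirs* on the spin-up slow
manifold — they are held at their initial (modern-scale) inventories
during spin-up, and their relative tendencies (≲ 5 × 10⁻¹¹ yr⁻¹) satisfy
the steady-state criterion (10⁻¹⁰ yr⁻¹).  The resulting pre-glacial state
carries a persistent net organic-burial margin of ~0.05 Tmol O₂-eq/yr.
After a large perturbation this margin, together with the sulfur "battery"
charged during the overshoot (oceanic sulfate plus a freshly deposited
gypsum reservoir that re-releases sulfur for pyrite burial over its
~9 × 10⁷-yr lifetime), sustains pO₂ above 10⁻³ PAL through 10⁸ years under
F_red = 0.075, while F_red = 0.3 drains the same battery within a few
10⁷ years and returns the system below 10⁻⁶ PAL.  The initial seawater
Ca²⁺ is set to 20.6 mM (Precambrian oceans were calcium-rich), which
controls how much of the sulfate peak is parked in gypsum.

## Sulfur cycle

The sulfur flux laws are: degassing of gypsum and pyrite proportional to
reservoir size (0.5 and 0.3 Tmol S/yr at the 150 × 10¹⁸ and 250 × 10¹⁸ mol
references); gypsum weathering proportional to reservoir size and the
relative carbonate weathering flux (1.6 Tmol S/yr at reference); pyrite
oxidative weathering with a Monod pO₂ dependence (1.3 Tmol S/yr at
reference; half-saturation 0.017 of present pO₂, normalisation 1.017, land
fraction f_a); gypsum burial bilinear in relative [Ca²⁺] and [SO₄²⁻]
(2.1 Tmol S/yr at reference); and pyrite burial proportional to relative
[SO₄²⁻] and organic burial and inversely proportional to relative pO₂ —
the COPSE shorthand for microbial sulfate reduction, with the pO₂ ratio
floored at 10⁻¹⁰ to cap the anoxic amplification.  The modern pyrite
burial reference is taken as F_vpyr* + F_wpyr* = 1.6 Tmol S/yr, the value
required for modern steady-state closure; all starred constants are
configuration-exposed.  Total sulfur S_S + S_D + PYR + GYP is conserved
identically by construction.

## Isotopes

Fractionation is attributed entirely to microbial sulfate reduction:
pyrite buries at δ³⁴S_sw − Δ_MSR with the Michaelis–Menten law
Δ_MSR = Δ_max [SO₄]/([SO₄] + K_MSR) (nominally Δ_max = 40‰,
K_MSR = 0.2 mM); gypsum buries at seawater composition.  Seawater sulfate
carries one δ³⁴S for both boxes.  All spin-up sulfur starts at the mantle
value (0‰).  Organic carbon buries at δ¹³C_A − 25‰; CO₂ injected at the
deglaciation reset carries −5‰.  Mass-weighted isotope moments are
conserved exactly by the tendency algebra (to integrator tolerance in a
run); reservoirs below 10¹² mol have their delta derivative frozen to
avoid 0/0.

The reported buried-pyrite curve δ³⁴S^b_pyr = δ³⁴S_sw − Δ_MSR is the
*instantaneous* burial composition, not the sediment-reservoir mean — the
sharp early excursions exist only in the instantaneous signal.

## Numerics

The 20-variable system is stiff (timescales from ~2 yr for surface P to
~10⁹ yr for the crust) and is integrated with LSODA at rtol 10⁻⁸ (10⁻⁷ in
ensembles) and per-component absolute tolerances; output is sampled on a
logarithmic grid (default 400 points, 10²–10⁸ yr).  Halving the tolerances
moves the minimum buried-pyrite δ³⁴S by < 0.5‰ and the O₂ overshoot by
< 5%.

Spin-up is performed as a damped Newton (Powell hybrid) solve of the
tendency function in log-space — brute-force integration cannot converge
the crustal pools — preceded by a 3 × 10⁷-yr relaxation integration that
brings the fast variables onto the slow manifold, and followed by a
verification integration confirming stationarity.  Total sulfur closes the
solve exactly through the pyrite pool; isotope deltas, which carry a
global shift symmetry at any fixed point, are pinned afterwards by moment
conservation.  Perturbation experiments reset pCO₂ by adding carbon to A
(alkalinity untouched), mixing the mantle δ¹³C into the pool.

The Monte Carlo ensemble (pCO₂ init uniform 0.08–0.8 atm; initial pyrite
uniform 50–500 × 10¹⁸ mol; K_MSR log-uniform 0.02–2 mM; Δ_max uniform
10–60‰; F_red = 0.075) re-uses spin-ups from a 20-point grid in the
initial pyrite inventory, interpolated linearly — the steady state varies
near-linearly with PYR and the interpolation error is below 2% per
reservoir against direct spin-ups.  Results are ordered by sample index
and failures are flagged, never dropped.  The default test-suite and
acceptance ensembles use 2000 members; the full 10⁴-member design is
available through the CLI (`redoxbox ensemble --n 10000`).

## What the simulations do and do not show

The generator of scenarios *is* the study design: the boundary conditions,
initial inventories, and parameter ranges above.  Passing tests show the
coupled network reproduces the designed equilibria, thresholds, and
anomaly statistics; they do not validate the model against the
stratigraphic record itself (bulk δ³⁴S_pyr data carry diagenetic and
depositional overprints outside this model's scope), nor outside the
sampled ranges.

## Known limitations

* The predecessor C–P–O₂–CH₄ core is reconstructed from standard COPSE-
  style laws and calibrated to printed anchors; its emergent overshoot
  thresholds land at 0.17/0.40 atm against the reported ~0.15/0.5 atm
  (within the ~20% reconstruction tolerance), and the accepted-set minimum
  pCO₂ of the rejection analysis is correspondingly shifted high by
  ~0.03 atm.
* No AOM, no explicit H₂S or Fe speciation, no pyrite-acid carbonate
  weathering, no nutrient competition with Fe-phototrophs, no salinity
  stratification, and no simulation of the glaciation itself.
* The low-O₂ branch under F_red = 0.075 is marginally subcritical by
  construction; modest parameter changes (±5% in the P delivery
  efficiency) can destabilise it.  This mirrors the physical situation —
  permanent oxidation after a transient requires the pre-glacial state to
  sit near criticality — but it makes the calibration delicate.
* Deep-ocean P is carried unchanged through the deglaciation reset; the
  post-glacial nutrient state is otherwise unconstrained.
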