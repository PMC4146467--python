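# Methods

## The model

`saspnet` implements a discrete, synchronous, multi-valued logical network
of the signaling pathway that the egg peptide **speract** activates in sea
urchin sperm flagella, culminating in oscillatory intracellular calcium
(Ca²⁺) that steers the flagellar beat. The network has **21 nodes**:

| node | levels | meaning |
| --- | --- | --- |
| Speract | 0/1 | extracellular ligand (self-sustaining input) |
| SR | 0/1 | speract receptor |
| GC | 0/1 | guanylate cyclase |
| cGMP | 0/1 | cyclic GMP |
| PDE | 0/1 | phosphodiesterase (cGMP degradation) |
| KCNG | 0/1 | cGMP-gated K⁺ channel |
| NHE | 0/1 | Na⁺/H⁺ exchanger |
| HCN | 0/1 | hyperpolarization-activated cation channel |
| cAMPCC | 0/1 | cAMP-gated Ca²⁺-permeable channel |
| LVA | 0/1/2 | low-voltage-activated Ca²⁺ channel (inactive/closed/open) |
| HVA | 0/1/2 | high-voltage-activated Ca²⁺ channel (inactive/closed/open) |
| CaCC | 0/1 | Ca²⁺-dependent Cl⁻ channel |
| CaKC | 0/1 | Ca²⁺-dependent K⁺ channel |
| CaP | 0/1 | Ca²⁺ pump |
| NCE | 0/1 | Na⁺/Ca²⁺ exchanger |
| dK, dNa, dCl, dCa | 0/1 | aggregate permeability changes per ion |
| V | 0/1/2 | membrane potential (hyperpolarized/rest/depolarized) |
| Ca | 0/1/2 | intracellular Ca²⁺ (basal/tonic/supratonic) |

Exactly four nodes are ternary (V, LVA, HVA, Ca); the state space has
2¹⁷ · 3⁴ = 10,616,832 states. Calcium has seven regulators (LVA, HVA,
cAMPCC, CaP, NCE, dCa, Ca), so its truth table has 2⁴·3³ = **432 rows**.

All nodes update **synchronously**: state(t+1) is obtained by applying
every node's truth table to state(t). Attractors are therefore cycles of
the deterministic map; the wild-type network has attractors of periods 4
and 8, and channel clamps reshape the attractor landscape.

## Reconstruction of the truth tables

The original model's complete truth tables were distributed as
supplementary text files that are not redistributable here. This package
therefore ships a **synthetic reconstruction** (`src/saspnet/sasp.py`,
fixture `src/saspnet/data/sasp_synthetic/`): the wiring diagram, node
arities and activating/inhibiting character of every interaction follow
the published architecture, but each table entry is generated from an
explicit physiological *balance rule* written by this package, not
transcribed.

The mechanism encoded (one level of change per step):

1. **Adapting upstream arm.** Speract → receptor → guanylate cyclase →
   cGMP; cGMP induces PDE, which latches active, so cGMP is a single
   transient pulse and the cGMP-gated K⁺ channel (KCNG) closes again.
   The upstream arm reaches a fixed point; sustained oscillations are
   generated downstream. This is deducible from the reported perturbation
   periods (4, 8, 7, 9, 3 share no common divisor, ruling out a shared
   upstream pacemaker; and a permanently open KCNG would mask every CaKC
   clamp through the shared K⁺ permeability node dK).
2. **Voltage loop.** K⁺ (KCNG or CaKC) and Cl⁻ (CaCC) currents
   hyperpolarize V; NHE and HCN are active away from depolarization and
   the HCN Na⁺ current depolarizes V back. V moves one level toward the
   dominant current balance and relaxes toward rest on a tie.
3. **Voltage-gated Ca²⁺ channels** are three-state machines
   (inactive/closed/open). LVA fires exactly at rest and recovers at or
   below rest; HVA fires only at depolarization and recovers only at
   hyperpolarization; both inactivate immediately after one open step.
4. **Calcium balance.** Influx counts LVA-open, HVA-open and cAMPCC;
   efflux counts the pump (supratonic threshold), the exchanger
   (facilitated by hyperpolarization) and calcium's own inactivation.
   Ca moves one level with the balance and decays one level on a tie.

### Identification protocol

The free constants of these balance rules (firing/recovery voltages,
channel thresholds, tie behaviour, current weights) were selected by a
bounded grid search (three passes, ~50k mechanistically labeled variants;
see `scratch/` scripts, not part of the package) scored **only** against
qualitative attractor-periodicity statements for the wild type and the
channel-clamp scenarios: WT periods {4, 8}; CaKC block leaves the period
set unchanged; CaCC block simplifies it; constitutive CaKC yields a
period-7 signature; the triple block-plus-activation scenario yields
period 3; HCN block introduces new modes. Quantitative basin fractions,
transient statistics and the response-direction table were **held out**
of the identification and used only as validation afterwards. The frozen
rules were not modified after validation.

### Residual discrepancies (known and deliberate)

The reconstruction reproduces the wild-type period set {4, 8} exactly,
transients ≤ 27 steps, the CaKC-block invariance, the period-7 signature
under constitutive CaKC, and period 3 under the triple
block-plus-activation. It does **not** reproduce:

- the reference basin weights: here period 8 dominates (≈ 93.5% of 10⁵
  speract-activated initial conditions) over period 4 (≈ 6.5%), the
  reverse of the reference split. Basin sizes depend on fine table
  structure that balance rules do not pin down;
- the triple-blockage (HCN⁻CaCC⁻CaKC⁻) coexistence of periods 8 and 9
  (and hence the 72-step ensemble module). With all three channels
  clamped and KCNG adapted, the only remaining V-regulating current is
  dCa, leaving a short Cav/V/Ca loop whose natural period is small; the
  reconstruction gives period 4 there. This appears structurally out of
  reach for any single-step balance-rule encoding;
- consequently, several cells of the response-direction table (most
  visibly the triple-blockage column) point the other way.

These discrepancies are reported, not patched: the corresponding checks
in `tests/test_acceptance.py` fail honestly against the reconstruction.

## Analyses

- **Attractors and basins** (`saspnet.dynamics`). States are encoded as
  mixed-radix int64 codes; for networks up to 2²⁴ states the full
  transition map is precomputed, and attractors are found by vectorized
  probing with first-return period detection and a two-pointer transient
  measurement. Basin statistics come either from exhaustive enumeration
  or from i.i.d. sampled initial conditions (`ICPolicy`; all pathway
  analyses pin Speract = 1 and draw every other node uniformly).
- **Perturbations** (`saspnet.perturbations`). A knockout clamps a node
  to 0 and a constitutive activation clamps it to 1 from t ≥ 1 onward.
  `scenario_suite()` yields the 12 analysed scenarios: wild type, the
  single clamps HCN⁻, CaCC⁻, CaKC⁻, CaKC⁺, all pairwise combinations,
  and the two triples HCN⁻CaCC⁻CaKC⁻ and HCN⁻CaCC⁻CaKC⁺.
- **Ensemble traces** (`saspnet.ensemble`). The mean Ca level over 10⁵
  random speract-activated initial conditions, iterated 1200 steps with
  the first 150 discarded as transient (the measured maximum transient is
  29 across all scenarios, so 150 is conservative).
- **Spectra and envelopes** (`saspnet.spectral`). Plain periodogram of
  the mean-centered ensemble trace, trimmed to a multiple of its
  recurrent module and Parseval-normalized; dominant lines are reported
  with harmonic attribution and a mode-diversity count. Running averages
  with window *w* remove any component whose period divides *w*; the
  *recurrent module* of a series is the smallest shift p with
  max|x[t+p] − x[t]| below tolerance.
- **Response-direction table** (`saspnet.reporting`). For each scenario,
  mean, peak-to-trough amplitude, peak value and Fourier mode diversity
  of the steady-state Ca trace are compared against the wild type and
  rendered as up / = / down.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  sampled quantity is bitwise reproducible for a fixed seed.
- Equality tolerances: recurrent-module detection uses an absolute
  tolerance of 1e-9 on the ensemble mean; spectral lines below an
  absolute power floor of 1e-18 are treated as silence.
- Default parameters: 10⁵ initial conditions, 1200 ensemble steps with
  150 discarded, 1000-step spectra, 50-step summary window.

## Scope and limitations

- Synchronous updating only; asynchronous schedules are out of scope.
- The reconstruction is a faithful mechanism encoding, not a transcription
  of the original tables; quantitative basin/direction statistics differ
  as detailed above.
- `saspnet.synthetic` provides random and signed-random network
  generators used by the property-based tests; they are test
  infrastructure, not biological models.
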