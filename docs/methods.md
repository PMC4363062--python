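# Methods

`ankledose` computes organ equivalent doses and the ICRP-103 effective
dose in the ankle region from point-dosimeter (MOSFET-style)
measurements in a layered anthropomorphic leg phantom, propagates a
complete measurement-uncertainty budget, and can generate fully
synthetic studies for testing the pipeline end to end.

## Dose model

For each tissue T the equivalent dose is

    H_T = w_R * sum_i f_i * D_Ti        [Sv; reported in uSv]

with `w_R = 1 Sv/Gy` for x-rays, `f_i` the *fraction irradiated* — the
fraction of the whole-body organ (by mass, area, or node count) lying
in the exposed, dosimetrically evaluated region — and `D_Ti` the mean
absorbed dose of the dosimeters representing sub-unit *i* (mGy,
averaged over repeated exposures with a sample-SD spread). The
effective dose is

    E = sum_T w_T * H_T

with the ICRP-103 tissue weighting factors. Muscle and lymphatic nodes
are the only leg tissues in the ICRP-103 *remainder* set of 13 tissues
that share a collective weight `w_rem = 0.12`; each remainder member
present contributes `(w_rem / 13) * H_T`. The divisor 13 (the full
remainder set size, not the number of members present) is a deliberate
design choice: it treats the shared weight as split over the whole
ICRP set, and it is the convention under which the shipped
configuration reproduces the published per-tissue contributions.

Readings are stored in mGy; the single mGy→uSv conversion happens in
the equivalent-dose step. Report values are rounded half-up (0.1 uSv
for doses, integer percent for uncertainties and shares) at display
only; all arithmetic is unrounded.

### Aggregation modes

How member dosimeter doses combine into a sub-unit contribution is
declared per fraction entry:

* **mean_then_fraction** (bone marrow): several dosimeters sample one
  bone at different depths/layers; c = f * mean(members).
* **per_site_fraction** (skin, bone surface): each site carries the
  full fraction; c = f * dose, summed over sites.
* **group_mean** (muscle, lymphatic nodes): one entry for the tissue;
  c = f * mean(members).

For the bone surface this choice is genuinely ambiguous — averaging
the two tuberosity dosimeters instead of summing them halves H_T. The
shipped default uses per-site fractions (each tuberosity dosimeter
weighted 0.049) because that is the only reading consistent with the
published bone-surface contribution; both modes are available through
the fraction-table configuration.

### Shipped configuration

The default phantom has six 25 mm layers (indices 23–28, kept verbatim
from the physical phantom's numbering) and twenty dosimeters: ten in
bone marrow (tibia ×4, fibula ×2, navicular, talus, metatarsals,
calcaneus), four in muscle, two in skin, two on the bone surface and
two in lymphatic tissue. The default fraction table assigns 19 of the
20; the talus marrow dosimeter carries no published fraction and is
reported as *unused* rather than silently folded into a bone group
(inclusion is a one-line config edit).

Fraction provenance: marrow 1.1 % of whole-body marrow mass in the
region (0.7 % calf from MRI volumetry + 0.4 % foot from cadaver data),
distributed per bone (the per-bone values sum to 1.2 %; the table keeps
them as published rather than rescaling); bone surface 4.9 % (ICRP 70
surface-to-volume ratios with ICRP 89 skeletal mass fractions); skin
3.5 % of the Du Bois-Du Bois whole-body area (layer perimeters × 25 mm
plus foot planimetry); muscle 0.9 % of a 28 kg whole-body muscle mass;
lymphatic nodes 1 % per ankle (lymphoscintigraphy estimate). The
bone-surface and muscle percentages rest on external anatomical data
and ship as cited constants; the marrow, skin and Du Bois helpers are
implemented so alternative anatomies can be evaluated. The marrow
fractions assume 100 % red marrow; no red/yellow split is applied,
which tends to overestimate the marrow contribution.

Du Bois-Du Bois: BSA[m²] = 0.007184 · W[kg]^0.425 · H[cm]^0.725, the
standard published constants, grouped in one named tuple so an
alternate BSA model can be swapped.

## Uncertainty budget

All uncertainties are relative (percent, 1SD) and combine in
quadrature ("weighted sum of variances", the GUM convention).

* **Type A** — sample SD of the repeated exposures relative to the
  mean, no √n reduction (the budget describes a single measurement,
  not the mean's standard error).
* **Point dose** — u_c = sqrt(typeA² + 10² + 10² + 5² + 1²): phantom
  positioning, dosimeter positioning, x-ray source variation, cable
  irradiation. Defaults are configurable per study.
* **Tissue dose** — every contribution term additionally carries the
  fraction-irradiated uncertainty u_f = 25 %; independent terms
  combine as u_T = sqrt(Σ (c_i·sqrt(u_i²+u_f²))²) / Σ c_i.
* **Effective dose** — the same dose-weighted quadrature over tissue
  terms (c_T = w_T·H_T), expanded by a coverage factor k (default 2,
  ≈95 %).

**Correlation granularity.** Dosimeters enter the tissue quadrature as
independent terms — their placements, readings and local fraction
errors are physically distinct — with one exception: the two
bone-surface dosimeters sit on the same calcaneal tuberosity and are
treated as fully correlated (dose-weighted mean point uncertainty, a
single fraction term). The tissue level is where this choice bites:
full independence would let the two bone-surface terms partially
cancel (≈21 %) while per-site correlation keeps the tissue at
sqrt(16²+25²) ≈ 30 %. The shipped default (independent everywhere,
bone surface correlated) is the only combination consistent with all
published tissue-level values; the correlated set is a parameter of
`build_budget`.

The reported *remainder* uncertainty pools the muscle and lymph terms
in one quadrature, since they share a single collective weight.

## Synthetic studies

The generator emulates the statistical structure of real extremity
scans, not their physics:

* **Dose field** — phenomenological two-exponential model: inside the
  FOV, dose = peak · exp(−μ·depth) with a per-tissue typical depth
  (skin 0 mm … marrow 30 mm); outside, the in-field edge value ×
  `out_of_field_fraction` decaying exponentially with distance.
  Defaults (peak 10 mGy, μ = 0.01 /mm, fraction 0.1, decay 0.09 /mm)
  give the ≈40× in-to-out-of-field spread seen between field-centre
  and field-edge dosimeters. A tiny positivity floor (peak × 1e-15)
  keeps the far scatter tail from underflowing to zero. No spectra,
  detector response or voxel anatomy are modelled.
* **Reading noise** — multiplicative Gaussian: reading = true·(1+ε),
  ε ~ N(0, σ_rel(true)), with σ_rel(D) = floor + scale / D^power.
  Defaults floor = 4 %, scale = 7.25 %·mGy, power = 1 hit the observed
  anchors (≈33 % at 0.25 mGy, ≈5 % above 4 mGy). An inverse-dose law
  was preferred over an inverse-square-root law because no
  non-negative floor lets 1/√D satisfy both anchors; power = 0.5
  recovers the square-root form if wanted. Negative draws are
  truncated at zero and counted (logged and stored in the readings
  table's attrs), never silently dropped.
* **Determinism** — every random draw goes through a seeded
  `numpy.random.Generator`; identical seeds give byte-identical
  fixture bundles.

Because the synthetic noise is purely statistical while the expanded
uncertainty also carries the systematic components, coverage of the
±U_c (k=2) interval in synthetic recovery runs is expected near 100 %
(asserted ≥85 %). Passing recovery tests therefore demonstrate
pipeline correctness and calibration plumbing, not that real
systematic errors are as modelled. Recovery runs use 200 seeded
studies of 20 dosimeters × 6 exposures, a size chosen to bound the
Monte-Carlo error on the bias check well below the noise level while
keeping the suite fast.

## Numerical and edge-case choices

* Sample SD uses the n−1 denominator; a single exposure leaves the
  type-A term undefined (`None`) and the budget refuses to build on it
  rather than assuming zero.
* A zero mean with nonzero spread leaves the relative SD flagged
  undefined; an all-zero dosimeter reports 0 %.
* Percentages of E are computed from unrounded contributions, then
  rounded half-up; their displayed sum may differ from 100 by up to 2
  rounding units. E = 0 makes the breakdown undefined (error, not NaN).
* Fold ratios display as nearest-integer "n-fold" at ≥10 and one
  decimal below.
* A region skin area exceeding the whole-body area is an error unless
  capping is explicitly requested.

## Known reproduction gaps

Running the engine on the published mean doses of the high-resolution
small-FOV CBCT protocol gives a bone-marrow contribution of ≈4.2 uSv
against the published 3.9 (≈7 % high; whether the talus dosimeter or
per-layer sub-fractions entered the original marrow average is not
recoverable), hence E ≈ 14.6 uSv against the published 14.3. The
published per-tissue uncertainty values are reproduced to within ±1
point except skin (25 % vs 26 %), and the expanded k=2 effective-dose
uncertainty to 32 % exactly. These gaps are asserted with explicit
tolerances in the test suite rather than patched.
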