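# woundfield

Steady-state volume-conductor modelling of electric fields around a skin
wound, for designing direct-current electrostimulation (electrotherapy)
electrode layouts.

Intact epithelium maintains a transepithelial potential (TEP) of tens of
millivolts between the epidermis and the dermis.  A wound short-circuits
this battery and drives an endogenous current out of the wound bed — the
field that guides cell migration (electrotaxis) during healing.
Electrotherapy tries to reinforce that field with surface electrodes.
`woundfield` models both situations on the same geometry: a four-layer skin
cylinder (stratum corneum, epidermis, dermis, subcutis; 5.514 mm total)
with a conical wound (4 mm mouth, full-thickness apex) immersed in
phosphate-buffered saline (PBS), and answers the questions a designer
cares about: how strong is the field at the wound edge, do the driven
current loops circulate the same way as the endogenous ones, and how much
Joule heat is deposited in each layer.

## Model

Under steady DC the potential V obeys the conduction equation

    ∇ · (σ ∇V) = 0

with piecewise-constant conductivity σ per tissue/medium (relative
permittivities are carried as metadata; they play no role in the resistive
steady state).  Electrodes are ideal equipotential (Dirichlet) patches —
including the internal epidermis–dermis plane at +30 mV for the endogenous
TEP — and all other boundaries carry zero flux.  The derived outputs are
E = −∇V, the current density J = σE, the volume-averaged dissipation
density Q = ⟨σ|E|²⟩ per layer, and its safety conversion to surface power
(q·t, in mW/cm²).

Axisymmetric layouts are solved with linear finite elements on a mapped
structured triangulation of the (r, z) half-plane that conforms exactly to
every layer interface and to the wound cone; the non-axisymmetric
side-by-side pad layout (geo5) uses a finite-volume voxel grid with
harmonic-mean face conductances.  Both paths reproduce layered 1-D
conduction to machine precision (see `woundfield.validation`).

Seven stimulation scenarios are built in:

| name         | description                                                        |
|--------------|--------------------------------------------------------------------|
| `endogenous` | TEP battery: grounded intact surface, +30 mV epidermis–dermis plane |
| `geo1`       | grounded 4 mm electrode covering the wound bed, +30 mV on all intact skin |
| `geo2`       | grounded 3 mm disc at the wound mouth, 0.5 mm ring gap              |
| `geo3`       | grounded wound-bed electrode, 2 mm ring gap                         |
| `geo4`       | grounded 3 mm disc, 2.5 mm ring gap                                 |
| `geo5`       | ±30 mV pads covering each side of the intact skin, nothing on the wound |
| `geo5_air`   | geo5 with the surrounding buffer replaced by air                    |

## Worked example

```python
import woundfield as wf

sol, report = wf.run_scenario("endogenous")
print(f"max |E| at wound edge: {report.max_EF_mV_per_mm:.1f} mV/mm")
print(f"current loops:         {report.loop_pattern}")
for layer, q in report.joule_density_W_per_m3.items():
    print(f"  {layer:<16s} Q = {q:8.3f} W/m^3")
```

prints

```
max |E| at wound edge: 107.8 mV/mm
current loops:         two_loop_endogenous_like
  stratum corneum  Q =    9.060 W/m^3
  epidermis        Q =    2.212 W/m^3
  dermis           Q =    0.957 W/m^3
  subcutis         Q =    0.056 W/m^3
```

The wound-edge maximum sits at the mouth of the wound (x ≈ 8 and 12 mm on
the 0–20 mm diameter axis) and is close to the 1-D estimate 30 mV /
0.314 mm ≈ 96 mV/mm — the TEP dropped across corneum + epidermis.  The
corneum, six orders of magnitude more resistive than the dermis, absorbs
most of the dissipation; converted to surface power (≈ 1.3 × 10⁻⁵ mW/cm²)
it is far below the 40 mW/cm² skin-safety threshold, so 30 mV stimulation
is thermally harmless.  `two_loop_endogenous_like` means the driven current
circulates out of the wound and back through the intact skin symmetrically
on both sides, the pattern a therapeutic layout should mimic
(`geo5` instead yields `single_loop`: current sweeps sideways across the
wound).

A command-line front end wraps the same pipeline:

```sh
woundfield run -s geo1 -s geo2 -o out/        # profiles + metrics CSVs
woundfield validate                            # oracle suite
woundfield sweep -s geo1 --resolutions 0.4,0.2,0.1
woundfield compare out/metrics.csv             # vs packaged reference table
```

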