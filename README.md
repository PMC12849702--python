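# fernspike

Terrestrial ecosystem disruption at the onset of the Paleocene–Eocene
Thermal Maximum (PETM, ~56 Ma), from microscope slide to global carbon
cycle. The PETM opens with a 3–4 ‰ negative carbon isotope excursion (CIE)
in δ¹³C, marking a massive input of ¹³C-depleted carbon. In expanded
marine-margin sections, pollen and spores record what happened on land at
the same time: conifer swamp forests collapse and disturbance-adapted ferns
spike within the first centimetres above the CIE base — a classic
"fern spike". `fernspike` is for palynologists and paleoclimate modellers
who want to quantify that signal, put it on a time axis, and ask what it
means for the global carbon budget.

The package covers four stages:

1. **Assemblage quantification** (`fernspike.assemblage`). From raw counts:
   relative abundances as % of the terrestrial pollen+spore sum,
   absolute concentrations via exotic-marker (*Lycopodium*) normalisation,

   c = n · N_spike / (n_Lyc · w)   [grains g⁻¹ dry sediment],

   microcharcoal as % of total palynofacies, and fold changes of interval
   mean concentrations.
2. **Chronology** (`fernspike.chronology`). Annual diatom laminae give
   sedimentation rates (s [cm ky⁻¹] = annual thickness [µm yr⁻¹] / 10);
   thickness/rate arithmetic turns stratigraphic intervals into durations
   with tephra beds subtracted; the CIE base (first anomalously low δ¹³C
   value) is detected and used to align multiple sites at h = 0.
3. **Carbon-cycle box model** (`fernspike.carboncycle`). Five reservoirs
   (atmosphere, surface ocean, deep ocean, plant, soil) with full δ¹³C
   mass balance, forced by an endogenic carbon injection and three
   terrestrial feedbacks: an imposed collapse of gross primary productivity
   (GPP) with slow linear recovery, Q10 soil respiration, and kerogen
   (rock organic carbon) weathering amplified by the biosphere deficit:

   F_ker = F_ker,0 · (1 + γ · d),   d = 1 − (M_plant + M_soil)/(M_plant,0 + M_soil,0).

4. **Synthetic records & experiment suites** (`fernspike.synthetic`,
   `fernspike.experiments`). A generator with realistic counting statistics
   (Poisson totals, multinomial composition, Poisson marker counts) makes
   every stage testable without any external data; suites chain the stages
   end to end.

## Worked example

```python
from fernspike import (SyntheticSiteSpec, generate_site, default_group_map,
                       relative_abundance, concentration, fold_change,
                       detect_cie_base, sampling_resolution, duration_range)

spec = SyntheticSiteSpec(seed=1)          # U1567B-like synthetic section
record = generate_site(spec)
groups = default_group_map()

base = detect_cie_base(record.d13c)
print(f"CIE base detected at {base:.2f} mbsf")

spike_sample = next(s for s in record.samples
                    if base - 0.5 < s.depth_mbsf < base and not s.tephra_flag)
pct = relative_abundance(spike_sample, groups)
print(f"fern spores at {spike_sample.depth_mbsf:.2f} mbsf: "
      f"{pct['fern']:.1f} % of the terrestrial assemblage, "
      f"{concentration(spike_sample, 'fern', groups):,.0f} grains/g")

fc = fold_change(record, "fern", (base + 0.01, base + 1.0),
                 (base - 1.0, base - 0.01), groups)
print(f"fern concentration fold change across the CIE base: {fc:.0f}x")

step_y, window_y = sampling_resolution(4.0, 0.5, 40.0)
print(f"sampling resolution at 40 cm/ky: {step_y:.0f}-y steps, "
      f"{window_y:.1f} y per slice")
lo, hi = duration_range(5.0, 7.5, 20.0, 40.0, excluded_cm=1.5)
print(f"vegetation-shift duration: {lo:.1f}-{hi:.0f} y")
```

Output:

```
CIE base detected at 80.24 mbsf
fern spores at 79.76 mbsf: 45.9 % of the terrestrial assemblage, 76,471 grains/g
fern concentration fold change across the CIE base: 55x
sampling resolution at 40 cm/ky: 100-y steps, 12.5 y per slice
vegetation-shift duration: 87.5-300 y
```

Reading it: the detector places the CIE base exactly where the generator
put it (80.24 mbsf). One spike-phase sample counts 45.9 % fern spores
(the latent value is 40 %; a 300-grain count has a binomial sd of ~2.8
points, and marker normalisation adds concentration scatter). The interval
mean concentrations rise ~55-fold across the base for this seed (~70-fold
in expectation). At 40 cm ky⁻¹, 4-cm sampling resolves 100-year steps of
12.5 years each, and a 5–7.5 cm shift interval containing a 1.5-cm ash bed
corresponds to at most 300 years of elapsed time.

The box model runs from a shell, too:

```sh
fernspike calibrate            # injection d13C for a 3.5 permil control CIE
fernspike simulate --reduction 0.5 --out scratch/run50
fernspike fig4 --out scratch/fig4
```

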