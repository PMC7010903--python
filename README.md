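# celldose

Cellular dosimetry of ¹⁷⁷Lu-DOTATATE radionuclide therapy in vitro: Monte
Carlo cellular S values for realistic cell geometries, MIRD-formalism
absorbed dose to the nucleus over a 4-h uptake plus 6-day colony-forming
experiment, and linear / linear-quadratic dose–response analysis.

For peptide receptor radionuclide therapy (PRRT), correlating clonogenic
survival with *absorbed dose to the nucleus* — rather than with added
activity — requires cellular dosimetry that respects cell morphology and
sub-cellular source localisation.  The core quantity is the **S value**,
the absorbed dose to the nucleus per decay in a source compartment
(medium M, cell membrane CS, cytoplasm Cy, or Golgi G), combined through the
MIRD formalism:

    D(N) = Ã_M·S(N←M) + Ã_CS·S(N←CS) + Ã_C·S(N←C)

where Ã are cumulated activities (Bq·s) per interval,
Ã = f·A₀·(e^(−λ_p T₁) − e^(−λ_p T₂))/λ_p, with f the measured decay-corrected
compartment fraction and λ_p the ¹⁷⁷Lu decay constant.  Survival is fitted as
SF = exp(−αD − βD²) with AIC model selection.

The package is organised as an analysis project: every computation lives in
the library under `src/celldose/` (electron spectrum and range–energy tables,
cell geometries, the straight-line CSDA transport engine, uptake kinetics,
dose assembly, dose–response fits, and a synthetic-data generator that stands
in for the unpublished raw measurements), and the numbered scripts under
`analysis/` are thin drivers that write tables to `results/`.

## Worked example

Compute self- and cross-dose S values for the average flat adherent cell
(3500 µm³ body, 1050 µm³ nucleus) and the dose-per-decay hierarchy:

```python
import celldose as cd

engine = cd.TransportEngine()                      # packaged Lu-177 spectrum
cell = cd.TruncatedConeCell.reference()            # flat adherent cell
for source in ("Cy", "CS", "G"):
    s = engine.self_s_value(cell, source, n_histories=100_000, seed=1)
    print(f"S(N<-{source}) = {s.value:.3e} +- {s.stderr:.1e} Gy/(Bq s)")

layout = cd.layout_monolayer(cell, gap=0.0, cutoff_um=280.0)
cross = engine.cross_s_value(cell, layout, "Cy", n_histories=100_000, seed=2)
print(f"total cross S(N<-Cy), touching monolayer = {cross.value:.3e}")
```

prints

```
S(N<-Cy) = 1.343e-04 +- 1.3e-06 Gy/(Bq s)
S(N<-CS) = 9.247e-05 +- 1.1e-06 Gy/(Bq s)
S(N<-G) = 1.069e-04 +- 1.2e-06 Gy/(Bq s)
total cross S(N<-Cy), touching monolayer = 1.127e-04
```

The cytoplasm delivers the highest dose per decay to the nucleus (it
surrounds it closely in a flattened cell), the Golgi sits in between, and the
membrane — spread over the whole footprint — the least.  The cross-dose from
all touching neighbours within the 280-µm electron range is of the same order
as the self-dose under straight-line transport (see `docs/methods.md` for why
this is an upper bound), and collapses by ~84% when cells sit one diameter
apart and ~99% at five diameters.

The analysis sequence reproduces the study's tables from the package:

```
python analysis/01_published_table_checks.py   # printed-table arithmetic
python analysis/02_svalue_parameter_study.py   # volume/source/shift/proximity MC
python analysis/03_uptake_kinetics.py          # synthetic uptake fits
python analysis/04_absorbed_dose.py            # MIRD dose per scenario
python analysis/05_dose_response.py            # linear vs LQ with AIC
```

For example, `01` reports that relocating the internalized source from the
cytoplasm to the Golgi raises the nuclear self-dose by +64% on average (up to
+149% for one cell), and that spherical cell models predict a ~3× higher
cumulative dose than mesh-reconstructed cells for the same kinetics; `02`
shows the self S value falling exponentially with cell volume (R² ≈ 0.98,
+55% from 3500 to 1900 µm³) and a 16–38% drop of S(N←G) when the nucleus
moves 1–3 µm away from the Golgi.

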