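# osteoquant

Multi-modal quantification of bone–implant systems, built as a tested,
reusable pipeline with synthetic phantoms so every stage is verifiable by
parameter recovery:

- **morphometry** — degradation rate `DR = (Vi − Vr)/(Ai·t)` (mm/year),
  bone-to-implant contact `BIC = A/Ad` (%), and bone volume fraction
  `BV/TV` inside a 200 µm peri-implant ROI, from labeled 3D volumes
  (background / bone / degradation layer / residual metal) plus a
  registered pre-implantation screw mask. Surface areas by 6-connectivity
  exposed-face counting, validated against exhaustive brute-force
  enumeration.
- **elemental_maps** — XRF map segmentation (bone / degradation layer /
  empty from Ca and Gd presence, Otsu-based rules, Gd precedence),
  pixelwise Ca/P, Gd/P, Gd/Ca ratios, and mean-ratio profiles vs distance
  from the implant interface or from blood-vessel walls, with 95 %
  normal-approximation confidence intervals per bin.
- **scattering** — azimuthal (radial-q) integration of flat-detector
  frames; mineral platelet thickness `T = 4Q/(πP)` from the stack-of-cards
  model (Porod plateau + invariant with low-q closure and analytic high-q
  tail); (002) Gaussian peak fit → Bragg d-spacing and Scherrer
  crystallite size.
- **la_icp_ms** — laser-ablation ICP-MS quantification: gelatin-standard
  calibration (static or piecewise-linear drift between standard scans),
  CPS→ppm conversion, per-channel limit of detection `LOD = mean + 3·SD`
  over a control area, percentile-rule region classification
  (implant-channel visibility, Ca/P below 50 %, Fe below 20 % of the
  99.9th-percentile cutoffs) and per-region statistics including % pixels
  above LOD.
- **phantoms** — deterministic generators for all four modalities with
  exactly known ground truth: an eroded threaded screw with degradation
  shell and partial bone apposition (truth from continuous geometry),
  element maps with controllable Ca/P-vs-distance profiles and a
  Gd-bearing layer, Debye–Scherrer rings with Scherrer-consistent widths,
  two-phase SAXS patterns whose `T` is exact by construction, and
  multi-channel CPS scans with piecewise-constant ppm regions, Poisson
  noise and linear calibration drift.
- **io / config / pipeline / cli** — TIFF / two-column-text / CSV readers
  and writers, YAML config with strict key checking, and an end-to-end
  synthetic demo pipeline that writes a reproducibility manifest.

## CLI

```sh
oq simulate --modality screw --seed 1 --out phantoms_out
oq morpho --labels phantoms_out/labels.tif --ref phantoms_out/reference.tif --days 61
oq xrf profile --ca ca.tif --p p.tif --gd gd.tif --pixel-um 0.5 --bin-um 1 --max-um 30
oq saxs fit-t --pattern saxs.txt
oq waxs fit-002 --frame frame.tif --geometry geom.txt
oq litm report --channels scans/ --standards standards.csv --pixel-um 15
oq run --seed 1 --out results   # end-to-end synthetic pipeline + manifest
```

Units are fixed at the boundaries: µm for pixel/voxel sizes and distances,
nm for d / τ / T, nm⁻¹ for q, mm/year for DR, ppm (mg/kg) for
concentrations.

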