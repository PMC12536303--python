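# octamorph

Inter-frame OCT angiography (OCTA) and morphometry for layered skin and
mucosa — vessel density, vessel diameter and epithelial thickness — with a
synthetic speckle phantom that validates every stage against exact ground
truth.

## Who this is for

OCT angiography derives flow contrast without contrast agents: B-scans are
repeated at each slow-axis position (here J = 6 repeats, ΔT = 5 ms apart)
and moving blood decorrelates the speckle between repeats while static
tissue does not.  This package is for researchers quantifying
microvasculature and layer morphology from such repeated-B-scan volumes —
the motivating application is characterizing vulvar lichen sclerosus, where
vessel morphology changes and the dermal–epidermal junction (DEJ) can
become optically indistinguishable — and for anyone who needs a seedable
OCTA phantom with known vessels, layers and noise to benchmark a processing
chain.

## The statistic at the core

Per voxel, from the amplitudes |A_j| of the J repeats, the intensity-based
Doppler variance (IBDV) is

σ² = 1 − Σ_{j=1}^{J−1} |A_j||A_{j+1}| / Σ_{j=1}^{J−1} (|A_j|² + |A_{j+1}|²)/2

σ² ∈ [0, 1]: 0 for perfectly repeating frames, ≈ 1 − π/4 ≈ 0.215 for fully
decorrelated Rayleigh speckle; it is invariant under global amplitude
scaling.  Numerator and denominator are averaged over a small lateral
window before the ratio.  The chain is: IBDV per position → volume with a
noise-floor mask → en-face maximum-intensity projection → Mexican-hat
(negated Laplacian-of-Gaussian) vessel enhancement → binarization → density
(% of a region occupied by vessels) and skeleton/distance-transform
diameters (mean ± SD over many sample points).  In parallel, per B-scan:
surface detection → DEJ detection (missing where the boundary contrast is
below threshold, reproducing the sclerosis failure mode) → epithelial
thickness (median over A-scans).

See `docs/methods.md` for the model, parameters and design choices.

## Worked example

`examples/phantom_subject.yaml` defines a three-site synthetic subject whose
epithelium thins from 300 µm (labia majora) to 120 µm (labia minora), each
site carrying two decorrelating vessels of true diameters 273 and 195 µm
(true en-face density 37.5 %):

```bash
octamorph run --config examples/phantom_subject.yaml --outdir out
```

prints the morphometry report the pipeline wrote to `out/morphometry.csv`:

```
subject_id   group              site density_pct diameter_mean_um diameter_sd_um vuet_um
 phantom-A control      labia_majora     38.1104          224.543        37.7877  299.29
 phantom-A control interlabial_sulci     39.4287          236.073        39.9026 196.825
 phantom-A control      labia_minora     38.3789          223.722        38.4661 116.673
```

Reading it: recovered vessel density is within ~2 percentage points of the
true 37.5 %, mean diameters within one pixel (39 µm) of the true 234 µm,
and the epithelial thickness column reproduces the designed 300 → 200 →
120 µm thinning to within ~3 µm.  Setting `dej_contrast: 0` at a site (the
sclerosis-like loss of layer contrast) leaves that site's `vuet_um` cell
empty — rendered as an em-dash in the printed table.

Other subcommands: `octamorph simulate` (phantom YAML → HDF5 with ground
truth), `angio` (HDF5 → σ² volume + en-face TIFF), `quantify` (angiogram
TIFF → vessel metrics CSV), `summarize` (report CSV → stats JSON).  The
same functionality is available as a library (`octamorph.generate_speckle_frames`,
`compute_ibdv`, `assemble_volume`, `enface_mip`, `enhance_vessels`, …).

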