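# slicequant

Quantification pipeline for irradiated thin-cut tissue slice cultures.

Tumor slice cultures (TSC) and organotypic brain slice cultures (OBSC) are
300–500 µm vibratome-cut sections kept on membrane inserts — an ex vivo
model that preserves the original 3-D tissue architecture and is used to
study radiation response, e.g. after proton beam irradiation. Evaluating
such experiments means turning microscope images and plate readings into
numbers: how many DNA double-strand breaks persist per cell, how much of a
slice is necrotic, how many cells died each day in culture, whether the
automated counter agrees with a human, and whether the delivered dose was
actually uniform. `slicequant` implements that whole chain as a tested,
scriptable library with a thin CLI, plus synthetic-data generators that
produce every input with exact ground truth so each stage can be verified
end to end.

## What it computes

**γH2AX foci per nucleus.** Nuclei are segmented from the DAPI channel
(Otsu on the blurred channel; distance-transform watershed for touching
nuclei), filtered by area — strictly above 65 µm² — and by an exclusion
list that stands in for the manual rejection of mitotic/apoptotic cells.
Foci are counted as local maxima of the Gaussian-blurred γH2AX channel with
a relative prominence floor. Counts are normalised for nuclear
cross-section,

    cfoci_i = foci_i × (mean group nucleus area) / (area_i),

which removes the sampling bias of larger nuclei (a bigger cross-section
shows more of the damage in a 2-D section). For tissue without resolvable
foci, nuclei are scored binary positive/negative against slide background.

**Slice morphology.** RGB sections are unmixed by Beer–Lambert color
deconvolution (OD least squares onto stain vectors); the package reports the
necrotic fraction of H&E sections, DAB(CD44)- and DAPI-positive area
fractions, and assembles them into depth profiles (depth = slice index ×
500 µm) for Pearson correlation analysis.

**Plate assays.** LDH cytotoxicity with a terminal lysis step:
`total = lysis + Σ daily`, daily cell-death fraction `daily_i / total`,
survival `1 − cumulative death` (the fractions and the final survival sum
to 1 exactly). Resazurin (PrestoBlue) viability:
`A_s(571) − A_s(601) − [A_m(571) − A_m(601)]`, and day-1 normalisation.

**Statistics.** Bland–Altman bias, SD of differences and 95% limits of
agreement for paired counters; Pearson correlation matrices with exact-t
p-values; and a slice-clustered permutation test (difference of group means
of slice means, labels permuted across whole slices) for treatment effects
on nested per-nucleus data.

**Dose QA.** Radiochromic-film net OD → dose through a monotone calibration
curve, and lateral homogeneity `H = 100 × D2 / D98` over a region of
interest, against the ≥ 95% criterion.

## Worked example

Simulate a fluorescence scene and run the foci pipeline on it:

```sh
$ slicequant simulate scene --n-nuclei 12 --mean-foci 6 --seed 11 --out-dir demo
wrote scene with 12 nuclei, 64 foci to demo
$ slicequant foci --dapi demo/dapi.tif --gamma demo/gamma.tif \
      --pixel-size 0.25 --out demo/nuclei.csv
12 included nuclei, mean area 129.4 um^2, mean foci 5.33, mean cfoci 5.69
```

All 12 simulated nuclei were segmented and included (all areas exceed
65 µm²); the mean count of 5.33 foci per nucleus is the recovered version of
the simulated Poisson(6) damage load (64 foci / 12 nuclei), and the mean
cfoci of 5.69 differs from the raw mean because the area correction
up-weights counts in nuclei smaller than the 129.4 µm² group mean. The
per-nucleus table shows the correction at work — nucleus 1 is small
(76.3 µm²), so its 7 raw foci become 11.87 cfoci:

```
label,x,y,area_um2,foci,cfoci,included,reason
1,181.99,33.54,76.3125,7,11.869,True,none
2,54.13,44.90,116.875,5,5.536,True,none
...
```

The same works from Python:

```python
import slicequant as sq

dapi, gamma, truth = sq.generate_foci_scene(12, ("poisson", 6.0), seed=11)
params = sq.FociParams(pixel_size=0.25)
table, summary, labels, maxima = sq.analyze_scene(dapi, gamma, params)
```

Validating a counter against a second observer:

```sh
$ slicequant stats bland-altman --counts paired_counts.csv
{
  "bias": 0.164,
  "sd_diff": 4.872842413455697,
  "loa_low": -9.386771130373166,
  "loa_high": 9.714771130373165,
  "n": 500
}
```

Here the two counters disagree by 0.16 foci on average (no systematic
bias) with a difference SD of 4.87, so 95% of paired counts fall within
about ±9.5 foci of each other.

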