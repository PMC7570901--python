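# fragmode

Tools for comparing small-molecule fragmentation techniques in LC-HRMS/MS
non-target screening, built around the question of whether ultraviolet
photodissociation (UVPD, parameterized by laser reaction time in ms) yields
more informative MS2 spectra than the routine higher-energy collisional
dissociation (HCD, parameterized by collision energy) for organic
micro-pollutants in water.

The package is aimed at analytical chemists and informaticians running
reference-standard fragmentation campaigns: it predicts fragments in silico,
processes raw runs, annotates MS2 peaks, scores fragmentation quality per
technique, and selects structurally diverse compound panels.

## What it computes

**Combinatorial fragment prediction.** Fragments are enumerated by systematic
bond dissociation (no fragmentation rules): every deletion of one bond between
heavy atoms (tree depth 1), and one further deletion applied to each result
(depth 2). Ring-bond deletions yield connected ring-opened intermediates that
feed depth 2. Hydrogens stay attached; hydrogen rearrangement is represented by
six charge configurations applied to each unique fragment formula M:

[M]+, [M+H]+, [M+2H]+ (positive mode);  [M]−, [M−H]−, [M−2H]− (negative mode)

with m/z = monoisotopic mass + ΔH·m(H) − q·m(e), so a protonated species is
neutral mass + 1.007276 Da.

**Spectral processing.** mzML runs are centroided (intensity-weighted m/z,
apex intensity per local-maximum region), the precursor's extracted ion
chromatogram (XIC) is built at 10 ppm, its apex RT and trapezoidal AUC are
measured, and the three MS2 scans of highest master intensity (the precursor's
MS1 intensity at the MS2's RT) near the apex are kept per fragmentation mode.

**Annotation and scoring.** MS2 peaks are matched to predicted ions when both
a relative (default 10 ppm) and an absolute (default 0.02 Da) tolerance hold.
Per spectrum, with n_exp experimental peaks, n_match matched peaks and n_theor
predicted ions:

- Score 1 = n_match / n_theor
- Score 2 = n_match / n_exp
- Score 3 = Σ intensity(matched fragments) / intensity(MS1 precursor)

Mass-error distributions get a maximum-likelihood normal fit; per-compound
tables classify fragmentation behavior into four groups (poor with both /
preference for HCD / preference for UVPD / good with both).

**Chemical-space compound selection.** 1024-bit extended (path-based)
fingerprints, the pairwise Tanimoto distance matrix d = 1 − |A∩B|/|A∪B|,
k-means over the distance-matrix rows with elbow-method selection of k, and a
10×10 self-organizing map as an independent check of cluster separation.

A synthetic-run generator reproduces the acquisition design (MS1 100–800 m/z,
MS2 50–500 m/z, HCD CE ∈ {20, 35, 60}, UVPD reaction time ∈ {25…800} ms) with
planted fragments, chromatographic Gaussians, and seeded m/z / intensity noise,
so the entire pipeline is testable without instrument data.

## Worked example

```python
import fragmode as fm
from fragmode.chem import ChargeConfig

ions = fm.predicted_ion_table(fm.MODEL_COMPOUNDS["triadimenol"][0], "positive", 2)
print(f"{len(ions)} predicted ions")
mz = fm.ion_mz(fm.parse_formula("C2H2N3"), ChargeConfig.M_PLUS_2H)
print(f"triazolyl fragment [C2H2N3+H]+H+: m/z {mz:.4f} (nominal {fm.nominal_mz(mz)})")

spec = fm.FixtureSpec(          # synthetic run with one planted fragment
    smiles=fm.MODEL_COMPOUNDS["triadimenol"][0], polarity="positive",
    fragments=(fm.PlantedFragment("C2H2N3", ChargeConfig.M_PLUS_2H,
                                  tuple((str(m), 0.3) for m in fm.default_modes())),),
    seed=1,
)
run = fm.simulate_run(spec)
x = fm.xic(run, spec.precursor_mz)
rt, inten = x.apex()
print(f"precursor m/z {spec.precursor_mz:.4f}, apex at {rt:.2f} min, AUC {x.auc():.0f}")
top = fm.select_top_ms2(run, spec.precursor_mz, x)
sp = top[fm.FragMode("HCD", 35.0)][0]
matches = fm.match_fragments(sp, ions)
scores = fm.compute_scores(matches, sp, ions, x.intensity_at(sp.rt))
print(f"HCD@35CE: {scores.n_matched}/{scores.n_exp} peaks matched, "
      f"score1={scores.score1:.4f} score2={scores.score2:.2f} score3={scores.score3:.2f}")
```

prints

```
210 predicted ions
triazolyl fragment [C2H2N3+H]+H+: m/z 70.0400 (nominal 70)
precursor m/z 296.1160, apex at 10.00 min, AUC 368189
HCD@35CE: 1/1 peaks matched, score1=0.0048 score2=1.00 score3=0.30
```

The depth-2 table for triadimenol holds 210 (formula, charge-configuration)
ions. The triazolyl fragment's theoretical m/z rounds to the nominal 70 at
which it is observed. In the synthetic run the protonated precursor
(m/z 296.1160) elutes with its apex at 10.00 min; in the HCD 35 spectrum the
single fragment peak is matched (score 2 = 1), it represents one of 210
predicted ions (score 1 ≈ 0.005), and it carries 30% of the precursor's MS1
intensity (score 3 = 0.30).

A CLI mirrors the library: `fragmode predict|cluster|som|annotate|simulate|report`
(see `fragmode --help`).

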