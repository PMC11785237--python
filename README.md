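# cryoswim

Automated water and Mg²⁺ modeling and solvent-shell analysis for
cryo-EM density maps of RNA.

High-resolution (~2.2 Å) cryo-EM maps of RNA resolve not only the
nucleotides but also ordered solvent: water molecules hydrogen-bonded to
the RNA and Mg²⁺ ions directly coordinated to it. Deciding which density
peaks deserve an atom is the hard part — at this resolution a peak can be
noise, a partially occupied site, or a genuine ordered water. `cryoswim`
implements SWIM (segment-guided water and ion modeling) together with the
cross-validation and density-comparison machinery needed to judge the
result, plus a synthetic-data generator so the whole pipeline runs and
tests offline.

It is aimed at structural biologists modeling solvent into RNA maps and
at methods developers who want a tested, scriptable reference for the
placement and validation rules.

## What it computes

**SWIM placement.** With whole-map mean `avgD` and standard deviation
`σ`, the map is watershed-segmented at `avgD + 3σ`; segments are visited
by decreasing volume, and the highest interpolated density point of each
(`Pmax`) is modeled as water, Mg²⁺, or nothing:

1. Q-score at `Pmax` must exceed 0.7 in the full map **and both half
   maps** (independent evidence against noise peaks);
2. the nearest nucleotide must itself be well resolved (Q ≥ 0.6);
3. density at `Pmax` must reach `avgD + 5σ`;
4. chemistry: a Mg²⁺ needs an electronegative atom (O, or non-protonated
   N) at 1.8–2.5 Å, no protonated nitrogen at 1.8–3.4 Å and no carbon
   within 3.0 Å; a water needs an N/O at 2.5–3.4 Å or a Mg²⁺ at
   1.8–2.5 Å, with no C/P within 3.2 Å. New waters within 2.5 Å of an
   accepted water (ions: 4.5 Å) are dropped. Placement iterates (≤ 3
   passes) with accepted solvent joining the model.

**Q-score.** Atomic resolvability as the Pearson correlation between the
density profile sampled on concentric shells (rejecting samples closer to
another atom) and a reference Gaussian
`g(r) = A·exp(−½(r/0.6 Å)²) + B` with `A = avgD + 10σ`, `B = avgD − σ`;
contour-level invariant by construction. Solvent B-factors are reported
as `B = 150(1 − Q)`.

**Consensus.** Solvent from two independently determined map/model pairs
is paired and labeled *consensus* when the two placements are within 1 Å
after least-squares alignment of the local RNA (nucleotides within 10 Å)
**and** bind the same RNA atoms (close binders at 2.5–3.2 Å for water,
1.8–2.2 Å for Mg²⁺, cross-checked within expanded ranges).

**Density comparison.** The solvent shell (1.8–3.5 Å from well-resolved
RNA) of a reference map is compared against candidate densities by
Pearson CC, 20-bin mutual information, and a classification sweep
(positives = reference > 3σ) yielding PRC/ROC curves, AU-PRC, AU-ROC and
max-MCC, with min-max-normalized per-nucleotide AU-PRC scores.

**Ensemble analysis.** For coordinate frame sets (MD-style), per-species
occupancy densities, watershed binding sites (1 Å de-duplication),
frame-to-site assignment under local neighborhood alignment, occupancy,
water RMSF, Mg²⁺ residence times (single-frame gaps merged), composite
inverse-distance-weighted densities, and per-residue RNA flexibility with
`B = (8π²/3)·RMSF²`.

## Worked example

Generate the default synthetic fixture (a 6-bp A-form duplex with five
planted waters and one Mg²⁺, simulated at 2.2 Å with two independent
half maps at SNR 10) and run the full pipeline:

```python
import numpy as np
from cryoswim import fixtures, qscore, swim

fx = fixtures.make_maps()
qbr = qscore.q_by_residue_dict(fx.full, fx.model)
result = swim.run_swim(fx.full, fx.half1, fx.half2, fx.model, qbr)
for p in result.placements:
    d = min(np.linalg.norm(p.coord - q.coord) for q in fx.plants)
    print(f"{p.species:5s} peak {p.peak_sigma:5.1f} sigma  "
          f"Q_full {p.q_full:.2f}  error vs plant {d:.2f} A")
```

prints

```
MG    peak  14.2 sigma  Q_full 0.98  error vs plant 0.05 A
water peak   8.6 sigma  Q_full 0.99  error vs plant 0.01 A
water peak   8.9 sigma  Q_full 0.97  error vs plant 0.02 A
water peak   9.5 sigma  Q_full 0.98  error vs plant 0.03 A
water peak   9.1 sigma  Q_full 0.98  error vs plant 0.04 A
water peak   8.0 sigma  Q_full 0.98  error vs plant 0.03 A
```

All six planted sites are recovered with the right species: waters peak
near 8–9σ (above the 5σ gate), the Mg²⁺ — simulated 1.5× brighter — near
14σ, and every placement lands within 0.05 Å of its planted position.
The same pipeline is available from the shell:

```sh
cryoswim fixtures --out fx/ --seed 0
cryoswim swim --map fx/full.mrc --half1 fx/half1.mrc --half2 fx/half2.mrc \
              --model fx/model.cif --out solvated.cif --report swim.json
```

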