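# mifkit

Quantitative analysis toolkit for the biophysics of macrophage migration
inhibitory factor (MIF) homo- and heterotrimers. MIF is a homotrimeric
cytokine with a solvent channel along its 3-fold axis; engineered variants at
the channel gate (position 99) and mixed tagged/untagged trimers change the
protein's backbone dynamics, channel geometry, stability and tautomerase
activity. `mifkit` implements the full analysis chain used to characterize
such variants, for NMR spectroscopists and structural biologists who have
peak-height tables, shift assignments, PDB coordinates and assay curves but
want the downstream numbers reproducible and tested:

- **Spin relaxation** — per-residue R1 and R2 from single-exponential fits of
  peak heights h(t) = A·e^(−Rt) over the standard delay schedules, hetNOE
  from saturated/unsaturated peak-height ratios, and the R1R2 product with
  propagated uncertainties (R1R2 flags µs–ms exchange while suppressing
  anisotropic-tumbling artifacts).
- **Chemical-shift perturbations** — combined amide CSP
  Δδ = √(ΔδH² + (0.14·ΔδN)²), significance by a 10% trimmed mean + 1.5σ
  cutoff, and bookkeeping of residues broadened beyond detection.
- **Dynamics correlation** — ordinary least squares between two per-residue
  profiles (R1R2 or NOE) with ±1.5σ residual bands; residues outside the band
  report genuinely altered dynamics.
- **Channel geometry** — trimer 3-fold axis via inter-chain Kabsch rotations,
  an axial free-radius probe of the solvent channel (perpendicular distance
  to the axis minus Bondi vdW radius), gate constriction, closest
  inter-subunit atom distances, and Cα superposition RMSD.
- **Assembly & assays** — binomial mixed-trimer stoichiometry
  P(k) = C(3,k)·f^k·(1−f)^(3−k), species masses, expected SDS-PAGE band
  ratios, Michaelis–Menten fits (kcat, Km, kcat/Km, relative efficiency) and
  two-state van 't Hoff melt fits (Tm, ΔH).
- **Synthetic data** — generators for every input class with known ground
  truth, so each stage has a parameter-recovery test surface.

## Worked example

Predict the mixed-trimer species ladder at a 50:50 tagged/untagged monomer
ratio, conditioned on Ni-affinity retention (at least one tagged subunit):

```
$ mif assemble --f 0.5
 k_tagged  mass_kda  probability  band_ratio
        0   37.9000       0.0000         NaN
        1   57.3000       0.4286      0.7888
        2   76.7000       0.4286      0.1972
        3   96.1000       0.1429      0.0000
```

With monomer masses of one third of the tagged homotrimer (96.1 kDa) and the
untagged trimer (37.9 kDa), the two mixed species come out at 76.7 and
57.3 kDa, and the untagged/tagged band-intensity ratio grows monotonically as
WT content rises — the SEC/SDS-PAGE signature of a 2:1 / 1:2 heterotrimer
ladder.

A full synthetic round trip — generate decay series, fit rates, score CSPs,
profile a channel, fit assays:

```
$ mif synth decay --seed 2 --kind R2 --out s
$ mif relax fit s/decay_R2.csv --out rates.csv
fit 100 residues (0 unconverged) -> rates.csv
$ mif synth shifts --seed 3 --out s
$ mif csp --ref s/shifts_reference.csv --var s/shifts_variant.csv
cutoff 0.0618 ppm; 8 significant, 4 broadened -> csp.csv
$ mif synth shell --out s
wrote s/shell.pdb (true gate radius 1.30 A)
$ mif geom profile s/shell.pdb --out prof.csv
gate radius 1.30 A at z -0.80 (residue 4) -> prof.csv
$ mif synth mm --out s && mif assay mm s/mm.csv
kcat 10.134 1/s, Km 0.5283 mM, kcat/Km 19.181 1/(s mM)
$ mif synth melt --out s && mif assay melt s/melt.csv
Tm 76.92 C, dH 416 kJ/mol
```

The seed-3 shift pair plants 8 perturbation hotspots and 4 broadened
residues; the scorer recovers exactly those 8 above its 0.062 ppm cutoff.
The shell's constricted gate ring is recovered at its analytic free radius
(1.30 Å), and the noisy assay fits land within a few percent of the
generating truth (kcat 10 s⁻¹, Km 0.5 mM; Tm 76.9 °C).

`mif pipeline --seed 4 --out run` chains all stages and writes per-stage
CSV/JSON plus `run/summary.json`; rerunning with the same seed reproduces the
summary byte for byte.

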