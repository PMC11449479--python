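# lpptether

Analysis of Braun lipoprotein (Lpp) tethering to peptidoglycan (PG) from
heavy-isotope pulse-chase mass spectrometry of the diagnostic **Tri→KR
muropeptide** — the disaccharide-tripeptide
GlcNAc-MurNAc<sup>R</sup>-L-Ala-D-iGlu-DAP cross-linked, through the DAP side
chain, to the Lys-Arg remnant that trypsin digestion leaves from the Lpp
C-terminus.

*E. coli* grown on [¹³C]glucose/[¹⁵N]ammonium and switched to light medium
produces four Tri→KR isotopologues, according to whether the stem and Lpp
moieties are old (heavy) or new (light): new→new, old→old, old→new, new→old.
Their relative abundances over one generation encode how fast Lpp is tethered
to PG and how fast the L,D-transpeptidase YafK hydrolyzes the bond again.

The package is aimed at PG structural biologists and proteomics analysts who
want to (1) compute exact isotopologue and MS² fragment masses for branched,
reduced, moiety-wise labeled muropeptides, (2) assign and quantify peak lists,
(3) simulate and fit the turnover kinetics, and (4) generate ground-truth
synthetic data for validation.

## The model

All masses are neutral monoisotopic masses. An assembly of residues with `b`
condensation bonds has composition `Σ residues − b·H₂O` (+H₂ if MurNAc is
borohydride-reduced); a fully ¹³C/¹⁵N-labeled moiety adds
`n_C·1.0033548 + n_N·0.9970349` Da.

Kinetics, in an exponentially growing culture (rate `μ = ln2/T`, doubling
time `T = 60 min`), tracks free Lpp `F_o, F_n`, bound isotopologues `B_xy`
(x = stem age, y = Lpp age), and tetrapeptide donor stems `D_o, D_n`:

```
dB_xy/dt = k_t · F_y · p_x − k_h · B_xy        p_x = D_x / (D_o + D_n)
dF_o/dt  = −k_t·F_o + k_h·(B_oo + B_no)
dF_n/dt  = μL − k_t·F_n + k_h·(B_on + B_nn)
dD_o/dt  = −k_t·(F_o+F_n)·p_o                  dD_n/dt = μδL − k_t·(F_o+F_n)·p_n
```

`k_t` is the tethering rate per free Lpp, `k_h` the YafK hydrolysis rate per
bond (0 in ΔyafK). Old Lpp is conserved (`F_o + B_oo + B_no` is constant);
total Lpp grows as `L₀·e^{μt}`. A bound species that is neither synthesized
nor degraded therefore loses half its relative abundance per generation
(dilution), and hydrolysis multiplies that decay by `e^{k_h·t}`: fold
decreases of 4 (wild type) versus 2 (ΔyafK) over one generation give the
model-free estimate `100·(1 − 2/4) = 50 %` of bonds hydrolyzed per
generation — a lower bound, since released old Lpp can re-tether to old
donor stems.

## Worked example

```sh
lpptether demo --seed 9 --out-dir demo
```

runs masses → synthetic generation (wild type and ΔyafK) → assignment →
quantification → joint fit and prints a JSON report. With seed 9 it contains:

```
"theoretical_table": {"n_masses": 28, "n_within_0.01_of_rounded": 28},
"wt_oo_cohort_60_over_0":   0.2499999999833637,
"yafk_oo_cohort_60_over_0": 0.4999999998940692,
"headline": {"fold_wt": 1.4026.., "fold_mut": 1.2745..,
             "hydrolyzed_percent": 9.13..},
"fit": {"estimates": {"k_t": 0.011645.., "k_h": 0.012186..}},
"true_params": {"k_t": 0.0115524.., "k_h": 0.0115524..}
```

Reading: all 28 theoretical masses of the Tri→KR MS² grid round to the
published 2-dp values; the never-replenished t = 0 bound species ends one
generation at exactly half (ΔyafK, dilution only) or a quarter (wild type,
dilution × hydrolysis at `k_h = ln2/60`) of its initial relative abundance;
and the joint fit recovers the generating rates
(`k_h ≈ 0.01155 min⁻¹`, i.e. half the bonds hydrolyzed per generation) from
noisy synthetic data to within ~5 % on this single draw. The model-free
headline estimate on the same data is far below 50 % because, with one
well-mixed free-Lpp pool, re-tethering of old Lpp regenerates old-stem
isotopologues — the lower-bound caveat in action (see `docs/methods.md`).

Other subcommands: `masses`, `generate`, `simulate`, `assign`, `quantify`,
`fit` (see `lpptether --help`); every run writes a manifest JSON with the
configuration and output checksums.

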