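# tcrquant

Quantitative analysis tools for T-cell antigen receptor (TCR-CD3) signaling
studies. The package is aimed at labs that measure receptor triggering with
flow-cytometric dose-response readouts (pErk, pζ MFI), probe complex
stability with detergent-solubilisation immunoblots, and image receptor
organisation with dSTORM — and want the downstream quantitation to be
scripted, tested and reproducible instead of living in a spreadsheet.

## What it computes

**Kinetic-proofreading dose-response model.** A bound receptor must
complete N sequential proofreading steps at rate k_p before its ligand
unbinds at rate k_off, so the response at ligand concentration L is

    Y(L) = scale · L/(K_d + L) · (k_p/(k_p + k_off))^N

`tcrquant.proofreading` fits a WT/mutant dataset pair jointly (shared K_d,
fixed k_off and N, per-condition k_p by default), the setting in which a
higher mutant plateau resolves into a higher intrinsic proofreading rate
rather than altered binding. `tcrquant.binding_models` provides the
surrounding regression families: one-site specific binding, Hill slope,
one-phase exponential dissociation, and 3-/4-parameter logistic
([agonist] vs response) fits with EC50 estimates.

**Nested-model inference.** `tcrquant.nested_inference` compares nested
least-squares fits with the extra-sum-of-squares F-test
(F = ((SS₀−SS₁)/(df₀−df₁))/(SS₁/df₁)) — shared-K_d, shared-k_p and
shared-maximal-response hypotheses — plus Welch/paired t-tests and a
simulation harness that measures empirical test size and power.

**Immunoblot subunit ratios.** `tcrquant.dsa_quant` implements the
detergent-stability-assay arithmetic: band signal = median − local
background, total β = β1+β2+β3, per-lane subunit ratios (ζ/β₂, ε/β_T, …)
normalised to a reference condition (reference mean ≡ 1), with per-blot
pairing and replicate statistics.

**SMLM localization statistics.** `tcrquant.localization_stats` covers
photon-count filtering, re-blink merging (one pixel, up to five consecutive
frames), segment-correlation drift correction, edge-corrected pair
auto-correlation g(r), and DBSCAN cluster-size summaries (≥ 7 neighbours
within 25 nm).

**Synthetic data.** `tcrquant.synthetic_data` generates every input class
with known ground truth — dose-response and dissociation tables, immunoblot
band tables, clustered localization patterns with blinking overcounting —
so every fitter and estimator is validated by round-trip against the
generating parameters.

## Worked example

Simulate one WT/mutant experiment under the canonical study conditions
(10-dose 1:2 series from 600 nM, 3 replicates, CV 0.1 noise, true
k_p = 0.1 vs 0.5 s⁻¹) and ask whether one proofreading rate explains both:

```python
from tcrquant.scenarios import simulate_kpr_pair, KPR_CONDITIONS
from tcrquant.proofreading import fit_kpr_joint, kp_sharing_fits
from tcrquant.nested_inference import ess_f_test

wt, mut = simulate_kpr_pair(seed=1)
fit = fit_kpr_joint(wt, mut, koff_fixed=0.85, n_fixed=2.7,
                    scale_fixed=KPR_CONDITIONS["scale"], weighted=True)
print(f"shared Kd  = {fit.params['WT'].kd:.1f} nM")
print(f"kp (WT)    = {fit.params['WT'].kp:.4f} s^-1")
print(f"kp (mut)   = {fit.params['mut'].kp:.4f} s^-1")
print(f"kp ratio   = {fit.kp_ratio('mut', 'WT'):.2f}")

null, alt = kp_sharing_fits(wt, mut, 0.85, 2.7, weighted=True)
print(ess_f_test(null, alt, null_label="shared kp", alt_label="per-condition kp"))
```

prints

```
shared Kd  = 29.5 nM
kp (WT)    = 0.1005 s^-1
kp (mut)   = 0.5033 s^-1
kp ratio   = 5.01
null=shared kp alt=per-condition kp F(1,56)=2437.71 p=7.38362e-48
```

The joint fit recovers the generating K_d (30 nM) and the 5-fold k_p
difference, and the extra-sum-of-squares F-test overwhelmingly rejects the
single-k_p null — the statistical signature of a mutation that raises
intrinsic signaling capability without changing ligand binding. (Absolute
k_p values require the probability→response scale to be calibrated, here by
`scale_fixed`; without it the fit reports k_p and scale as structurally
confounded, while the F-test is unaffected.)

The same workflow runs from the shell:

```
tcrquant run config.yaml        # simulate → joint fit → F-test → report bundle
tcrquant fit data.csv --family logistic4 --out fit.txt
tcrquant dsa bands.csv --scheme zeta_over_beta2 --reference WT --out ratios.csv
tcrquant smlm locs.csv --mask-rect 5000,5000 --out-prefix cell1
```

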