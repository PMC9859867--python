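# collateraltime

Time-resolved automated collateral scoring on CT perfusion and multiphase
CTA, for researchers studying collateral circulation in acute ischemic
stroke with large-vessel occlusion.

## The problem and the method

Collateral status is commonly scored on a CT angiography snapshot, but the
score depends on when that snapshot catches the contrast bolus. This
package analyses that time dependency with an automated **collateral ratio**

    CR = 100 % × V_occluded / V_contralateral

where `V` is the contrast-enhanced vessel volume in the occluded-side and
contralateral middle-cerebral-artery territory. From a dynamic CT perfusion
(CTP) series it computes, per subject:

* per-frame CR plus four time-intensity curves (vessel volumes per side,
  arterial/venous enhancement, and the blood-subtracted arteriovenous
  ratio `(A − 40 HU)/(V − 40 HU)`),
* the CR at six predefined time points — the peaks of contralateral and
  occluded vessel volume, arterial enhancement, venous enhancement and AV
  ratio, and the arteriovenous equilibrium (AV ratio = 1) — plus a
  timing-invariant CR from the maximum-intensity projection over time,
* a per-subject **contrast acquisition phase** model: the AV-ratio curve
  normalized so equilibrium → 0 and maximum → 1, split into early
  arterial / peak arterial / equilibrium / early venous / late venous,
* the temporal alignment of three multiphase-CTA (mCTA) acquisitions onto
  the CTP time axis by minimizing the summed absolute AV-ratio difference,
  with the acquisition phase of each mCTA volume,
* cohort statistics: the Spearman correlation matrix across the ten CR
  variables and standardized regressions of each CR against ASPECTS-like
  and NIHSS-like covariates, with median/IQR summaries.

Everything is exercisable without patient data through a seeded synthetic
phantom cohort (gamma-variate bolus, mirrored vessel trees, delayed and
attenuated collateral filling, bolus-tracked mCTA sampling); see
`docs/methods.md` for the model and its limitations.

## Worked example

A noise-free phantom with 60 % collateral filling delayed by 3.2 s:

```python
import collateraltime as ct

cfg = ct.PhantomConfig(collateral_fraction=0.6, collateral_delay_s=3.2,
                       noise_sd_hu=0.0)
model = ct.PhantomModel(cfg)
series, regions = model.simulate_series(), model.region_spec()

tics = ct.extract_tics(series, regions)
landmarks = ct.find_timepoints(tics)
for name in ("av_max", "arterial_max", "equi", "venous_max"):
    lm = landmarks[name]
    print(name, lm.time_s, ct.cr_at_time(tics, lm.time_s))
```

prints (seconds, CR in percent):

```
contrast arrival: 8.21 s
av_max        t = 10.00 s  (1.79 s after arrival)  CR =   0.00 %
arterial_max  t = 14.00 s  (5.79 s after arrival)  CR =  16.75 %
equi          t = 17.95 s  (9.74 s after arrival)  CR =  93.06 %
venous_max    t = 20.00 s  (11.79 s after arrival)  CR = 174.79 %
CR_mip = 77.03 %
```

The CR rises steeply across the acquisition — near zero at the AV-ratio
peak, when the delayed collateral filling has barely begun; close to parity
at equilibrium; and above 100 % at the venous peak, when contrast lingers
in collateral-filled vessels while the healthy side already washes out.
That is the time dependency the analysis quantifies. Aligning three mCTA
volumes sampled at 18, 26 and 34 s recovers the true offset exactly at the
0.1 s search resolution:

```
recovered mCTA offset: 18.0 s (true 18.0), phases ['PV', 'LV', 'LV']
```

The full cohort pipeline (58 synthetic subjects by default) runs from the
shell and writes the cohort table, correlation matrix, association tables,
phase-distribution counts and median/IQR summary as CSV:

```sh
collateraltime run --out results/
```

Subcommands `simulate`, `curves`, `score`, `phases`, `align`, `profile` and
`stats` expose the individual stages on NIfTI/JSON/CSV files.

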