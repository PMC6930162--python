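# sigprof

Single-cell fluorescence biosensor analysis: per-cell kinetic fits of Ca²⁺
and cAMP traces, PBM-index cluster-number selection for signaling-profile
discovery, cAMP half-life distributions, and ER-stress reporter image
quantification — with a synthetic-data generator that emulates the
experiments' statistical structure and carries ground truth for validation.

## Who this is for

Labs running live-cell biosensor assays of the kind where:

* a Gq agonist (e.g. carbachol via the hM1 receptor) evokes cytosolic Ca²⁺
  transients reported by a genetically encoded indicator (R-GECO), imaged
  every 2 s;
* a blue-light-activated adenylyl cyclase (bPAC) pulse transiently raises
  cAMP, whose phosphodiesterase-driven degradation is reported by R-cADDis
  every 20 s over a 15-min window;
* an IRE1α–XBP1 splicing reporter marks ER-stressed cells with a nuclear
  green fluorophore next to a constitutive nuclear red expression marker.

## The models

**Ca²⁺ transient decay.** Each cell's stimulus-aligned fold change is fit to

    ΔF/F(t) = α · e^(−θt)

with amplitude α (unitless ΔF/F) and clearance rate θ (s⁻¹), by bounded
least squares with deterministic data-driven initialization.

**cAMP degradation.** Each post-pulse trace is fit to the logistic

    ΔF/F(t) = α / (1 + β · e^(−θt))

on its decaying branch (θ < 0, β < 1, so the curve falls from ≈α back toward
baseline).  The half-life is the closed form

    t½ = ln(β) / θ,

the time at which the fitted curve crosses α/2; per-condition t½
distributions are compared as empirical CDFs.

**Profile discovery.** Cells are first filtered for a positive response
(max post-stimulus ΔF/F ≥ 0.2 for cAMP data), then the raw ΔF/F vectors on
the common grid are clustered by seeded multi-restart k-means for K = 2…7,
and K is selected by maximizing the PBM cluster-validity index

    PBM(K) = ((1/K) · (E₁/E_K) · D_K)²

where E₁ is the total distance of all traces to the global centroid, E_K the
total within-cluster distance, and D_K the maximum pairwise centroid
distance (Euclidean throughout).

**Image statistics.** Nuclei are segmented on the red channel (Otsu +
connected components + minimum area); a cell is stressed when its mean
nuclear green exceeds a threshold (Otsu on the per-nucleus distribution when
bimodal, else 3× background); and

    percent stressed = 100 · n_dual / n_red

per image, alongside green/red-ratio fold changes and normalized cell
counts over time.

## Worked example

```python
import sigprof as sp
from sigprof import traces

# three cAMP degradation families (rapid / intermediate / delayed)
ts, gt = sp.gen_camp_traces(n_cells=300, noise_sd=0.05, seed=0)
kept, removed = sp.qc_filter(ts, min_dff=0.2)
aligned = kept.map(traces.align_to_stimulus)

model = sp.select_k(aligned, k_range=range(2, 8), seed=0)
fits = sp.fit_traceset(aligned, model="logistic")
fractions = sp.profile_fractions(model, aligned)
```

Output:

```
cells retained: 300 removed: 0
selected K: 3
  K=2  PBM=   23.97
  K=3  PBM=   45.45
  K=4  PBM=   43.07
  K=5  PBM=   35.15
  K=6  PBM=   30.34
  K=7  PBM=   27.64
converged fits: 300 / 300
median t1/2 (s): 261.6
condition  profile  mean    sd  n_wells
     camp        0 0.280 0.070        3
     camp        1 0.317 0.078        3
     camp        2 0.403 0.012        3
```

The PBM index peaks at K = 3, recovering the three generating degradation
profiles; every fit converges, the pooled median cAMP half-life is ≈262 s
(the generator draws family half-lives in 60–120 s, 180–300 s and 420–600 s),
and the per-well profile fractions (mean ± SD over the three wells) are the
population readout compared across conditions with well-level pooled t-tests.

## Command line

```
sigprof init --out cfg.yaml
sigprof simulate --scenario fig5 --seed 1 --outdir bundle
sigprof analyze bundle --seed 1 --outdir report
```

Scenarios: `fig2` (four Ca²⁺ profile families), `fig5` (three cAMP families),
`fig6` (two cAMP families), `fig3` (per-cell stress vs max Ca²⁺ table),
`fig1` (two-channel stress-reporter images).  `simulate` writes tidy trace
CSVs / 16-bit TIFFs plus ground truth and a checksummed manifest; `analyze`
runs QC → fits → clustering → statistics and writes `report.json` with fit,
assignment, centroid and fraction tables beside it.  Ground truth is never
read by `analyze`.

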