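# chemokit

Quantifying bacterial chemotaxis and swimming behaviour from video-microscopy
and microwell chemotaxis assays.

Marine heterotrophic bacteria locate nutrient hotspots — lysing phytoplankton
cells, sinking particles, polysaccharide plumes — by run-and-tumble
chemotaxis: near-straight swimming "runs" interrupted by brief reorientation
("tumble") events whose rate the cell modulates along chemical gradients. Two
complementary measurements quantify this behaviour:

* **Cell tracking.** Phase-contrast video (25–30 frames/s, 0.326 µm/pixel)
  is converted into single-cell trajectories, from which swimming speed,
  the motile fraction and the reorientation frequency are computed.
* **In situ chemotaxis assay (ISCA).** A 5×5 array of 110 µL microwells
  releases chemoattractants through narrow ports; chemotactic cells swim in
  and are counted by flow cytometry. The **chemotactic index**

  *I*<sub>C</sub> = (cell concentration in treatment wells) / (cell
  concentration in filtered-seawater control wells),

  with *I*<sub>C</sub> > 1 indicating attraction, is compared across
  treatments (e.g. the polysaccharide laminarin with and without dissolved
  DMSP) and correlated against environmental covariates.

chemokit implements this entire chain as a tested, reusable pipeline, plus a
synthetic-data module that generates run-and-tumble trajectories, rendered
image stacks, ISCA count tables and environmental covariate tables with known
ground truth — so every downstream stage is testable without any external
data.

## Components

| module | contents |
| --- | --- |
| `chemokit.synthetic` | run-and-tumble simulator (Poisson tumbling, heading persistence, localisation noise, drift, non-motile subpopulation), video renderer, ISCA count generator, environment-table generator |
| `chemokit.tracking` | per-pixel median background subtraction, sub-pixel spot detection, gated minimum-cost linking (max displacement 31 px/frame, min separation 51 px by default), ensemble-median drift correction |
| `chemokit.motility` | Savitzky–Golay smoothing (order 2, window 5), 9-frame windowed speed, 12 µm/s motile classification, reorientation detection (>25° direction change **and** filtered speed < 70% of the trajectory mean), censored run times, per-cell reorientation frequency |
| `chemokit.isca` | per-plate *I*<sub>C</sub>, one-sided attraction tests, DMSP fold changes, log2 enrichment, molarity arithmetic, Spearman screens with Benjamini–Hochberg adjustment |
| `chemokit.cli` | `chemokit simulate / track / motility / isca` command-line interface |

## Worked example

```python
import chemokit as ck

# --- motility: simulate 100 swimmers at 0.5 tumbles/s and analyse them ----
params = ck.SimulationParams(n_cells=100, duration=30.0, tumble_rate=0.5,
                             turn_angle_min=45.0, nonmotile_fraction=0.25,
                             seed=1)
ts = ck.simulate_run_and_tumble(params)
summary, events, qc = ck.summarize_trajectories(ts)
motile = summary[summary["motile"]]
print(f"mean swimming speed: {motile['mean_speed_um_s'].mean():.1f} um/s")
print(f"median reorientation frequency: "
      f"{motile['reorientation_hz'].median():.3f} 1/s")
print(f"population tumble rate: {ck.population_tumble_rate(summary):.3f} 1/s")

# --- ISCA: 3 plates, laminarin at a 5.3-fold design effect ----------------
design = ck.IscaDesign(n_plates=3,
                       treatments=[("laminarin", 5.3), ("glucose", 1.0)],
                       seed=1)
table = ck.generate_isca_counts(design)
results, global_p = ck.attraction_results(table)
for r in results:
    print(f"{r.treatment}: I_C = {r.ic_mean:.1f} +/- {r.ic_sd:.1f} "
          f"(n={r.n_replicates}), one-sided p = {r.p_one_sided:.3f}, "
          f"significant = {r.significant}")

print(f"fold change 147.3/57.9 = {ck.fold_change(147.3, 57.9, ndigits=1)}")
```

prints

```
mean swimming speed: 38.3 um/s
median reorientation frequency: 0.517 1/s
population tumble rate: 0.478 1/s
glucose: I_C = 1.0 +/- 0.0 (n=3), one-sided p = 0.334, significant = False
laminarin: I_C = 5.1 +/- 0.1 (n=3), one-sided p = 0.000, significant = True
fold change 147.3/57.9 = 2.5
```

The simulated tumble rate (0.5 s⁻¹) is recovered by the detector chain
(0.478 s⁻¹, the per-cell median frequency 0.517 s⁻¹ carries the documented
censoring bias); the null glucose treatment stays at *I*<sub>C</sub> ≈ 1 and
non-significant while the laminarin effect is detected; and the published
mean indices 147.3 (with 1 µM DMSP) versus 57.9 (without) give the 2.5-fold
enhancement.

The same chain runs from the shell:

```bash
chemokit simulate video --config sim.yaml --seed 1 --out video.tif
chemokit track --in video.tif --out tracks.csv
chemokit motility --in tracks.csv --out summaries/
chemokit simulate isca --config isca.yaml --out counts.csv
chemokit isca test --in counts.csv --out results.csv
```

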