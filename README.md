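# cfmkinetics

Dissociation kinetics and single base-stacking energetics for centrifuge
force microscope (CFM) force-clamp experiments.

A CFM is a miniature video microscope spun in a centrifuge bucket: every
microsphere tethered to the cover glass by a single DNA construct feels a
constant centrifugal force F = m_eff ω²r, and when the weak central duplex
of its tether dissociates the bead vanishes from view. One spin therefore
runs hundreds of single-molecule pulling experiments in parallel. Comparing
two constructs that are identical except for one terminal base stack turns
those dissociation kinetics into a direct measurement of the free energy of
a single stacking interaction between adjacent nucleobases — an energy of
order 1 kcal/mol that is hard to isolate any other way.

`cfmkinetics` implements the full analysis chain for this assay, plus a
synthetic-data generator so every stage can be validated with known ground
truth (raw CFM movies are terabyte-scale and rarely shareable):

1. **Force calibration** (`physics`): RPM ↔ force (F = m_eff ω²r) and
   relative centrifugal field; thermal energy k_BT.
2. **Synthetic experiments** (`synthetic`): exponential tether populations
   with stuck-bead and slow multi-tether fractions, right-censoring, paired
   stack/control designs with exact ground-truth ΔG, and rendered bead
   movies (multi-page TIFF) with per-bead truth sidecars.
3. **Bead tracking** (`tracking`): circle-Hough detection in the first
   frame, exclusion of clustered / out-of-focus / edge beads, per-bead ROI
   intensity-variance traces, and dissociation calling from the persistent
   variance drop.
4. **Kinetics** (`kinetics`): empirical survival ("decay") curves on the
   saved-frame grid, bounded fits of y = y₀ + A·e^(−kt) (y₀ ≥ 0 absorbs
   stuck beads), event histograms for QC, and replicate aggregation
   (mean ± sd of per-replicate off-rates).
5. **Energetics** (`energetics`): Bell-Evans fits of ln k versus force
   (k(F) = k_thermal·e^(F/f), transition distance x‡ = k_BT/f) and stacking
   free energies ΔG_stack = RT·ln(k_stack/k_control) with first-order error
   propagation, including per-force consistency checks.
6. **Pipeline + CLI** (`pipeline`, `cli`): a config-driven end-to-end run
   (`simulate → track → fit → aggregate → energy`) with a reproducibility
   manifest, and `cfmkinetics` subcommands `simulate`, `track`, `fit`,
   `bellevans`, `energy`, `run`, `demo`.

## Worked example

Simulate a paired stack/control experiment at 15 pN with a known stacking
energy of −1.9 kcal/mol (3 replicates × 500 tethers per arm), fit each
replicate's survival curve, aggregate, and recover ΔG:

```python
import cfmkinetics as cfm

T = 294.15
model = cfm.TetherPopulationModel(n_tethers=500, off_rate=0.05, seed=42)
stack, control = cfm.paired_experiment(
    dG_stack=-1.9, control_rate=0.05, temperature=T,
    model_base=model, n_replicates=3, force_pN=15.0,
)
est = {}
for label, datasets in (("stack", stack), ("control", control)):
    fits = [cfm.fit_single_exponential(cfm.build_survival_curve(ds, 5.0))
            for ds in datasets]
    est[label] = cfm.aggregate_replicates(fits, label, force=15.0)
    print(f"{label:8s} k = {est[label].k_mean:.4g} +/- {est[label].k_sd:.2g} 1/s "
          f"({est[label].n_replicates} replicates, {est[label].n_tethers_total} tethers)")
energy = cfm.delta_g_stack(est["stack"], est["control"], T)
print(f"dG_stack = {energy.dG:.2f} +/- {energy.dG_err:.2f} kcal/mol")
```

prints

```
stack    k = 0.001915 +/- 0.00011 1/s (3 replicates, 1500 tethers)
control  k = 0.04654 +/- 0.00051 1/s (3 replicates, 1500 tethers)
dG_stack = -1.87 +/- 0.04 kcal/mol
```

The stacked construct dissociates ~24× slower than the control; RT·ln of
that ratio recovers the configured −1.9 kcal/mol within the propagated
uncertainty. `cfmkinetics demo --out demo_run` runs the same analysis end
to end from rendered 16-bead movies instead of sampled times.

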