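# mixproc

Mixture-process crossed experimental design, Scheffé-type response-surface
modeling, and multi-response desirability optimization for formulation
studies — built around a solid-lipid-nanoparticle formulation campaign with
two process factors (% polysorbate 80 in the surfactant couple, ultrasound
time) and a three-component lipid blend (carnauba wax, glyceryl behenate,
glyceryl distearate).

## What it does

- **dataset** — the packaged 66-run study (63 distinct design points + 3
  replicates) with particle size (nm), polydispersity index, and zeta
  potential magnitude (mV); a strict CSV dialect; and a seeded simulator
  that generates responses from user-supplied true coefficients.
- **design** — simplex-centroid mixture points crossed with factorial
  process grids, [-1, 1] process-factor coding, model matrices for the
  three built-in model forms (6-term process quadratic, 7-term reduced
  cubic Scheffé, 28-term multiplicative crossed model), and D-optimal
  subset selection by a Fedorov-style exchange algorithm.
- **model** — OLS fitting with ANOVA summaries (R², regression F and p
  under the mean-corrected, intercept-absorbed convention), prediction at
  arbitrary conditions, and pooled replicate variance.
- **desirability** — piecewise-linear partial desirability ramps
  (bilateral / larger-is-better / smaller-is-better), weighted geometric
  aggregation, and global maximization over the simplex × process box by a
  dense grid scan plus multi-start coordinate-descent refinement.
- **surfaces** — ternary slices (fixed process setting) and process-plane
  slices (fixed blend) of any fit or of the global desirability, exported
  as long-form CSV, with optional contour rendering.

## CLI

All commands take a YAML config (`--config`), write to `--out`, and log
version, seed, and config hash; reruns with identical inputs are
byte-identical. Exit codes: 0 success, 2 config error, 3 data error,
4 numerical failure.

```sh
# 63-run crossed design (or a D-optimal subset via design.method)
mixproc design --config config.yaml --out design.csv

# fit configured responses; YAML report with coefficients, R², F, p
mixproc fit --data runs.csv --config config.yaml --out fit.yaml

# predict all responses at one condition (p80,us,cw,gb,gds)
mixproc predict --data runs.csv --config config.yaml \
    --at "40.8,7.5,0.59,0.22,0.19" --out pred.yaml

# maximize global desirability; writes report + ternary/process slice grids
mixproc optimize --data runs.csv --config config.yaml --seed 1 --out opt.yaml

# evaluate a ternary or process slice as long-form CSV
mixproc surface --data runs.csv --config config.yaml --out grid.csv

# seeded synthetic responses from configured true coefficients
mixproc simulate --config config.yaml --seed 1 --out sim.csv
```

`--data fixture` uses the packaged 66-run dataset. A minimal config is the
empty file — every key has a sensible default; see `src/mixproc/config.py`
for the schema (unknown keys are rejected).

Example config:

```yaml
model: multiplicative_deg3
responses: [ps_nm, pdi, zp_abs_mv]
desirability:
  ps_nm:     {shape: bilateral,        min: 50, max: 200, target: 100, weight: 1}
  pdi:       {shape: right_unilateral, max: 0.4, target: 0, weight: 1}
  zp_abs_mv: {shape: left_unilateral,  min: 25, target: 40, weight: 1}
design: {method: full_cross, p80_levels: [0, 50, 100], us_levels: [1, 5, 10]}
grid_step: 0.01
seed: 1
```

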