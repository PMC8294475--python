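# ljtypes

How many Lennard-Jones types does a force field need? `ljtypes` is a
desk-scale pipeline for exploring that question: SMIRKS-rule atom-typing
models, a regularized property-matching objective, a damped Gauss-Newton
optimizer with multi-start and superspace diagnostics, greedy type
splitting, and scaled parameter-space distances between optimized models.

Instead of production molecular dynamics, the pipeline runs against two
desk-scale backends:

- a **synthetic property oracle** — a smooth, type-separable map from typed
  LJ parameters to liquid density, heat of vaporization and dielectric
  constant, with a known ground-truth parameter set and noise at realistic
  simulation uncertainties, so every stage (typing → optimization → model
  comparison) is testable offline and parameter recovery is provable;
- a **toy liquid simulator** — a rigid-molecule NPT Metropolis Monte Carlo
  engine (minimum-image 12-6 LJ + truncated Coulomb, LJ tail correction,
  log-volume barostat moves) implementing the standard property
  definitions: density from the mean box volume, heat of vaporization as
  the gas/liquid potential-energy difference plus RT, and the dielectric
  constant from box-dipole fluctuations.

## Layout

| Module | Role |
| --- | --- |
| `ljtypes.chem` | molecules, ordered-SMIRKS typing rules, model-name grammar (`HCON` … `H2CO3N`, `SMIRFF15`), refinement relations |
| `ljtypes.core` | LJ types, Lorentz-Berthelot combination, pair energies, physical ↔ mathematical parameter transform |
| `ljtypes.objective` | regularized least-squares objective, restraint contributions, percent-error reporting |
| `ljtypes.optimize` | damped Gauss-Newton / gradient-descent local optimization, multi-start, superspace consistency check, greedy type splitting |
| `ljtypes.liquid` | property definitions + toy NPT MC engine |
| `ljtypes.compare` | common-row parameter expansion, epsilon scale factor, model distance matrices |
| `ljtypes.synth` | compound-library generator, ground-truth parameters, noisy reference tables, train/test splits |
| `ljtypes.cli` | study orchestration (`run_study`) and the `ljtypes` command-line interface |

A packaged fixture (`ljtypes/data/optimized_params.csv`) carries the
five-column optimized parameter table used by the distance-matrix analysis.

## CLI

```bash
ljtypes typify CCO --model H2CON          # per-atom LJ types
ljtypes counts                            # defined type count per model
ljtypes synth --n 24 --seed 1             # synthetic study manifest
ljtypes optimize --model HCO3N --n 40     # fit one model on the oracle
ljtypes simulate CCO --n-molecules 24     # toy NPT liquid properties
ljtypes compare --models HCON,H2CON,HCO3N,H2CO3N
ljtypes study --seed 0 --out study_out    # full multi-model study + reports
```

`ljtypes study` accepts a YAML config (`--config`); test-set objectives are
scaled (1/15 for split design 1, 1/3 for design 2) only in the report layer.

## Notes and limitations

- The toy simulator trades accuracy for speed on purpose: rigid molecules,
  truncated electrostatics, small boxes. Its dielectric estimates are biased
  and used only qualitatively.
- Charges are consumed as given (the synthetic library uses fixed
  per-functional-group charges); no charge derivation is performed.
- Typing rules follow last-match-wins semantics over an ordered list, with a
  general per-element fallback so typing is total on H/C/N/O chemistry.
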