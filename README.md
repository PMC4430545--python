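# adaptivepull

Staged nonequilibrium pulling on toy systems with exact oracles:
steered Langevin dynamics with Jarzynski free-energy estimation, naive
adaptive staging (JE-criterion ensemble contraction), full-relaxation
staging (zero-work constrained relaxation), and work-weighted
hydrogen-bond pathway analysis on synthetic peptide-backbone fixtures.

Everything runs on one CPU with no external data: analytic potentials
carry closed-form or quadrature free-energy oracles, and structure
fixtures are generated programmatically.

## Package layout

| module | contents |
| --- | --- |
| `potentials` | toy potentials (`free`, `harmonic`, `double_well`, `tilted_double_well`, `bead_spring_helix`) with analytic gradients; `reference_pmf` quadrature oracle |
| `curves` | `PMFCurve` free-energy profile container |
| `dynamics` | BAOAB Langevin integrator under a moving harmonic guide, trapezoidal work accounting, batch propagation with per-trajectory RNG streams |
| `jarzynski` | log-sum-exp exponential work averaging, JE-criterion trajectory selection, jackknife errors |
| `asmd` | stage plans; `run_smd`, `run_naive_asmd`, `run_fr_asmd`, `assemble_pmf` |
| `structures` | polyalanine-like backbone fixtures from ideal dihedrals, pseudo-solvent placement, PDB + label-TSV round-trips |
| `hbond` | geometric H-bond detection (4 Å / 140° defaults), helical-class contact profiles with Jarzynski work weighting, 2-D peptide/solvent histograms |
| `config`, `output`, `cli` | YAML run configs with protocol defaults, TSV/JSON outputs with manifests, `adaptivepull` CLI |

Units throughout: Å, kcal/mol, ps, K (velocities quoted in Å/ns at the
user-facing layer). See `constants.py`.

## CLI

```sh
adaptivepull run --config run.yaml --mode asmd --tps 100 --seed 1 --out run/
adaptivepull pmf --in run/ --out pmf.tsv
adaptivepull fixtures --type solvated --n-res 10 --hb-placed 3 --out fix
adaptivepull hbonds --pdb fix.pdb --out counts.tsv
adaptivepull histogram --counts pairs.tsv --out hist.tsv
adaptivepull oracle --config run.yaml --out reference.tsv
```

Minimal config (defaults fill in the standard protocol — ten 2 Å stages
13→33 Å, k = 7.2 kcal/mol/Å², 300 K, γ = 5 ps⁻¹, 2 fs step, 100 ps
relaxation):

```yaml
system:
  kind: harmonic
  params: {a: 1.0}
mode: asmd
```

Exit codes: 0 success, 2 configuration error, 3 numerical failure.
Each run directory contains per-stage `works.tsv`/`pmf.tsv`, the
assembled `pmf.tsv`, and a `manifest.json` (file list, config + hash,
seed, version) from which the run is reconstructible.

## External engines

All-atom systems can be attached by satisfying the same duck-typed
surface the toy systems use: an object with `dimension`, `energy(x)` and
`gradient(x)` (batched over `(B, dim)`), plus a reaction coordinate with
`value/gradient/dof_indices`. The staged runners, estimators and
analysis are agnostic to what produces the forces. No engine glue ships
with the package and none is exercised in CI.
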