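# groovemapper

Tested, reusable implementations of the computational analyses behind mapping
an alternative BH3-binding groove on a BCL2-family protein:

- **csp** — NMR chemical-shift-perturbation analysis of ¹H,¹⁵N-HSQC titration
  series (Sparky-style peak lists). Per-residue combined CSP
  `sqrt((ΔδNH² + ΔδN²/25)/2)`, mean+1SD threshold, and classification into
  *shifted* (focal, dose-responsive shifts) vs *attenuated* (intensity lost to
  the noise floor) residues.
- **grooves** — mapping classified residues onto structure-defined grooves
  (canonical α3/α4/α5 vs noncanonical α4/α6/α7 residue sets, author/PDB
  numbering) with a permutation test for per-groove enrichment.
- **ensemble** — conformer-population stability analysis: best-fit (Kabsch)
  Cα pairwise RMSD under an atom mask (receptor 102–125 and 147–177, peptide
  4–23), average-linkage clustering terminated at ε = 2.0 Å, population of the
  most populated cluster, and bootstrap site ranking.
- **assays** — steady-state 1:1 binding-affinity fitting
  (`R_eq = Rmax·C/(K_D + C)`, threefold-saturation QC) and liposome
  dye-release quantification (`(F_sample − F_blank)/(F_Triton − F_blank)·100%`).
- **synthetic** — generators for every input with known ground truth
  (titration peak lists, conformer ensembles, isotherms, dequenching traces);
  fully seeded and byte-deterministic.
- **pipeline** — YAML-config-driven orchestration producing a hash-stable
  `report.json` / `report.md`.

MD simulation itself is out of scope; the ensemble stage consumes saved
conformations (multi-model PDB or plain coordinate tables).

## CLI

```sh
# synthetic inputs
groovemapper simulate peaks    --n-residues 200 --seed 1 --out peaks/
groovemapper simulate ensemble --n-frames 2000 --populations 0.65,0.35 --seed 1 --out ens.dat
groovemapper simulate isotherm --kd 1000 --seed 1 --out iso.csv
groovemapper simulate release  --true-release 0.46 --seed 1 --out trace.csv

# analysis stages
groovemapper csp --apo peaks/apo.list --point 1=peaks/point_1.list \
    --point 4=peaks/point_4.list --noise-floor 0.1 --out csp_out/
groovemapper map --profile csp_out/csp_profile.csv --pdb model.pdb --chain A \
    --permutations 9999 --seed 1
groovemapper cluster --ensemble ens.dat --epsilon 2.0 --out cluster_out/
groovemapper fit-kd --isotherm iso.csv
groovemapper release --traces 'trace_*.csv' --window 0.1

# end-to-end
groovemapper run --config run.yaml
```

A minimal `run.yaml`:

```yaml
seed: 1
outdir: out
csp:
  apo: peaks/apo.list
  points: {"1": peaks/point_1.list, "4": peaks/point_4.list}
  noise_floor: 0.1
map:
  pdb: model.pdb
  chain: A
cluster:
  ensembles: {siteA: ensA.dat, siteB: ensB.dat}
  epsilon: 2.0
fit:
  isotherms: {bmf: iso.csv}
release:
  traces: {bmf: [trace_0.csv, trace_1.csv]}
```

## Acceptance

The acceptance gate is property- and simulation-based and lives in
`tests/test_acceptance.py` (CSP closed forms and call recovery, a quaternion
superposition oracle, a naive average-linkage clustering oracle, population
recovery and site ranking, K_D recovery with SE coverage, saturation QC and
release identities, groove-set regression, end-to-end determinism).

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

There are no numeric headline targets to reproduce offline, so the report is
an empty JSON object; the script runs an end-to-end self-check before writing
it.
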