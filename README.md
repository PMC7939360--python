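# idrslab

Residue-level coarse-grained **slab simulations** of intrinsically
disordered region (IDR) liquid–liquid phase separation (LLPS), with the
full analysis suite for calling phase coexistence and classifying chain
conformational forms.

The pipeline: amino-acid sequence → charged-bead topology (one bead per
residue; K/R = +e, D/E = −e) → Langevin dynamics in an elongated periodic
box under harmonic bonds + 12-6 Lennard-Jones + Debye–Hückel screened
electrostatics → density profiles along z, the P_H−P_L order parameter,
critical-temperature estimation, head–end distances, displacement
statistics, electrostatic-contact counts, chain-pair g(r), and
packed/dispersed/fully-spread (P/D/F) form classification.

## Model summary

| quantity | default | unit |
|---|---|---|
| bond length a | 0.38 | nm |
| bond stiffness k | 50,000 | kJ/mol/nm² |
| LJ σ / ε | 1.0 / 0.01 | nm / kJ/mol |
| LJ form | 4ε[(σ/r)¹²−(σ/r)⁶] | |
| K_coulomb | 138.94 | kJ·mol⁻¹·nm·e⁻² |
| dielectric | 80 | |
| κ | 3.2·√C_salt | nm⁻¹ |
| cutoffs (LJ, DH) | 3.0, 3.0 (shifted to zero) | nm |
| bead mass | 110 | g/mol |
| T_0 / τ | 100 K (k_B·T_0 = 0.83145 kJ/mol) / 1 ns | reduced units |
| integrator | BAOAB Langevin, dt = 2 fs, γ = 1 ps⁻¹ | |

Salt mode is either a molar concentration (e.g. `0.01` for 10 mM) or the
string `screened`, which zeroes the electrostatic term exactly.
Temperatures are multiples of T_0; 1 τ = 500,000 steps.

## CLI

All commands are subcommands of `idrslab` (the most common also have
standalone entry points):

```bash
# sequence statistics: id, L, n_pos, n_neg, f_plus, f_minus, ncpr, scd
idrslab seqstats my.fasta --builtin

# full pipeline from a YAML config: pack -> minimize -> (anneal) ->
# Langevin per temperature -> TSV analysis suite
idrslab simulate --config config.yaml

# initial configuration only
idrslab build --config config.yaml --out init.xyz

# re-analyze a stored trajectory
idrslab analyze --config config.yaml --traj runs/T1/traj.xyz \
    --temperature 1.0 --out reanalysis/

# aggregate phase.tsv files into T_cr estimates per salt condition
idrslab phasediagram runs*/phase.tsv

# synthetic ground-truth inputs
idrslab fixtures planted-slab --out slab.xyz
idrslab fixtures charged-gas --out gas.xyz
```

Example config:

```yaml
sequence: EKGEKGEKGG     # or fasta: path/to/file.fasta
n_chains: 200
box_xy: 40.0             # nm
box_z: 300.0             # nm
temperatures: [1.0, 1.5, 2.0, 3.0, 4.0]   # T_0 units
salt: 0.01               # molar, or "screened"
steps: 500000
seed: 1
outdir: runs/swc
```

Outputs per temperature: `traj.xyz`, `profile.tsv` (γ, m_γ, P_γ, D_γ),
`phase.tsv` (P_H, P_L, LLPS flags at the 0.15/0.07 thresholds),
`chains.tsv` (per frame/chain head–end distance D, displacement |z|,
E_intra, E_inter), `windows.tsv` (per-|z|-window chain fraction, mean D,
standard error, boundary-exclusion flag), `rdf.tsv`, `forms.tsv` (P/D/F
labels). Every TSV carries the config hash; reruns are byte-identical.
Exit codes: 0 success, 2 config error, 3 numeric failure.

Trajectory formats: multi-frame XYZ (nm; comment line carries step, τ and
box), PDB snapshots (Å, box in CRYST1), or a flat TSV
(`frame step tau bead x y z`).

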