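# rnagrow

Hierarchical chain growth (HCG) of atomistic single-stranded RNA ensembles,
with SAXS/FRET forward models and Bayesian ensemble reweighting.

Full-length ssRNA chains are assembled by recursively merging pairs of short
pieces drawn from tetramer fragment conformer pools.  A merge superimposes
the junction atoms (backbone O3'/P/O5' with doubled weights plus the full
overlap nucleobase and its C1'), rejects pairs whose weighted RMSD exceeds
0.64 A or that produce heavy-atom clashes below 2 A outside the junction
region, removes the two overlap nucleotides and keeps the bridging phosphate
from the downstream piece.  Ensembles carry uniform weights and can be
scored against experiment through:

- **SAXS** — Debye-formula intensities with Cromer–Mann form factors,
  Guinier radius of gyration, ensemble averaging, scale/offset fitting and
  reduced chi-squared;
- **FRET** — transfer efficiencies under three dye-dynamics models (fixed
  kappa^2 = 2/3, linker-averaged distances, and explicit per-conformer
  orientation factors) with fluorophore conformers mapped onto the chain
  termini by the same alignment/clash machinery;
- **stacking** — geometric base-stack detection and per-base stacking
  factors for runs of consecutively stacked bases;
- **reweighting** — KL-regularized weight refinement against SAXS profiles
  (with iterative scale/background refitting) or scalar FRET means, with
  theta scans, L-curve tables and rank-ordered weight CDFs.

Because the original MD fragment libraries are external, the package ships a
synthetic generator that builds tetramer libraries from idealized A-form-like
templates with Gaussian torsion noise, a minority of unstacked/inverted base
states and bent central-junction states; mock dye libraries with an anchor
dinucleotide, a designated center oxygen and a transition-dipole axis are
generated the same way.  Structured segments (e.g. stem-loops read from
multi-model PDB) can be mixed with grown disordered segments.

## Command line

```sh
rnagrow synth-fragments --key AAAA --n 1000 --noise 5 --seed 1 --out libs/AAAA.pdb
rnagrow grow --sequence AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA --mode homo \
    --library-root libs --n 10000 --seed 1 --out rA30.pdb
rnagrow saxs --ensemble rA30.pdb --q-max 3.0 --n-q 200 --out rA30_saxs.dat
rnagrow fret --ensemble rA19.pdb --model 1 --r0 5.4 --taud 4.0 --seed 1 --out eff.txt
rnagrow stacking --ensemble rA30.pdb --out stacks.json
rnagrow reweight-saxs --member-profiles members.txt --exp exp.dat --theta 100 --out rw.json
rnagrow reweight-fret --efficiencies eff.txt --target 0.56 --sem 0.03 --theta 40 --out rw.json
rnagrow demo --seed 1 --out report.json
```

Ensembles are multi-model PDB files with a two-column weight sidecar; SAXS
profiles are 3-column whitespace text (q in nm^-1, I, sigma).

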