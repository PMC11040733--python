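; Sample GROMACS run parameters for a coarse-grained assembly simulation
; built from asmgo-exported files (system.top + table_*.xvg).
; Pass the bonded tables via:  gmx mdrun -tableb table_a0.xvg table_d0.xvg ...
integrator               = sd          ; Langevin dynamics
dt                       = 0.002       ; reduced time units (tau)
nsteps                   = 50000000
nstxout-compressed       = 50000
compressed-x-precision   = 100

cutoff-scheme            = group       ; tabulated bondeds require group tables
nstlist                  = 20
ns-type                  = grid
pbc                      = xyz
rlist                    = 2.0
coulombtype              = cut-off
rcoulomb                 = 2.0         ; no charges in the model
vdwtype                  = cut-off
rvdw                     = 2.0

tc-grps                  = System      ; split large systems into several
tau-t                    = 1.0         ; coupling groups if unstable
ref-t                    = 120         ; reduced temperature (kappa)
ld-seed                  = -1

gen-vel                  = yes
gen-temp                 = 120
constraints              = none
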