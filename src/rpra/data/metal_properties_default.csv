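# Per-metal toxicity and transfer constants — a literature-assembled
# stand-in table (synthetic defaults): chronic reference doses per route
# (USEPA IRIS/RAGS convention, dermal = oral x gastrointestinal absorption
# fraction), central soil-water partition coefficients for near-neutral
# alluvial soils, central plant uptake factors (dry-weight, leafy
# vegetables), dermal permeability constants in water, dermal absorption
# fractions from solids, and the volatilization factor (elemental Hg only).
# Override per run with a site-specific table of the same schema.
metal,rfd_oral,rfd_dermal,rfd_inhalation,kd,puf,kp,abs,vf
As,3.0e-4,3.0e-4,3.0e-4,900,0.004,1.0e-3,0.03,
Hg,3.0e-4,2.1e-5,8.57e-5,2000,0.006,1.0e-3,0.001,32376.4
Cd,1.0e-3,2.5e-5,1.0e-3,1300,0.36,1.0e-3,0.001,
Zn,0.3,0.3,0.3,1700,0.11,6.0e-4,0.001,
Pb,3.5e-3,3.5e-3,3.5e-3,2800,0.012,1.0e-4,0.001,
Cu,0.04,0.04,0.04,1500,0.074,1.0e-3,0.001,
Cr,3.0e-3,7.5e-5,2.86e-5,3500,0.010,2.0e-3,0.001,
Ni,0.02,8.0e-4,2.06e-2,1500,0.048,2.0e-4,0.001,
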