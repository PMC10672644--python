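# Hip contact and muscle forces (N) at the femur for walking (instant of
# maximum contact force) and stair-climbing (instant of maximum torsional
# moment), after the in-vivo/musculoskeletal data of Heller et al.
# (J Biomech, 2001).  Documentation fixture for the organ-scale loading the
# site-ensemble surrogate stands in for; not consumed by the simulation.
pattern,load,fx,fy,fz,location
walking,hip_contact,-459.0,-278.8,-1948.2,P0
walking,abductor,493.0,36.6,735.3,P1
walking,tensor_fascia_latae_proximal,61.2,98.6,112.2,P1
walking,tensor_fascia_latae_distal,-4.3,-6.0,-161.5,P1
walking,vastus_lateralis,-7.7,157.3,-789.7,P2
stair_climbing,hip_contact,-504.1,-515.1,-2008.6,P0
stair_climbing,abductor,595.9,244.8,721.7,P1
stair_climbing,iliotibial_band_proximal,89.3,-25.5,108.8,P1
stair_climbing,iliotibial_band_distal,-4.3,-6.8,-142.8,P1
stair_climbing,tensor_fascia_latae_proximal,26.4,41.7,24.7,P1
stair_climbing,tensor_fascia_latae_distal,-1.7,-2.6,-55.3,P1
stair_climbing,vastus_lateralis,-18.7,190.4,-1148.4,P2
stair_climbing,vastus_medialis,-74.8,336.6,-2270.4,P3
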