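# kind: qk
# units: energy MeV, coefficient pSv cm^2
# Product Q(E)*k(E) of the energy-dependent neutron quality factor and the
# ICRU soft-tissue fluence-to-kerma factor, i.e. the point dose equivalent
# per unit fluence under the kerma approximation. Assembled from standard
# tissue kerma factors (1/v nitrogen capture at low energy, hydrogen elastic
# scattering in the keV-MeV range, nuclear-reaction kerma above 20 MeV) and
# mean quality factors that peak near 0.5 MeV and decline at high energy
# where the secondary charged particles are fast, low-LET protons.
# Log-log interpolation between nodes; constant above the last node.
energy_mev,value
1.0e-9,2.60
1.0e-8,0.85
2.53e-8,0.54
1.0e-7,0.27
1.0e-6,0.094
1.0e-5,0.031
1.0e-4,0.029
1.0e-3,0.25
1.0e-2,3.4
3.0e-2,12.0
5.0e-2,24.0
1.0e-1,48.0
2.0e-1,97.0
3.0e-1,125.0
5.0e-1,176.0
7.0e-1,195.0
1.0,210.0
2.0,265.0
3.0,295.0
5.0,330.0
7.0,360.0
10.0,390.0
14.0,410.0
17.0,405.0
20.0,396.0
30.0,357.0
50.0,308.0
75.0,281.0
100.0,264.0
150.0,247.0
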