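# kind: hstar
# units: energy MeV, coefficient pSv cm^2
# Fluence-to-ambient-dose-equivalent conversion coefficients h*(10)(E) for
# neutrons, standard reference coefficients with a high-energy extension
# above 20 MeV. Log-log interpolation between nodes; constant above the last
# node.
energy_mev,value
1.0e-9,6.60
1.0e-8,9.00
2.53e-8,10.6
1.0e-7,12.9
2.0e-7,13.5
5.0e-7,13.6
1.0e-6,13.3
2.0e-6,12.9
5.0e-6,12.0
1.0e-5,11.3
2.0e-5,10.6
5.0e-5,9.90
1.0e-4,9.40
2.0e-4,8.90
5.0e-4,8.30
1.0e-3,7.90
2.0e-3,7.70
5.0e-3,8.00
1.0e-2,10.5
2.0e-2,16.6
3.0e-2,23.7
5.0e-2,41.1
7.0e-2,60.0
1.0e-1,88.0
1.5e-1,132.0
2.0e-1,170.0
3.0e-1,233.0
5.0e-1,322.0
7.0e-1,375.0
9.0e-1,400.0
1.0,416.0
1.2,425.0
2.0,420.0
3.0,412.0
4.0,408.0
5.0,405.0
6.0,400.0
7.0,405.0
8.0,409.0
9.0,420.0
10.0,440.0
12.0,480.0
14.0,520.0
15.0,540.0
16.0,555.0
18.0,570.0
20.0,600.0
30.0,515.0
50.0,400.0
75.0,330.0
100.0,285.0
125.0,260.0
150.0,245.0
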