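shift_cm1,tentative_assignment
522,"nu(C-O-C), cellulose"
747,"nu(C-O-H), pectin"
855,"omega(Ce-H), serine"
1515,"nu(C=C), carotenoid"
1563,"chlorophyll b"
1619,"delta(H-N-H), methionine; delta_a(NH3+), lysine; nu(C=C), tyrosine"
1646,"delta(H2O), water; nu(C=C), ethylene"
1657,"nu(C=O) + omega(N-H), amide I"
1669,"nu(C=O) + omega(N-H), amide I"
1686,"nu(C=O) + omega(N-H), amide I"
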