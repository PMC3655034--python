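# Ideal (mean) covalent geometry of the peptide backbone.
# Values transcribed from the Engh & Huber stereochemical parameter
# tabulation (Acta Cryst. A47, 392-400, 1991), the standard restraint
# set derived from small-molecule crystal structures.
# Syntax:  bond A-B LENGTH   |   angle A-B-C DEGREES
# A residue-specific override is written with an @RES suffix and takes
# precedence for that residue type.
# N-H is not observable in X-ray data; 1.020 A is the conventional
# neutron-derived amide bond length.

bond N-CA 1.458
bond N-CA@GLY 1.451
bond N-CA@PRO 1.466
bond CA-C 1.525
bond CA-C@GLY 1.516
bond C-N 1.329
bond C-N@PRO 1.341
bond C-O 1.231
bond CA-CB 1.530
bond CA-CB@ALA 1.521
bond N-H 1.020

angle N-CA-C 111.2
angle N-CA-C@GLY 112.5
angle N-CA-C@PRO 111.8
angle CA-C-N 116.2
angle CA-C-N@GLY 116.4
angle C-N-CA 121.7
angle C-N-CA@GLY 120.6
angle C-N-CA@PRO 122.6
angle CA-C-O 120.8
angle O-C-N 123.0
angle C-N-H 119.2
angle CA-N-H 118.2
angle N-CA-CB 110.4
angle C-CA-CB 110.5
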