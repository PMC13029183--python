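# Published worked example of a DCW(1, 10) calculation for one training molecule.
# smiles: Cn1nnc(n1)c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F
# dcw: 111.17841
# predicted_pic50: 8.0321
# Only SMILES-based attributes were part of the published listing; the
# hydrogen-suppressed-graph invariants contributing to the full DCW were omitted,
# so the printed dcw is NOT the sum of the cw column below.
code	cw
C...........	0.3447
n...........	0.0186
1...........	-0.8026
n...........	0.0186
n...........	0.0186
c...........	-0.4471
(...........	0.269
n...........	0.0186
1...........	-0.8026
(...........	0.269
c...........	-0.4471
1...........	-0.8026
c...........	-0.4471
c...........	-0.4471
(...........	0.269
C...........	0.3447
O...........	0.6288
C...........	0.3447
C...........	0.3447
2...........	2.3436
(...........	0.269
C...........	0.3447
C...........	0.3447
N...........	0.295
C...........	0.3447
C...........	0.3447
2...........	2.3436
(...........	0.269
c...........	-0.4471
2...........	2.3436
c...........	-0.4471
c...........	-0.4471
c...........	-0.4471
c...........	-0.4471
c...........	-0.4471
2...........	2.3436
(...........	0.269
c...........	-0.4471
c...........	-0.4471
(...........	0.269
c...........	-0.4471
1...........	-0.8026
(...........	0.269
C...........	0.3447
(...........	0.269
F...........	0.1799
(...........	0.269
(...........	0.269
F...........	0.1799
(...........	0.269
F...........	0.1799
n...C.......	0.2397
n...1.......	0.4141
n...1.......	0.4141
n...n.......	-0.7738
n...c.......	0.0923
c...(.......	0.3964
n...(.......	2.0629
n...1.......	0.4141
1...(.......	0.1163
c...(.......	0.3964
c...1.......	0.1739
c...1.......	0.1739
c...c.......	0.4688
c...(.......	0.3964
C...(.......	-0.7408
O...C.......	-0.7979
O...C.......	-0.7979
C...C.......	0.1772
C...2.......	0.1987
2...(.......	-0.1962
C...(.......	-0.7408
C...C.......	0.1772
N...C.......	1.0573
N...C.......	1.0573
C...C.......	0.1772
C...2.......	0.1987
2...(.......	-0.1962
c...(.......	0.3964
c...2.......	2.4377
c...2.......	2.4377
c...(.......	0.3964
c...c.......	0.4688
c...c.......	0.4688
c...c.......	0.4688
c...c.......	0.4688
c...2.......	2.4377
2...(.......	-0.1962
c...(.......	0.3964
c...c.......	0.4688
c...(.......	0.3964
c...1.......	0.1739
1...(.......	0.1163
C...(.......	-0.7408
C...(.......	-0.7408
F...(.......	-0.8252
F...(.......	-0.8252
(...(.......	-1.4187
F...(.......	-0.8252
F...(.......	-0.8252
F...(.......	-0.8252
C...n...1...	-0.9283
n...1...n...	0.2246
n...n...1...	0.1801
n...n...c...	-1.0518
n...c...(...	0.2283
n...(...c...	0.5503
1...n...(...	2.8307
n...1...(...	3.551
c...(...1...	0.2971
1...c...(...	0.1144
c...1...c...	0.0403
c...c...1...	2.3309
c...c...(...	0.9158
c...(...C...	0.426
O...C...(...	-0.2246
C...O...C...	0.1366
O...C...C...	1.2334
C...C...2...	2.2071
C...2...(...	0.4969
C...(...2...	-1.0604
C...C...(...	-0.8527
N...C...C...	2.1912
C...N...C...	2.1254
N...C...C...	2.1912
C...C...2...	2.2071
C...2...(...	0.4969
c...(...2...	-0.124
2...c...(...	-0.6234
c...2...c...	-0.8324
c...c...2...	-0.6698
c...c...c...	-0.8924
c...c...c...	-0.8924
c...c...c...	-0.8924
c...c...2...	-0.6698
c...2...(...	-2.0438
c...(...2...	-0.124
c...c...(...	0.9158
c...c...(...	0.9158
c...(...c...	-0.856
1...c...(...	0.1144
c...1...(...	1.4353
C...(...1...	1.0971
(...C...(...	0.1113
F...(...C...	2.1949
(...F...(...	0.1479
F...(...(...	0.1855
F...(...(...	0.1855
(...F...(...	0.1479
F...(...F...	0.4795
Cmax.2......	2.1757
Nmax.1......	0.3841
Omax.1......	0.5766
Smax.0......	0.8094
NOSP11000000	5.7413
HALO10000000	-0.6663
BOND00000000	0.5132
++++F---N===	-0.2205
++++F---O===	-0.9908
++++N---O===	6.1527
$00011001000	-0.6679
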