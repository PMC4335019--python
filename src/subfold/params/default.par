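# subfold default nearest-neighbor parameter set (kcal/mol, 37 C).
# A compact Turner-style table: stacking free energies for all 36 ordered
# combinations of the six allowed pair types, loop initiation tables to
# length 30, affine multiloop model, terminal AU/GU penalty, and a
# logarithmic extrapolation coefficient for loops longer than 30.
# This is NOT a bit-exact reproduction of any published table.

[stack]
# rows: outer pair (i,j); columns: inner pair (i+1,j-1)
# order: AU UA CG GC GU UG
-0.9 -1.1 -2.2 -2.1 -0.6 -1.4
-1.3 -0.9 -2.4 -2.1 -1.0 -1.3
-2.1 -2.1 -3.3 -2.4 -1.4 -2.1
-2.4 -2.2 -3.4 -3.3 -1.5 -2.5
-1.3 -1.4 -2.5 -2.1 -0.5  1.3
-1.0 -0.6 -1.5 -1.4  0.3 -0.5

[hairpin]
# loop length 3..30
5.4 5.6 5.7 5.4 6.0 5.5 6.4 6.5 6.6 6.7 6.8 6.9 7.0 7.0
7.1 7.1 7.2 7.3 7.3 7.4 7.4 7.5 7.5 7.5 7.6 7.6 7.7 7.7

[bulge]
# loop length 1..30
3.8 2.8 3.2 3.6 4.0 4.4 4.6 4.7 4.8 5.0 5.1 5.1 5.2 5.3 5.4
5.5 5.5 5.6 5.6 5.7 5.8 5.8 5.8 5.9 5.9 6.0 6.0 6.1 6.1 6.1

[internal]
# total unpaired length 2..30
1.5 1.6 1.1 2.0 1.9 2.1 2.3 2.4 2.5 2.6 2.7 2.8 2.9 2.9 3.0
3.1 3.1 3.2 3.2 3.3 3.4 3.4 3.4 3.5 3.5 3.6 3.6 3.6 3.7

[multiloop]
# closing (a), per-branch (b), per-unpaired (c)
3.4 0.4 0.0

[misc]
# terminal_au  ninio_m  ninio_max  loop_extrapolation  temperature_K
0.5 0.6 3.0 1.0786 310.15
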