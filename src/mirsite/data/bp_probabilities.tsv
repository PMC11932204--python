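# Base-pair formation probabilities observed in human rRNA crystal structures
# (57,468 canonical and non-canonical pairs from 1634 PDB structures).
# Unordered pairs; probabilities are per-type frequencies, dimensionless.
pair	probability
AA	0.0519
AC	0.0870
AG	0.1566
AU	0.4965
CC	0.0189
CG	0.6979
CU	0.0473
GG	0.0303
GU	0.1210
UU	0.0455
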