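# Turner 2004 length-dependent loop initiation free energies, kcal/mol, 37 C.
# kind: bulge (unpaired on one strand) or internal (total unpaired, both strands).
kind	size	dg37_kcal_mol
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
bulge	7	4.60
bulge	8	4.70
bulge	9	4.80
bulge	10	4.90
bulge	11	5.00
bulge	12	5.10
bulge	13	5.20
bulge	14	5.30
bulge	15	5.40
bulge	16	5.40
bulge	17	5.50
bulge	18	5.50
bulge	19	5.60
bulge	20	5.70
bulge	21	5.70
bulge	22	5.80
bulge	23	5.80
bulge	24	5.80
bulge	25	5.90
bulge	26	5.90
bulge	27	6.00
bulge	28	6.00
bulge	29	6.00
bulge	30	6.10
internal	2	1.00
internal	3	1.00
internal	4	1.10
internal	5	2.00
internal	6	2.00
internal	7	2.10
internal	8	2.30
internal	9	2.40
internal	10	2.50
internal	11	2.60
internal	12	2.70
internal	13	2.80
internal	14	2.90
internal	15	2.90
internal	16	3.00
internal	17	3.10
internal	18	3.10
internal	19	3.20
internal	20	3.30
internal	21	3.30
internal	22	3.40
internal	23	3.40
internal	24	3.50
internal	25	3.50
internal	26	3.50
internal	27	3.60
internal	28	3.60
internal	29	3.70
internal	30	3.70
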