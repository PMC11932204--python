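# Turner 2004 nearest-neighbor helix stacking free energies, kcal/mol, 37 C.
# Step (pair1, pair2): pair1 is the 5'-side pair on the top strand, pair2 the
# adjacent 3'-side pair; both strands antiparallel. Canonical pairs incl. GU.
pair1	pair2	dg37_kcal_mol
CG	CG	-3.30
CG	GC	-2.40
CG	GU	-1.40
CG	UG	-2.10
CG	AU	-2.10
CG	UA	-2.10
GC	CG	-3.40
GC	GC	-3.30
GC	GU	-1.50
GC	UG	-2.50
GC	AU	-2.40
GC	UA	-2.20
GU	CG	-2.50
GU	GC	-2.10
GU	GU	-0.50
GU	UG	1.30
GU	AU	-1.30
GU	UA	-1.40
UG	CG	-1.50
UG	GC	-1.40
UG	GU	0.30
UG	UG	-0.50
UG	AU	-1.00
UG	UA	-0.60
AU	CG	-2.20
AU	GC	-2.10
AU	GU	-0.60
AU	UG	-1.40
AU	AU	-0.90
AU	UA	-1.10
UA	CG	-2.40
UA	GC	-2.10
UA	GU	-1.00
UA	UG	-1.30
UA	AU	-1.30
UA	UA	-0.90
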