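# Bromoalterochromide compound library (synthetic fixture built from published
# elemental compositions and residue sequences; Ile/Leu collapsed to Xle).
# Columns: name, series (A = C15 aryl-polyene acyl, B = C17), br (bromine
# count), acyl_formula, residues, formula (override for non-peptides),
# elimination_mz (configured aryl-polyene elimination ion), known (1 = in the
# reference/dereplication library, 0 = treated as unknown).
name	series	br	acyl_formula	residues	formula	elimination_mz	known
bromoalterochromide A	A	1	C15H11BrO2	Thr-Val-Asn-Asn-Xle		210.9567	1
bromoalterochromide A'	A	1	C15H11BrO2	Thr-Val-Asn-Asn-Xle		210.9567	1
dibromoalterochromide A	A	2	C15H10Br2O2	Thr-Val-Asn-Asn-Xle		288.8672	1
dibromoalterochromide A'	A	2	C15H10Br2O2	Thr-Val-Asn-Asn-Xle		288.8672	1
bromoalterochromide B	B	1	C17H13BrO2	Thr-Val-Asn-Asn-Xle		236.9724	1
bromoalterochromide B'	B	1	C17H13BrO2	Thr-Val-Asn-Asn-Xle		236.9724	1
dibromoalterochromide B	B	2	C17H12Br2O2	Thr-Val-Asn-Asn-Xle		314.8829	1
dibromoalterochromide B'	B	2	C17H12Br2O2	Thr-Val-Asn-Asn-Xle		314.8829	1
bromoalterochromide D	A	1	C15H11BrO2	Thr-Xle-Asn-Asn-Xle		210.9567	0
bromoalterochromide D'	A	1	C15H11BrO2	Thr-Xle-Asn-Asn-Xle		210.9567	0
dibromoalterochromide D	A	2	C15H10Br2O2	Thr-Xle-Asn-Asn-Xle		288.8672	0
dibromoalterochromide D'	A	2	C15H10Br2O2	Thr-Xle-Asn-Asn-Xle		288.8672	0
bisucaberin		0			C18H32N4O6		1
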