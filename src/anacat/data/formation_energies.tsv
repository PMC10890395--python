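compound_id	name	dfg_prime_kj_mol	source
glc	D-glucose	-399.3127	alberty2003
xyl	D-xylose	-320.0006	alberty2003
pyr	pyruvate	-343.9328	alberty2003
akg	2-oxoglutarate	-624.4529	alberty2003
o2	O2 (aq)	16.4000	alberty2003
co2	CO2 (aq)	-385.9900	alberty2003
h2o	H2O	-151.0921	alberty2003
nh3	ammonia (NH4+/NH3)	92.0415	alberty2003
etoh	ethanol	76.6537	alberty2003
ac	acetate (acetate-/acetic acid)	-240.9758	alberty2003
lac	L-lactate	-302.2850	alberty2003
for	formate	-308.8007	alberty2003
pi	phosphate (HPO4 2-/H2PO4 -)	-1056.6959	alberty2003
so4	sulfate	-747.7687	alberty2003
atp	ATP (ATP 4-/HATP 3-)	-2264.7399	alberty2003;no-Mg-species
adp	ADP (ADP 3-/HADP 2-)	-1397.0307	alberty2003;no-Mg-species
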