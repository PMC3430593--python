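id	name	formula	charge	mass
sodium	Sodium	Na	1	22.9900
potassium	Potassium	K	1	39.0980
lithium	Lithium	Li	1	6.9400
calcium	Calcium	Ca	2	40.0780
magnesium	Magnesium	Mg	2	24.3050
zinc	Zinc	Zn	2	65.3800
ammonium	Ammonium	NH4	1	18.0390
chloride	Chloride	Cl	-1	35.4500
bromide	Bromide	Br	-1	79.9040
iodide	Iodide	I	-1	126.9040
fluoride	Fluoride	F	-1	18.9980
sulfate	Sulfate	SO4	-2	96.0560
hydrogensulfate	Hydrogen sulfate	HSO4	-1	97.0640
nitrate	Nitrate	NO3	-1	62.0040
phosphate	Phosphate	PO4	-3	94.9700
acetate	Acetate	C2H3O2	-1	59.0440
trifluoroacetate	Trifluoroacetate	C2F3O2	-1	113.0140
mesylate	Methanesulfonate	CH3SO3	-1	95.0920
tosylate	p-Toluenesulfonate	C7H7SO3	-1	171.1900
besylate	Benzenesulfonate	C6H5SO3	-1	157.1630
maleate	Hydrogen maleate	C4H3O4	-1	115.0640
fumarate	Hydrogen fumarate	C4H3O4	-1	115.0640
citrate	Dihydrogen citrate	C6H7O7	-1	191.1150
tartrate	Hydrogen tartrate	C4H5O6	-1	149.0780
oxalate	Hydrogen oxalate	C2HO4	-1	89.0260
benzoate	Benzoate	C7H5O2	-1	121.1150
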