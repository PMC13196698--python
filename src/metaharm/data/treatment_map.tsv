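original_value	curated_ontology_term	curated_ontology_term_id
antilipid	Antilipidemic Agent	TOY:0000069
antihta	Antihypertensive Agents	TOY:0000070
antidiab	Anti-diabetic Agent	TOY:0000071
diuranse	Diuretic	TOY:0000072
ace_inhib	Angiotensin-Converting Enzyme Inhibitors	TOY:0000073
beta_blockers	Beta-Adrenergic Antagonist	TOY:0000074
ca2_cbl	Calcium Channel Blocker	TOY:0000075
metformin	Metformin	TOY:0000061
glp_1	glucagon-like peptide-1 receptor agonist	TOY:0000076
dppiv	Dipeptidyl-Peptidase IV Inhibitors	TOY:0000077
insulin	Insulin	TOY:0000063
statin	statin	TOY:0000067
asa	Aspirin	TOY:0000066
clopidogrel	Clopidogrel	TOY:0000068
nitrate	Nitrate	TOY:0000078
ppi	Proton Pump Inhibitor	TOY:0000079
xantoxinh	Xanthine Oxidase Inhibitor	TOY:0000080
sitagliptin	Sitagliptin	TOY:0000062
lantus	Insulin Glargine	TOY:0000064
solostar	Insulin Glargine	TOY:0000064
novorapid	Insulin Aspart	TOY:0000065
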