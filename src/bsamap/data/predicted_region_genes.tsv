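gene_id	chrom	start	end	annotation
GSVIVT01001280001	chr2	4951821	4956004	Flavin-containing monooxygenase
GSVIVT01001281001	chr2	4957741	4960852	Flavin-containing monooxygenase
GSVIVT01001282001	chr2	4962612	4965728	Flavin-containing monooxygenase
GSVIVT01001284001	chr2	4974657	4978139	Flavin-containing monooxygenase
GSVIVT01001285001	chr2	4983356	4986675	Unnamed protein
GSVIVT01001286001	chr2	4989461	4989778	WRKY transcription factor 21
GSVIVT00007310001	chr2	5009498	5010308	Adenine phosphoribosyltransferase
GSVIVT01001270001	chr2	5025234	5026199	Unnamed protein
GSVIVT00007320001	chr2	5036698	5037504	Phosphatidic acid phosphatase 2
GSVIVT01001290001	chr2	5062531	5074048	mRNA-oxysterol-binding protein-related protein 2A
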