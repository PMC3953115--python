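mirna	gene	programs	direction
miR-149	ABCC3	miRanda;miRWalk;TargetScan	SCC
miR-149	MUC1	TargetScan	SCC
miR-149	CEACAM6	miRanda;miRWalk;TargetScan	SCC
miR-149	CGN	miRanda	SCC
miR-149	CLDN3	miRanda	SCC
miR-205	ACSL5	miRanda;TargetScan	SCC
miR-205	MLPH	miRWalk;TargetScan	SCC
miR-205	CEACAM6	miRanda;miRWalk;TargetScan	SCC
miR-378	TMEM45B	miRanda	SCC
miR-422a	TMEM45B	miRanda	SCC
miR-483-5p	TMEM45B	miRanda;TargetScan	SCC
miR-494	ACSL5	TargetScan	SCC
miR-494	MLPH	miRanda	SCC
miR-494	CEACAM6	miRanda	SCC
miR-601	MLPH	miRanda;miRWalk;TargetScan	SCC
miR-708	CEACAM6	miRanda;TargetScan	SCC
miR-375	DSC3	miRanda;miRWalk;TargetScan	AD
miR-375	KRT6A	miRanda	AD
miR-375	DMRT2	miRanda;miRWalk	AD
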