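variant_id	chr	pos	effect_allele	other_allele	eaf	beta	se	pvalue
rs2250417	11	111590526	NA	NA	NA	0.00995	0.0102	0.71
rs2300702	2	316411522	NA	NA	NA	0.00995	0.0153	0.29
rs2268797	2	31637256	NA	NA	NA	0.00995	0.0153	0.26
rs6748621	2	32115705	NA	NA	NA	0.00995	0.0102	0.68
rs7577696	2	32132286	NA	NA	NA	0.00995	0.0102	0.6
rs6760105	2	32160890	NA	NA	NA	0.00995	0.0102	0.61
rs212745	2	32266336	NA	NA	NA	0.00995	0.0102	0.64
rs212713	2	32311041	NA	NA	NA	0.00995	0.0102	0.61
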