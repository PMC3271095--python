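# five-predictor consensus table for candidate glomerular genes; start/end use the
# descending report convention (START pairs miRNA nt 1); sources comma-separated
gene	mirna	seed_len	start	sequence	end	pvalue	sources
PDPN	hsa-mir-485-5p	8	1453	AGAGGCUG	1446	0.031	RNA22,miRanda,miRDB,miRWalk,TargetScan
HBEGF	hsa-mir-212	9	1584	UAACAGUCU	1576	0.0056	RNA22,miRanda,miRDB,miRWalk,TargetScan
HBEGF	hsa-mir-132	10	1584	UAACAGUCUA	1575	0.0014	RNA22,miRanda,miRDB,miRWalk,TargetScan
HBEGF	hsa-mir-379	8	1833	UGGUAGAC	1826	0.0223	RNA22,miRanda,miRDB,miRWalk,TargetScan
FN1	hsa-mir-96	8	8340	UUUGGCAC	8333	0.0169	RNA22,miRanda,miRDB,miRWalk,TargetScan
FN1	hsa-mir-144	9	8331	UACAGUAUA	8323	0.0042	RNA22,miRanda,miRDB,miRWalk,TargetScan
GJA1	hsa-mir-495	8	2244	AAACAAAC	2237	0.0261	RNA22,miRanda,miRDB,miRWalk,TargetScan
PKD2	hsa-mir-183	8	4768	UAUGGCAC	4761	0.0315	RNA22,miRanda,miRDB,miRWalk,TargetScan
PKD2	hsa-mir-372	9	4022	AAAGUGCUG	4014	0.008	RNA22,miRanda,miRDB,miRWalk,TargetScan
PPARA	hsa-mir-223	9	5877	UGUCAGUUU	5869	0.0314	RNA22,miRanda,miRDB,miRWalk,TargetScan
SP1	hsa-mir-24	7	5240	UGGCUCA	5240	0.2725	RNA22,miRanda,miRDB,miRWalk,TargetScan
SP1	hsa-mir-31	9	6960	AGGCAAGAU	6952	0.0197	RNA22,miRanda,miRDB,miRWalk,TargetScan
SP1	hsa-mir-105	7	5548	UCAAAUG	5542	0.2725	RNA22,miRanda,miRDB,miRWalk,TargetScan
SP1	hsa-mir-155	8	2560	UUAAUGCU	2553	0.0764	RNA22,miRanda,miRDB,miRWalk,TargetScan
TJP1	hsa-mir-144	8	6469	UACAGUAU	6462	0.0218	RNA22,miRanda,miRDB,miRWalk,TargetScan
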