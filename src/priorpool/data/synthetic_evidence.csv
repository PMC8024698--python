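study_id,parameter_id,estimate,se,kind,longitudinal,control_t1,same_time_lag,observation,age_range,internalizing_scope,covariate_partner_symptoms,covariate_other_behavior,community_sample,meta_analysis
MPonMint_study1,MPonMint,-0.2218,0.1376,empirical,1,0,1,1,0,1,0,0,1,0
MPonMint_study2,MPonMint,-0.0982,0.1788,meta-analysis,1,0,0,1,1,0,0,1,1,1
MPonMint_study3,MPonMint,-0.3415,0.0872,empirical,1,0,0,0,1,1,0,1,1,0
MPonAint_study1,MPonAint,-0.1549,0.0601,meta-analysis,1,0,0,1,1,1,1,0,1,1
MPonAint_study2,MPonAint,-0.2072,0.1934,empirical,1,0,0,1,1,1,0,1,1,0
MPonAint_study3,MPonAint,-0.3995,0.209,empirical,1,0,1,0,0,1,0,1,1,0
APonMint_study1,APonMint,-0.1391,0.2621,empirical,1,0,0,1,0,1,1,1,1,0
APonMint_study2,APonMint,-0.0243,0.1293,empirical,1,0,1,1,1,1,1,0,1,0
APonMint_study3,APonMint,-0.155,0.0551,meta-analysis,1,0,1,0,1,0,1,1,1,1
APonAint_study1,APonAint,-0.2007,0.0872,meta-analysis,1,0,1,0,0,0,0,0,0,1
APonAint_study2,APonAint,-0.1527,0.2733,empirical,1,0,0,0,1,1,1,0,1,0
APonAint_study3,APonAint,-0.1574,0.1057,empirical,1,0,0,0,1,1,1,0,1,0
MintonMP_study1,MintonMP,-0.3159,0.1722,empirical,1,1,0,1,0,0,0,1,1,0
MintonMP_study2,MintonMP,-0.1122,0.149,empirical,1,1,1,0,1,1,0,1,1,0
MintonMP_study3,MintonMP,0.0712,0.2766,empirical,1,1,1,1,1,0,0,1,0,0
MintonAP_study1,MintonAP,-0.145,0.1466,empirical,1,0,1,1,0,1,0,0,1,0
MintonAP_study2,MintonAP,-0.0312,0.2468,empirical,1,1,0,1,0,1,0,0,1,0
MintonAP_study3,MintonAP,0.0045,0.1971,empirical,1,0,0,1,0,1,1,0,0,0
AintonMP_study1,AintonMP,0.0962,0.2576,empirical,1,0,0,1,0,1,1,1,0,0
AintonMP_study2,AintonMP,0.2355,0.2039,empirical,1,1,0,1,1,0,0,0,0,0
AintonMP_study3,AintonMP,-0.5123,0.2725,empirical,1,0,0,0,0,0,1,0,1,0
AintonAP_study1,AintonAP,-0.2551,0.0764,meta-analysis,1,1,1,0,0,1,0,1,0,1
AintonAP_study2,AintonAP,0.2354,0.2594,empirical,1,1,0,0,0,1,1,0,0,0
AintonAP_study3,AintonAP,-0.1225,0.1978,empirical,1,0,1,1,0,1,0,1,0,0
MNonMint_study1,MNonMint,0.6558,0.298,empirical,1,0,1,1,0,1,0,1,0,0
MNonMint_study2,MNonMint,0.3965,0.1636,empirical,1,0,0,1,0,0,1,1,1,0
MNonMint_study3,MNonMint,0.1584,0.2819,empirical,1,0,1,1,0,0,1,0,1,0
MNonAint_study1,MNonAint,0.0812,0.0841,meta-analysis,1,0,1,0,0,1,1,0,1,1
MNonAint_study2,MNonAint,0.2147,0.1776,empirical,1,0,0,1,1,1,1,1,0,0
MNonAint_study3,MNonAint,0.0468,0.1031,meta-analysis,1,0,1,1,0,0,0,1,0,1
ANonMint_study1,ANonMint,0.247,0.1099,empirical,1,0,0,1,0,1,1,0,0,0
ANonMint_study2,ANonMint,0.063,0.2944,meta-analysis,1,0,0,0,1,0,1,1,1,1
ANonMint_study3,ANonMint,-0.0622,0.288,empirical,1,0,0,1,0,0,0,1,0,0
ANonAint_study1,ANonAint,0.0674,0.1536,empirical,1,0,0,1,1,1,1,1,0,0
ANonAint_study2,ANonAint,0.0529,0.1503,empirical,1,0,0,1,0,1,0,0,1,0
ANonAint_study3,ANonAint,0.0443,0.1788,empirical,1,0,0,1,1,0,1,1,1,0
MintonMN_study1,MintonMN,0.1154,0.1605,empirical,1,0,1,1,0,1,0,1,1,0
MintonMN_study2,MintonMN,-0.1225,0.1972,empirical,1,0,0,0,1,1,1,1,0,0
MintonMN_study3,MintonMN,0.0899,0.2331,empirical,1,0,0,0,1,0,0,1,1,0
MintonAN_study1,MintonAN,0.1068,0.0705,meta-analysis,1,1,0,1,1,1,0,1,0,1
MintonAN_study2,MintonAN,0.1235,0.0813,empirical,1,0,0,1,0,1,1,0,1,0
MintonAN_study3,MintonAN,0.0772,0.0616,empirical,1,1,0,1,0,1,0,0,1,0
AintonMN_study1,AintonMN,0.3067,0.1861,empirical,1,1,0,0,1,0,0,0,1,0
AintonMN_study2,AintonMN,0.3899,0.1792,meta-analysis,1,1,0,0,1,1,1,1,0,1
AintonMN_study3,AintonMN,0.1383,0.102,empirical,1,0,1,0,1,1,1,1,1,0
AintonAN_study1,AintonAN,0.1235,0.1179,empirical,1,0,0,1,0,1,1,1,1,0
AintonAN_study2,AintonAN,0.0602,0.1618,empirical,1,1,1,0,0,1,0,1,1,0
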