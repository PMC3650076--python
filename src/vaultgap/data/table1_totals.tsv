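label	wiews_total	genesys_total	wiews_distinct	wiews_itpgrfa	sgsv_total
Cereals	3095022	1061698	1223255	2065416	495410
Food Legumes	1187206	397945	437496	734065	166339
Forage Crops	389225	161796	139298	47995	35103
Roots and Tubers	183044	66708	68549	71105	17669
Vegetables	397069	137084	107672	73209	17988
Oil Crops	140196	21030	39729	20511	4068
Major crops total	5979663	2040606	2185452	3117472	766292
All crops total	7205007	2334747	2498098	3319398	774601
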