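name,value
sgsv_samples_total,774601
sgsv_depositing_institutions,53
wiews_total_accessions,7205007
wiews_156_genera_total,5979663
distinct_accessions_156_genera,2185452
annex1_in_contracting_parties,2625646
article15_holdings,693752
itpgrfa_covered_total,3319398
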