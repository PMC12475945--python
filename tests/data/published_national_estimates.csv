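stratifier,level,visit_type,total_cost,n_visits
overall,all,overall,7746300000,484567
overall,all,ed_only,520700000,298721
overall,all,inpatient,7225000000,185846
sex,male,overall,6889700000,
reinjury_flag,1,overall,693400000,
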