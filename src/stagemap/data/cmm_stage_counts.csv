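grouping,level,I,II,III-IV
age_group,30-34,254,27,16
age_group,35-39,396,43,29
age_group,40-44,538,59,36
age_group,45-49,599,79,45
age_group,50-54,592,108,50
age_group,55-59,717,139,82
age_group,60-64,818,193,73
age_group,65-69,1009,256,98
age_group,70-74,837,298,98
age_group,75-79,685,298,90
age_group,80-84,472,323,61
age_group,85-89,290,270,28
age_group,90+,95,180,21
region_quintile,Q1,973,418,110
region_quintile,Q2,1362,490,139
region_quintile,Q3,1457,469,159
region_quintile,Q4,1574,447,140
region_quintile,Q5,1936,449,179
gothenburg_quintile,Q1,61,41,8
gothenburg_quintile,Q2,186,59,17
gothenburg_quintile,Q3,192,74,13
gothenburg_quintile,Q4,234,61,15
gothenburg_quintile,Q5,344,71,18
malmoe_quintile,Q1,24,23,7
malmoe_quintile,Q2,67,27,12
malmoe_quintile,Q3,85,29,6
malmoe_quintile,Q4,111,35,15
malmoe_quintile,Q5,134,36,19
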