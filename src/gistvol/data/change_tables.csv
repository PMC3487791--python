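cohort,timepoint_months,row,decrease,no_change,increase
training,3,decrease,12,1,1
training,3,no_change,16,11,6
training,3,increase,0,1,2
training,6,decrease,17,1,0
training,6,no_change,18,10,2
training,6,increase,0,0,6
training,12,decrease,23,0,0
training,12,no_change,5,7,4
training,12,increase,0,0,7
validation,3,decrease,7,0,0
validation,3,no_change,14,1,3
validation,3,increase,0,0,3
validation,6,decrease,12,1,0
validation,6,no_change,6,3,1
validation,6,increase,0,0,4
validation,12,decrease,15,0,0
validation,12,no_change,1,3,2
validation,12,increase,0,0,4
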