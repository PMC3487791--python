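table,cohort,timepoint_months,criteria,printed_p
change,training,3,,<.001
change,training,6,,<.001
change,training,12,,.008
change,validation,3,,<.001
change,validation,6,,.13
change,validation,12,,.50
response,training,3,SPHERE,.03
response,training,3,ELLIPSOID,<.001
response,training,3,CHOI,<.001
response,training,6,SPHERE,.002
response,training,6,ELLIPSOID,<.001
response,training,6,CHOI,<.001
response,training,12,SPHERE,.25
response,training,12,ELLIPSOID,<.001
response,training,12,CHOI,<.001
response,validation,3,SPHERE,1.00
response,validation,3,ELLIPSOID,<.001
response,validation,3,CHOI,<.001
response,validation,6,SPHERE,.63
response,validation,6,ELLIPSOID,.001
response,validation,6,CHOI,<.001
response,validation,12,SPHERE,1.00
response,validation,12,ELLIPSOID,.03
response,validation,12,CHOI,.001
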