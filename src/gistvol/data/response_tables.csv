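cohort,timepoint_months,criteria,row,pr,sd,pd
training,3,SPHERE,PR,4,0,0
training,3,SPHERE,SD,6,34,1
training,3,SPHERE,PD,0,0,5
training,3,ELLIPSOID,PR,4,0,0
training,3,ELLIPSOID,SD,22,15,4
training,3,ELLIPSOID,PD,0,0,5
training,3,CHOI,PR,3,1,0
training,3,CHOI,SD,23,11,4
training,3,CHOI,PD,0,1,2
training,6,SPHERE,PR,6,0,0
training,6,SPHERE,SD,10,30,0
training,6,SPHERE,PD,0,0,8
training,6,ELLIPSOID,PR,6,0,0
training,6,ELLIPSOID,SD,24,13,3
training,6,ELLIPSOID,PD,0,0,8
training,6,CHOI,PR,5,0,0
training,6,CHOI,SD,23,14,1
training,6,CHOI,PD,1,1,5
training,12,SPHERE,PR,12,0,0
training,12,SPHERE,SD,3,17,3
training,12,SPHERE,PD,0,1,10
training,12,ELLIPSOID,PR,12,0,0
training,12,ELLIPSOID,SD,13,5,5
training,12,ELLIPSOID,PD,0,0,11
training,12,CHOI,PR,10,0,0
training,12,CHOI,SD,13,7,2
training,12,CHOI,PD,1,1,8
validation,3,SPHERE,PR,1,0,0
validation,3,SPHERE,SD,0,24,0
validation,3,SPHERE,PD,0,0,3
validation,3,ELLIPSOID,PR,1,0,0
validation,3,ELLIPSOID,SD,16,5,3
validation,3,ELLIPSOID,PD,0,0,3
validation,3,CHOI,PR,1,0,0
validation,3,CHOI,SD,21,2,1
validation,3,CHOI,PD,2,0,1
validation,6,SPHERE,PR,5,1,0
validation,6,SPHERE,SD,3,14,0
validation,6,SPHERE,PD,0,0,4
validation,6,ELLIPSOID,PR,6,0,0
validation,6,ELLIPSOID,SD,11,5,1
validation,6,ELLIPSOID,PD,0,0,4
validation,6,CHOI,PR,6,0,0
validation,6,CHOI,SD,15,2,0
validation,6,CHOI,PD,3,0,1
validation,12,SPHERE,PR,9,0,0
validation,12,SPHERE,SD,1,9,1
validation,12,SPHERE,PD,0,0,5
validation,12,ELLIPSOID,PR,9,0,0
validation,12,ELLIPSOID,SD,5,4,2
validation,12,ELLIPSOID,PD,0,0,5
validation,12,CHOI,PR,9,0,0
validation,12,CHOI,SD,9,1,1
validation,12,CHOI,PD,3,0,2
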