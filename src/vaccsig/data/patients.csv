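patient_id,gender,ajcc_stage,dth,survival_months,died,microarray
MT061,M,IV,-,10.8,1,0
MT065,F,IV,-,5.7,1,0
MT066,M,IIIC,+,47.7,1,0
MT072,M,IV,-,15.2,1,0
MT076,F,IV,+,35.1,1,0
MT079,F,IV,-,9,1,1
MT080,M,IV,+,68.3,0,1
MT083,M,IIIC,-,17,1,1
MT084,M,IIIC,+,65.3,1,1
MT087,M,IV,NT,1.4,1,1
MT089,M,IV,NT,6.2,1,1
MT091,M,IV,+,50.6,1,1
MT093,F,IV,+,64.9,0,1
MT094,M,IV,NT,3.4,1,1
MT096,M,IIIA,+,31,1,1
MT098,M,IV,NT,2.6,1,1
MT101,M,IV,-,63.9,0,1
MT105,F,IIIA,-,63.5,0,0
MT109,F,IV,NT,2.4,1,0
MT114,M,IV,-,10.7,1,0
MT122,M,IIIC,+,29.9,1,0
MT123,M,IV,-,6.9,1,0
MT127,F,IV,+,12.1,1,0
MT128,F,IIIB,+,56.5,0,0
MT132,M,IV,-,43.6,1,0
MT141,M,IV,-,20.5,1,0
MT147,F,IV,+,12.8,1,0
MT158,M,IV,+,10.2,1,0
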