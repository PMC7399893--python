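label,actor,category,kind,people,hours_per_person,hourly_rate,units,unit_price,amount,lifespan_years
CLTS training,District health officials,local,recurrent,5,56,4.50,,,,
CLTS training,Health professionals (health centre),local,recurrent,5,56,2.54,,,,
CLTS training,Health extension workers,local,recurrent,24,56,1.79,,,,
CLTS promoter training,CLTS promoters,local,recurrent,38,32,0.67,,,,
CLTS orientation,District health officials,local,recurrent,3,8,4.50,,,,
CLTS orientation,CLTS promoters,local,recurrent,38,8,0.67,,,,
CLTS triggering,District health officials,local,recurrent,5,40,4.50,,,,
CLTS triggering,Health extension workers,local,recurrent,24,192,2.54,,,,
CLTS triggering,CLTS promoters,local,recurrent,38,304,0.67,,,,
CLTS triggering,Community members,local,recurrent,804,8,0.67,,,,
CLTS follow-up,District health officials,local,recurrent,5,256,4.50,,,,
CLTS follow-up,Health extension workers,local,recurrent,24,256,1.79,,,,
CLTS follow-up,CLTS promoters,local,recurrent,38,512,0.67,,,,
CLTS follow-up,CLTS committee,local,recurrent,72,128,0.67,,,,
CLTS follow-up,Community members,local,recurrent,1079,32,0.67,,,,
CLTS follow-up,Kebele leaders,local,recurrent,24,64,0.67,,,,
Review meeting,District health officials,local,recurrent,12,64,4.50,,,,
Review meeting,Health extension workers,local,recurrent,24,64,2.54,,,,
Review meeting,CLTS promoters,local,recurrent,38,64,0.67,,,,
Review meeting,CLTS committee,local,recurrent,72,64,0.67,,,,
Latrine construction (time),Community people,local,capital,872,120,,,,,10
Latrine construction (cement),Community people,local,capital,,,,71,27.90,,10
Latrine construction (handwashing facility),Community people,local,capital,,,,721,17.01,,10
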