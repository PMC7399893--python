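label,actor,category,kind,people,hours_per_person,hourly_rate,units,unit_price,amount,lifespan_years
CLTS promoter introduction,CLTS implementation,program,recurrent,,,,,,1200,
CLTS promoter training,CLTS implementation,program,recurrent,,,,,,2160,
Educating mothers,CLTS implementation,program,recurrent,,,,,,2160,
Community campaign,CLTS implementation,program,recurrent,,,,,,1800,
Information Education and Communication materials,CLTS implementation,program,recurrent,,,,,,9000,
Best promoter prize,CLTS implementation,program,recurrent,,,,,,2670,
CLTS training,CLTS implementation,program,recurrent,,,,,,5355,
CLTS implementation,CLTS implementation,program,recurrent,,,,,,2651,
Experience sharing,CLTS implementation,program,recurrent,,,,,,720,
Material incentives,CLTS implementation,program,recurrent,,,,,,3840,
Monitoring/follow-up after the CLTS triggering,CLTS implementation,program,recurrent,,,,,,43204,
Meeting/workshop,CLTS implementation,program,recurrent,,,,,,4800,
Motorcycle,Project management,program,capital,,,,,,5590,5
Vehicle,Project management,program,capital,,,,,,8990,5
Korean staff salary and benefits,Project management,program,recurrent,,,,,,78000,
Local management staff salary and benefits,Project management,program,recurrent,,,,,,24840,
Translator,Project management,program,recurrent,,,,,,3600,
Stationery,Project management,program,recurrent,,,,,,4520,
Drivers,Project management,program,recurrent,,,,,,4800,
Fuel,Project management,program,recurrent,,,,,,12000,
Office,Project management,program,recurrent,,,,,,3600,
Monitoring and evaluation,Project management,program,recurrent,,,,,,8925,
Report printing,Project management,program,recurrent,,,,,,4000,
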