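keyword	factor	subcategory	equivalents
kind nurse	service	f1
friendly staff	service	f2	courteous staff
faithful response	service	f3
careful answer	service	f4
technical knowledge	professionalism	f5
special course	professionalism	f6
professor rank	professionalism	f7
surgical skill	professionalism	f8	surgery skill
side effect	professionalism	f9
fast recovery	professionalism	f10
accurate diagnosis	professionalism	f12
antibiotics prescription	professionalism	f13	prescription drugs
proper treatment	professionalism	f14
waiting time	process	f15	long wait
long term	process	f15
right now	process	f16
dose standby	process	f16
reasonable cost	process	f17	expensive fee
hospitalized	process	f18
basic	process	f19
parking lot	environment	f20	parking
reservation	environment	f21
waiting room	environment	f22
office hours	environment	f23
clean facility	environment	f24	sanitary
modern equipment	environment	f26
operating room	environment	f27
good image	impression	e1
trustworthy	impression	e2	reliable place
first visit	impression	e3
fed up	impression	e4
gentle doctor	impression	e5
famous tradition	popularity	e6
word of mouth	popularity	e7
media advertising	popularity	e8	advertisement
renowned doctor	popularity	e9
everyone knows	popularity	e10
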