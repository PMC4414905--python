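canonical_id	canonical_name	region	aliases
SEO1	Sunrise Children Hospital	Seoul	sunrise kids|sunrise children
SEO2	Hanbit Pediatric Clinic	Seoul	hanbit clinic|hanbit pediatrics
SEO3	Moonlight Baby Center	Seoul	moonlight center|moonlight babies
DAE1	Dalgubeol Children Hospital	Daegu	dalgubeol kids
DAE2	Palgong Pediatric Clinic	Daegu	palgong clinic
DAE3	Suseong Baby Center	Daegu	suseong center
DAE4	Apsan Family Pediatrics	Daegu	apsan pediatrics
DAE5	Sincheon Childcare Hospital	Daegu	sincheon childcare
DAE6	Biseul Infant Clinic	Daegu	biseul infant
BUS1	Haeundae Children Hospital	Busan	haeundae kids
BUS2	Gwangan Pediatric Clinic	Busan	gwangan clinic
BUS3	Oryukdo Baby Center	Busan	oryukdo center
DJN1	Yuseong Children Hospital	Daejeon	yuseong kids
DJN2	Daedeok Pediatric Clinic	Daejeon	daedeok clinic
DJN3	Gyeryong Baby Center	Daejeon	gyeryong center
INC1	Songdo Children Hospital	Incheon	songdo kids
INC2	Bupyeong Pediatric Clinic	Incheon	bupyeong clinic
INC3	Wolmi Baby Center	Incheon	wolmi center
GWA1	Mudeung Children Hospital	Gwangju	mudeung kids
GWA2	Sajik Pediatric Clinic	Gwangju	sajik clinic
GWA3	Chungjang Baby Center	Gwangju	chungjang center
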