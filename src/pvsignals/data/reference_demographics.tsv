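variable	category	count
gender	male	1354
gender	female	1221
gender	missing	387
age_band	<18	6
age_band	18-64	395
age_band	>=65	1034
age_band	missing	1527
route	oral	2650
route	topical	228
route	other	84
weight_band	<50	90
weight_band	>100	77
weight_band	50-100	633
weight_band	missing	2162
reporter	consumer	1062
reporter	healthcare_professional	896
reporter	other	686
reporter	missing	318
indication	chronic obstructive pulmonary disease	1390
indication	missing	1279
indication	psoriasis	86
indication	bronchitis chronic	69
indication	asthma	69
indication	cough	69
country	united states	2275
country	germany	450
country	canada	32
country	south korea	25
country	netherlands	16
country	france	14
country	japan	14
country	united kingdom	14
country	italy	14
country	spain	14
country	australia	14
country	brazil	14
country	india	14
country	china	14
country	switzerland	14
country	sweden	14
country	belgium	10
year	2013	783
year	2014	305
year	2023	288
year	2012	217
year	2024	214
year	2011	131
year	2015	128
year	2016	128
year	2017	128
year	2018	128
year	2019	128
year	2020	128
year	2021	128
year	2022	128
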