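# Morphine milligram equivalent (MME) conversion factors, mg oral morphine per mg (or per mcg
# where noted) of drug, following the CDC oral-MME conversion file. Edit or extend as needed;
# morphine must stay exactly 1.
# drug_code	mme_per_unit
morphine	1.0
codeine	0.15
hydrocodone	1.0
hydromorphone	4.0
oxycodone	1.5
oxymorphone	3.0
tapentadol	0.4
tramadol	0.1
meperidine	0.1
butorphanol	7.0
pentazocine	0.37
fentanyl_mcg_hr_patch	2.4
buprenorphine_mcg_hr_patch	1.8
methadone	4.7
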