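sample	name	kind	abundance	host_name
day102_10um	Freya	phage	53.8	Polaribacter_HaHaR_3_91_R2A056_3_33
day102_10um	Freya_relatives	relative	63.3	Polaribacter_HaHaR_3_91_R2A056_3_33
day102_10um	Danklef	phage	10.4	Polaribacter_HaHaR_3_91_R2A056_3_33
day102_10um	Danklef_relatives	relative	45.8	Polaribacter_HaHaR_3_91_R2A056_3_33
day102_10um	Ingeline	phage	0.7
day102_10um	Ingeline_relatives	relative	0.8
day102_10um	Polaribacter_HaHaR_3_91_R2A056_3_33	host	0.14
day102_10um	Olleya_HaHaR_3_96	host	0.05
day116_10um	Polaribacter_HaHaR_3_91_R2A056_3_33	host	0.06
day116_10um	Olleya_HaHaR_3_96	host	0.03
day122_0.2um	Polaribacter_HaHaR_3_91_R2A056_3_33	host	0.07
day122_0.2um	Olleya_HaHaR_3_96	host	0.05
day128_3um	Harreka	phage	1.8
day128_3um	Harreka_relatives	relative	5.7
day142_10um	Freya_relatives	relative	0.04	Polaribacter_HaHaR_3_91_R2A056_3_33_AHE13PA
day142_10um	Danklef_relatives	relative	0.03	Polaribacter_HaHaR_3_91_R2A056_3_33_AHE13PA
day142_10um	Leef_relatives	relative	0.02	Polaribacter_HaHaR_3_91_R2A056_3_33_AHE13PA
day142_10um	Polaribacter_HaHaR_3_91_R2A056_3_33_AHE13PA	host	0.46
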