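hybrid_id	system	days_to_heading	plant_height	tillers	grains_per_panicle	spikelet_fertility	thousand_grain_weight	yield_per_plant
1.1	WA	85.1 ± 0.7	110.2 ± 5.2	10.4 ± 2.0	244.2 ± 33.8	82.9 ± 9.3	20.5 ± 0.8	43.0 ± 10.7
1.2	FA	84.2 ± 0.8	107.2 ± 4.5	10.7 ± 2.7	220.4 ± 44.8	85.8 ± 3.7	20.7 ± 1.0	41.6 ± 12.5
2.1	WA	79.2 ± 0.6	115.1 ± 5.7	9.1 ± 2.9	190.5 ± 20.8	79.3 ± 7.8	24.1 ± 0.9	34.3 ± 16.0
2.2	FA	79.1 ± 0.9	115.5 ± 1.9	8.8 ± 2.4	195.0 ± 21.3	87.9 ± 6.2	24.8 ± 1.0	38.5 ± 15.1
3.1	WA	86.1 ± 0.6	119.7 ± 4.5	8.5 ± 2.3	215.2 ± 36.1	63.0 ± 8.6	25.1 ± 1.1	29.0 ± 10.3
3.2	FA	86.9 ± 0.6	115.3 ± 4.1	7.9 ± 1.5	211.6 ± 39.6	74.2 ± 7.0	26.0 ± 0.7	32.2 ± 9.9
4.1	WA	81.6 ± 0.5	113.9 ± 3.7	10.1 ± 2.8	194.7 ± 36.5	77.1 ± 7.3	22.5 ± 0.7	35.8 ± 17.0
4.2	FA	82.7 ± 0.7	116.1 ± 3.2	8.9 ± 2.5	203.4 ± 31.1	80.2 ± 9.5	23.4 ± 1.3	35.0 ± 13.8
5.1	WA	83.4 ± 0.7	109.5 ± 4.2	9.2 ± 2.7	190.4 ± 23.0	87.4 ± 5.5	25.2 ± 0.7	39.3 ± 15.1
5.2	FA	83.6 ± 0.5	106.7 ± 4.3	9.9 ± 3.1	181.3 ± 25.8	89.8 ± 3.3	25.2 ± 0.6	41.0 ± 14.3
6.1	WA	81.4 ± 0.5	106.6 ± 4.3	9.1 ± 2.8	260.4 ± 38.3	55.5 ± 9.2	22.1 ± 0.7	29.1 ± 11.6
6.2	FA	80.6 ± 0.5	107.0 ± 6.3	8.8 ± 3.3	242.7 ± 29.6	81.4 ± 7.1	22.4 ± 1.2	38.3 ± 14.1
7.1	WA	90.3 ± 0.7	113.9 ± 4.9	10.2 ± 2.6	241.4 ± 35.5	31.1 ± 12.2	24.7 ± 1.3	19.3 ± 9.1
7.2	FA	89.4 ± 0.5	118.4 ± 5.0	9.2 ± 2.4	233.6 ± 39.6	75.4 ± 6.4	24.5 ± 0.9	39.8 ± 13.3
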