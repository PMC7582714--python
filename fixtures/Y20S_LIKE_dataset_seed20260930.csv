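# generator: allokin.synth.generate_dataset
# enzyme_nM: 2.0
# temperature_K: 310.15
# replicates: 3
# noise_cv: 0.05
# seed: 20260930
# substrate_inhibition_Ksi_uM: None
# n_truncated_velocities: 0
substrate_uM,modulator_uM,replicate,velocity_nM_per_s,enzyme_nM
5.0,0.0,1,0.18343883492589647,2.0
5.0,0.0,2,0.1668863258522466,2.0
5.0,0.0,3,0.17985009400378313,2.0
10.0,0.0,1,0.3055816088788231,2.0
10.0,0.0,2,0.3106208946821976,2.0
10.0,0.0,3,0.32445083807351877,2.0
15.0,0.0,1,0.4539394209652826,2.0
15.0,0.0,2,0.46661877295974846,2.0
15.0,0.0,3,0.4188637778923793,2.0
20.0,0.0,1,0.5549221076758234,2.0
20.0,0.0,2,0.5328842162768807,2.0
20.0,0.0,3,0.5032697866970993,2.0
25.0,0.0,1,0.6259733247232844,2.0
25.0,0.0,2,0.598585466308818,2.0
25.0,0.0,3,0.6270268297832702,2.0
5.0,0.1,1,0.18864541253314698,2.0
5.0,0.1,2,0.1998601750408723,2.0
5.0,0.1,3,0.1850113144161553,2.0
10.0,0.1,1,0.3385580856992561,2.0
10.0,0.1,2,0.3315516517256105,2.0
10.0,0.1,3,0.343409057912348,2.0
15.0,0.1,1,0.43411401924681775,2.0
15.0,0.1,2,0.4497138420861697,2.0
15.0,0.1,3,0.4681201625712026,2.0
20.0,0.1,1,0.5890532901157084,2.0
20.0,0.1,2,0.564013107904653,2.0
20.0,0.1,3,0.587866805517759,2.0
25.0,0.1,1,0.6288798345009107,2.0
25.0,0.1,2,0.6373174591077293,2.0
25.0,0.1,3,0.6841492349919468,2.0
5.0,0.3,1,0.29335156200473295,2.0
5.0,0.3,2,0.26352356836124385,2.0
5.0,0.3,3,0.2880974780033934,2.0
10.0,0.3,1,0.4577592171534172,2.0
10.0,0.3,2,0.4071388600286228,2.0
10.0,0.3,3,0.44115691574182464,2.0
15.0,0.3,1,0.5714580008063975,2.0
15.0,0.3,2,0.544786700446582,2.0
15.0,0.3,3,0.5321549504466794,2.0
20.0,0.3,1,0.5627228149762662,2.0
20.0,0.3,2,0.6316757466918724,2.0
20.0,0.3,3,0.552628227890296,2.0
25.0,0.3,1,0.7057490997161164,2.0
25.0,0.3,2,0.6830894815483441,2.0
25.0,0.3,3,0.566555523216338,2.0
5.0,0.5,1,0.32557492539853605,2.0
5.0,0.5,2,0.3604226075118797,2.0
5.0,0.5,3,0.34991234486270223,2.0
10.0,0.5,1,0.45832336735820645,2.0
10.0,0.5,2,0.48107735632380605,2.0
10.0,0.5,3,0.5115981015001846,2.0
15.0,0.5,1,0.5276927543949074,2.0
15.0,0.5,2,0.5409785537444487,2.0
15.0,0.5,3,0.5937384624443054,2.0
20.0,0.5,1,0.6295100113581136,2.0
20.0,0.5,2,0.5991053391580151,2.0
20.0,0.5,3,0.6426834564722486,2.0
25.0,0.5,1,0.6834816938562744,2.0
25.0,0.5,2,0.6982110563232177,2.0
25.0,0.5,3,0.7161602280720588,2.0
5.0,1.0,1,0.33728033071698416,2.0
5.0,1.0,2,0.34431301025827127,2.0
5.0,1.0,3,0.3833203610045264,2.0
10.0,1.0,1,0.5076076951300903,2.0
10.0,1.0,2,0.515514613523393,2.0
10.0,1.0,3,0.5212397778664115,2.0
15.0,1.0,1,0.5937575227962912,2.0
15.0,1.0,2,0.5809138119080782,2.0
15.0,1.0,3,0.5825594159153217,2.0
20.0,1.0,1,0.6715713932527794,2.0
20.0,1.0,2,0.6549359778883141,2.0
20.0,1.0,3,0.6825789889576949,2.0
25.0,1.0,1,0.6683848398746467,2.0
25.0,1.0,2,0.6689727489065477,2.0
25.0,1.0,3,0.6974690636795883,2.0
5.0,2.0,1,0.324617287421691,2.0
5.0,2.0,2,0.2988966683378807,2.0
5.0,2.0,3,0.3253204821644622,2.0
10.0,2.0,1,0.4386008495703883,2.0
10.0,2.0,2,0.3939146187112332,2.0
10.0,2.0,3,0.37958903839732505,2.0
15.0,2.0,1,0.5330307746626148,2.0
15.0,2.0,2,0.5156084285002039,2.0
15.0,2.0,3,0.47987086391077843,2.0
20.0,2.0,1,0.5823633587072892,2.0
20.0,2.0,2,0.5550020675913498,2.0
20.0,2.0,3,0.5640324138444226,2.0
25.0,2.0,1,0.5579687936157127,2.0
25.0,2.0,2,0.5679201330874138,2.0
25.0,2.0,3,0.5775183403283435,2.0
5.0,3.0,1,0.2356921544875464,2.0
5.0,3.0,2,0.24148717884540039,2.0
5.0,3.0,3,0.22399874948370854,2.0
10.0,3.0,1,0.39634140323640193,2.0
10.0,3.0,2,0.4069528486111731,2.0
10.0,3.0,3,0.3944464373166621,2.0
15.0,3.0,1,0.48180224239418157,2.0
15.0,3.0,2,0.437662862652128,2.0
15.0,3.0,3,0.4091687111374079,2.0
20.0,3.0,1,0.5265975040446943,2.0
20.0,3.0,2,0.5604175919691872,2.0
20.0,3.0,3,0.5266640566845586,2.0
25.0,3.0,1,0.6372233257287694,2.0
25.0,3.0,2,0.586867664060673,2.0
25.0,3.0,3,0.5719611905854641,2.0
5.0,5.0,1,0.17920802682614223,2.0
5.0,5.0,2,0.17363854024885111,2.0
5.0,5.0,3,0.16554432671259164,2.0
10.0,5.0,1,0.306130276019021,2.0
10.0,5.0,2,0.28460297543236995,2.0
10.0,5.0,3,0.30514653426303323,2.0
15.0,5.0,1,0.38701477575359683,2.0
15.0,5.0,2,0.3862299732908538,2.0
15.0,5.0,3,0.36593552608995,2.0
20.0,5.0,1,0.4599274746214636,2.0
20.0,5.0,2,0.45227002989030235,2.0
20.0,5.0,3,0.432171573223189,2.0
25.0,5.0,1,0.48881029042042945,2.0
25.0,5.0,2,0.46611212970848903,2.0
25.0,5.0,3,0.48636819031048034,2.0
5.0,10.0,1,0.11056221547786206,2.0
5.0,10.0,2,0.10904886993258193,2.0
5.0,10.0,3,0.10699373186446293,2.0
10.0,10.0,1,0.18580049375262445,2.0
10.0,10.0,2,0.21117262008463306,2.0
10.0,10.0,3,0.1889255511367679,2.0
15.0,10.0,1,0.26825302774700743,2.0
15.0,10.0,2,0.2467520923041228,2.0
15.0,10.0,3,0.25344944826077337,2.0
20.0,10.0,1,0.301693142061102,2.0
20.0,10.0,2,0.2621101282753432,2.0
20.0,10.0,3,0.3151699330739518,2.0
25.0,10.0,1,0.3750795528901038,2.0
25.0,10.0,2,0.32423785330127247,2.0
25.0,10.0,3,0.34322765066329275,2.0
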