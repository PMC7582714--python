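# generator: allokin.synth.generate_dataset
# enzyme_nM: 2.0
# temperature_K: 310.15
# replicates: 3
# noise_cv: 0.05
# seed: 20260930
# substrate_inhibition_Ksi_uM: None
# n_truncated_velocities: 0
substrate_uM,modulator_uM,replicate,velocity_nM_per_s,enzyme_nM
5.0,0.0,1,0.158745346871088,2.0
5.0,0.0,2,0.14442104201195138,2.0
5.0,0.0,3,0.15563970175105937,2.0
10.0,0.0,1,0.27284130038593446,2.0
10.0,0.0,2,0.2773406722449075,2.0
10.0,0.0,3,0.2896888621539679,2.0
15.0,0.0,1,0.4161122581414195,2.0
15.0,0.0,2,0.4277350288163431,2.0
15.0,0.0,3,0.38395949860845857,2.0
20.0,0.0,1,0.5202410836525978,2.0
20.0,0.0,2,0.4995804966184587,2.0
20.0,0.0,3,0.47181688308922565,2.0
25.0,0.0,1,0.5983588625994586,2.0
25.0,0.0,2,0.5721792041976259,2.0
25.0,0.0,3,0.5993658928746138,2.0
5.0,0.1,1,0.15098377626165574,2.0
5.0,0.1,2,0.15995959587241085,2.0
5.0,0.1,3,0.14807519847202955,2.0
10.0,0.1,1,0.2856152830989585,2.0
10.0,0.1,2,0.2797044964203187,2.0
10.0,0.1,3,0.2897076733282032,2.0
15.0,0.1,1,0.3824899151039836,2.0
15.0,0.1,2,0.39623463342432996,2.0
15.0,0.1,3,0.41245210544219213,2.0
20.0,0.1,1,0.5382944614505303,2.0
20.0,0.1,2,0.5154119962744584,2.0
20.0,0.1,3,0.5372102164452149,2.0
25.0,0.1,1,0.592847007162632,2.0
25.0,0.1,2,0.6008011825412781,2.0
25.0,0.1,3,0.6449496456496612,2.0
5.0,0.3,1,0.1752936845182802,2.0
5.0,0.3,2,0.15746981860182507,2.0
5.0,0.3,3,0.172154080498212,2.0
10.0,0.3,1,0.3182760611676177,2.0
10.0,0.3,2,0.2830801606224233,2.0
10.0,0.3,3,0.30673262326054807,2.0
15.0,0.3,1,0.4447010614573389,2.0
15.0,0.3,2,0.42394580811637506,2.0
15.0,0.3,3,0.4141159472602953,2.0
20.0,0.3,1,0.4779671202192849,2.0
20.0,0.3,2,0.5365345593308043,2.0
20.0,0.3,3,0.4693929508576117,2.0
25.0,0.3,1,0.6430737635864331,2.0
25.0,0.3,2,0.6224264741425751,2.0
25.0,0.3,3,0.5162415265452888,2.0
5.0,0.5,1,0.18929978914361914,2.0
5.0,0.5,2,0.20956135832965167,2.0
5.0,0.5,3,0.2034503517744082,2.0
10.0,0.5,1,0.325362828473799,2.0
10.0,0.5,2,0.34151583906887734,2.0
10.0,0.5,3,0.36318245413795686,2.0
15.0,0.5,1,0.4285564860719801,2.0
15.0,0.5,2,0.4393463167764507,2.0
15.0,0.5,3,0.48219435834908164,2.0
20.0,0.5,1,0.5636796397934166,2.0
20.0,0.5,2,0.536454505380044,2.0
20.0,0.5,3,0.5754754852331958,2.0
25.0,0.5,1,0.6592836058515011,2.0
25.0,0.5,2,0.6734914877690263,2.0
25.0,0.5,3,0.690805184359578,2.0
5.0,1.0,1,0.34193446664487537,2.0
5.0,1.0,2,0.34906419022799223,2.0
5.0,1.0,3,0.38860980394432354,2.0
10.0,1.0,1,0.5594088568448328,2.0
10.0,1.0,2,0.5681226730891458,2.0
10.0,1.0,3,0.5744320881573236,2.0
15.0,1.0,1,0.6859289950575669,2.0
15.0,1.0,2,0.6710915010231807,2.0
15.0,1.0,3,0.6729925590470611,2.0
20.0,1.0,1,0.7996996524559496,2.0
20.0,1.0,2,0.7798903871729422,2.0
20.0,1.0,3,0.8128073734637788,2.0
25.0,1.0,1,0.8129117535122335,2.0
25.0,1.0,2,0.8136267879258177,2.0
25.0,1.0,3,0.8482849486571915,2.0
5.0,2.0,1,0.6577029983966617,2.0
5.0,2.0,2,0.6055907759503408,2.0
5.0,2.0,3,0.6591277324102158,2.0
10.0,2.0,1,0.7619219140613787,2.0
10.0,2.0,2,0.6842945711555322,2.0
10.0,2.0,3,0.6594086787011418,2.0
15.0,2.0,1,0.8563984454644025,2.0
15.0,2.0,2,0.8284066842395926,2.0
15.0,2.0,3,0.770988620942141,2.0
20.0,2.0,1,0.8923627389476778,2.0
20.0,2.0,2,0.8504366865676609,2.0
20.0,2.0,3,0.8642740003264207,2.0
25.0,2.0,1,0.8281902418767678,2.0
25.0,2.0,2,0.8429609644303702,2.0
25.0,2.0,3,0.8572075346102853,2.0
5.0,3.0,1,0.642203026595965,2.0
5.0,3.0,2,0.657993039589409,2.0
5.0,3.0,3,0.6103413801996108,2.0
10.0,3.0,1,0.8441393420717643,2.0
10.0,3.0,2,0.866739904223347,2.0
10.0,3.0,3,0.8401033890482458,2.0
15.0,3.0,1,0.9043496387402006,2.0
15.0,3.0,2,0.8214993972685458,2.0
15.0,3.0,3,0.768015470957835,2.0
20.0,3.0,1,0.9147600612123306,2.0
20.0,3.0,2,0.9735094199965866,2.0
20.0,3.0,3,0.9148756707555747,2.0
25.0,3.0,1,1.0503299128648393,2.0
25.0,3.0,2,0.9673290941618916,2.0
25.0,3.0,3,0.9427588777963307,2.0
5.0,5.0,1,0.6992124237900065,2.0
5.0,5.0,2,0.677482067857057,2.0
5.0,5.0,3,0.6459010345428937,2.0
10.0,5.0,1,0.8585270822225954,2.0
10.0,5.0,2,0.7981548420079819,2.0
10.0,5.0,3,0.8557682275597648,2.0
15.0,5.0,1,0.9091829549014122,2.0
15.0,5.0,2,0.9073392810501977,2.0
15.0,5.0,3,0.8596631543744658,2.0
20.0,5.0,1,0.9658764602880185,2.0
20.0,5.0,2,0.9497953474606702,2.0
20.0,5.0,3,0.9075873315145455,2.0
25.0,5.0,1,0.9496978520091037,2.0
25.0,5.0,2,0.9055981370580408,2.0
25.0,5.0,3,0.9449531539651754,2.0
5.0,10.0,1,0.739969950789534,2.0
5.0,10.0,2,0.7298414432896756,2.0
5.0,10.0,3,0.7160868309335563,2.0
10.0,10.0,1,0.8224634595745964,2.0
10.0,10.0,2,0.934775576611114,2.0
10.0,10.0,3,0.8362968216697144,2.0
15.0,10.0,1,0.9368943089930222,2.0
15.0,10.0,2,0.8618006400654038,2.0
15.0,10.0,3,0.8851916702945359,2.0
20.0,10.0,1,0.8999194521472095,2.0
20.0,10.0,2,0.7818474143240857,2.0
20.0,10.0,3,0.940119326437126,2.0
25.0,10.0,1,0.9984274850925556,2.0
25.0,10.0,2,0.8630915280477817,2.0
25.0,10.0,3,0.9136406328349848,2.0
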