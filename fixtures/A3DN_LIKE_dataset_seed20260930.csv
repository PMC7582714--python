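# generator: allokin.synth.generate_dataset
# enzyme_nM: 2.0
# temperature_K: 310.15
# replicates: 3
# noise_cv: 0.05
# seed: 20260930
# substrate_inhibition_Ksi_uM: None
# n_truncated_velocities: 0
substrate_uM,modulator_uM,replicate,velocity_nM_per_s,enzyme_nM
5.0,0.0,1,0.2082173629750891,2.0
5.0,0.0,2,0.1894289761467008,2.0
5.0,0.0,3,0.20414386255460787,2.0
10.0,0.0,1,0.36111009741664873,2.0
10.0,0.0,2,0.3670650925292261,2.0
10.0,0.0,3,0.38340813170501337,2.0
15.0,0.0,1,0.5550863547858922,2.0
15.0,0.0,2,0.5705909242385496,2.0
15.0,0.0,3,0.5121951451753526,2.0
20.0,0.0,1,0.6988273453269223,2.0
20.0,0.0,2,0.6710744752756124,2.0
20.0,0.0,3,0.6337802804321451,2.0
25.0,0.0,1,0.8087325698189196,2.0
25.0,0.0,2,0.7733485490586749,2.0
25.0,0.0,3,0.8100936563394294,2.0
5.0,0.1,1,0.9952929559702173,2.0
5.0,0.1,2,1.0544620286602655,2.0
5.0,0.1,3,0.9761194589390559,2.0
10.0,0.1,1,1.5152068580264944,2.0
10.0,0.1,2,1.4838497667160002,2.0
10.0,0.1,3,1.536917242967358,2.0
15.0,0.1,1,1.7357355833126416,2.0
15.0,0.1,2,1.7981089838368056,2.0
15.0,0.1,3,1.8717037170342228,2.0
20.0,0.1,1,2.1686408146391,2.0
20.0,0.1,2,2.0764536355500436,2.0
20.0,0.1,3,2.164272688752649,2.0
25.0,0.1,1,2.1733751252476545,2.0
25.0,0.1,2,2.2025351053115574,2.0
25.0,0.1,3,2.3643832219055776,2.0
5.0,0.3,1,0.8946056064180123,2.0
5.0,0.3,2,0.8036420875626547,2.0
5.0,0.3,3,0.8785827396159133,2.0
10.0,0.3,1,1.3826836753902099,2.0
10.0,0.3,2,1.2297824582959445,2.0
10.0,0.3,3,1.332535627518083,2.0
15.0,0.3,1,1.7154719537068104,2.0
15.0,0.3,2,1.6354068086364995,2.0
15.0,0.3,3,1.5974872890558995,2.0
20.0,0.3,1,1.6819574972711018,2.0
20.0,0.3,2,1.8880552373507853,2.0
20.0,0.3,3,1.6517851531271739,2.0
25.0,0.3,1,2.102727635525054,2.0
25.0,0.3,2,2.0352149665737427,2.0
25.0,0.3,3,1.6880105921573951,2.0
5.0,0.5,1,0.679813430542982,2.0
5.0,0.5,2,0.752576780776249,2.0
5.0,0.5,3,0.7306309331385696,2.0
10.0,0.5,1,1.0653256523506973,2.0
10.0,0.5,2,1.1182149655840168,2.0
10.0,0.5,3,1.1891573069109926,2.0
15.0,0.5,1,1.3111264155455409,2.0
15.0,0.5,2,1.3441368412785903,2.0
15.0,0.5,3,1.4752262098591282,2.0
20.0,0.5,1,1.6370000955938213,2.0
20.0,0.5,2,1.5579347107706631,2.0
20.0,0.5,3,1.671256788135715,2.0
25.0,0.5,1,1.8372154128181923,2.0
25.0,0.5,2,1.8768082972926436,2.0
25.0,0.5,3,1.925056107410622,2.0
5.0,1.0,1,0.4704915245669167,2.0
5.0,1.0,2,0.4803018094185027,2.0
5.0,1.0,3,0.5347153824925932,2.0
10.0,1.0,1,0.8732034399134454,2.0
10.0,1.0,2,0.8868051807979633,2.0
10.0,1.0,3,0.8966537966608736,2.0
15.0,1.0,1,1.1650816492023592,2.0
15.0,1.0,2,1.1398794895850042,2.0
15.0,1.0,3,1.1431085232512452,2.0
20.0,1.0,1,1.4433899437932802,2.0
20.0,1.0,2,1.4076359026159255,2.0
20.0,1.0,3,1.4670482668032316,2.0
25.0,1.0,1,1.5360780052756464,2.0
25.0,1.0,2,1.537429134264711,2.0
25.0,1.0,3,1.6029191928999258,2.0
5.0,2.0,1,0.3534289112684537,2.0
5.0,2.0,2,0.3254254414836395,2.0
5.0,2.0,3,0.35419451852961126,2.0
10.0,2.0,1,0.5922268996811622,2.0
10.0,2.0,2,0.5318886947139896,2.0
10.0,2.0,3,0.5125453805736968,2.0
15.0,2.0,1,0.8338115025482253,2.0
15.0,2.0,2,0.8065580055230489,2.0
15.0,2.0,3,0.750654305691488,2.0
20.0,2.0,1,1.014869752585936,2.0
20.0,2.0,2,0.9671879293220137,2.0
20.0,2.0,3,0.9829248831165737,2.0
25.0,2.0,1,1.0565970280763564,2.0
25.0,2.0,2,1.075441371759168,2.0
25.0,2.0,3,1.09361700695896,2.0
5.0,3.0,1,0.2316091013224261,2.0
5.0,3.0,2,0.23730373458920734,2.0
5.0,3.0,3,0.2201182690109876,2.0
10.0,3.0,1,0.4718020141821897,2.0
10.0,3.0,2,0.4844338039985444,2.0
10.0,3.0,3,0.4695462601013914,2.0
15.0,3.0,1,0.6595338560997442,2.0
15.0,3.0,2,0.599111938629069,2.0
15.0,3.0,3,0.5601066041345513,2.0
20.0,3.0,1,0.8024953892927522,2.0
20.0,3.0,2,0.8540346852757759,2.0
20.0,3.0,3,0.8025968105608482,2.0
25.0,3.0,1,1.0576900227728643,2.0
25.0,3.0,2,0.9741075819142231,2.0
25.0,3.0,3,0.9493651915577099,2.0
5.0,5.0,1,0.15949558474278439,2.0
5.0,5.0,2,0.15453872798756815,2.0
5.0,5.0,3,0.14733485802781957,2.0
10.0,5.0,1,0.31691263437337713,2.0
10.0,5.0,2,0.2946271106134233,2.0
10.0,5.0,3,0.31589424378657416,2.0
15.0,5.0,1,0.45139795840694585,2.0
15.0,5.0,2,0.45048259741395763,2.0
15.0,5.0,3,0.4268119972007037,2.0
20.0,5.0,1,0.5911756131042086,2.0
20.0,5.0,2,0.5813329860955012,2.0
20.0,5.0,3,0.555499092496498,2.0
25.0,5.0,1,0.6813308575351289,2.0
25.0,5.0,2,0.6496929039048258,2.0
25.0,5.0,3,0.6779269231362292,2.0
5.0,10.0,1,0.0898352193860182,2.0
5.0,10.0,2,0.08860557932788898,2.0
5.0,10.0,3,0.086935716089168,2.0
10.0,10.0,1,0.16625887537376793,2.0
10.0,10.0,2,0.1889624812932292,2.0
10.0,10.0,3,0.1690552539822012,2.0
15.0,10.0,1,0.2609101334375298,2.0
15.0,10.0,2,0.23999774343563418,2.0
15.0,10.0,3,0.2465117725632992,2.0
20.0,10.0,1,0.3156602249749461,2.0
20.0,10.0,2,0.27424468946944086,2.0
20.0,10.0,3,0.3297609329127982,2.0
25.0,10.0,1,0.41864566016400306,2.0
25.0,10.0,2,0.36189861350624375,2.0
25.0,10.0,3,0.3830941070801975,2.0
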