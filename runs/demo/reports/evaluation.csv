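task_id,stratum,n,mae,baseline_mae,bootstrap_q1,bootstrap_median,bootstrap_q3,bootstrap_whisker_low,bootstrap_whisker_high,error_low_pct,error_high_pct,precision_low_pct,precision_high_pct,inconclusive_pct
CYP3A4_IC50,glue,163,0.35717168037016456,0.47480877105256375,0.3433296826244232,0.35627926753135464,0.3699376878913751,0.3034176747239954,0.40984969579180297,0.0,0.0,76.47058823529412,0.0,88.34355828220859
CYP3A4_IC50,heterobifunctional,152,0.41845060970928366,1.1200693701794409,0.4025921272891719,0.41809231092372173,0.435164487825035,0.3537335864853772,0.4840230286288296,0.0,0.0,0.0,97.14285714285714,7.894736842105263
CYP3A4_IC50,other,181,0.40078251235547785,0.5932932582828553,0.3866103003616745,0.401774741301799,0.41671897859245316,0.3414472830155065,0.46188199593862117,0.0,0.0,42.1875,0.0,64.08839779005525
CYP3A4_IC50,all,496,0.3918651437751803,0.7157872050363705,0.3818599748359215,0.3911150645297198,0.40010599643073774,0.3544909424436971,0.4274750288229621,0.0,0.0,49.382716049382715,95.1048951048951,54.83870967741935
CYP3A4_kobs,glue,139,0.2840554691158399,0.393388214573959,0.2702873577212259,0.284260601053594,0.295894499881768,0.23187664448041276,0.3343052131225812,0.0,10.526315789473685,85.18518518518519,63.1578947368421,66.90647482014388
CYP3A4_kobs,heterobifunctional,130,0.4049526104034542,0.7715030776737192,0.38423014133632594,0.40191026112366296,0.4181460401149645,0.3333562931683681,0.4690198882829223,0.0,0.78125,0.0,90.625,1.5384615384615385
CYP3A4_kobs,other,155,0.3375834046358254,0.4360830656909674,0.3243041091467875,0.33917656339001534,0.3495378763014248,0.2864534584148315,0.3873885270333808,10.294117647058824,40.0,64.70588235294117,20.0,46.45161290322581
CYP3A4_kobs,all,424,0.3406909841464711,0.5249274460034522,0.3344634255853309,0.34178612157734356,0.3500348994987806,0.3111062147151563,0.37339211036895514,7.368421052631579,5.555555555555555,70.52631578947368,80.8641975308642,39.386792452830186
HLM_CLint,glue,219,0.27523942604352847,0.5057254828677562,0.2659569613920482,0.2735834086058564,0.28313687878062815,0.24018708530917832,0.30890675486349806,0.0,8.333333333333334,81.72043010752688,33.333333333333336,46.57534246575342
HLM_CLint,heterobifunctional,204,0.361767394483773,0.7935066370084607,0.3507696654137278,0.3634434597841312,0.3735740932861825,0.3165630236050457,0.4077807350948646,0.0,0.0,0.0,93.29896907216495,4.901960784313726
HLM_CLint,other,245,0.30038531866481766,0.36084579872624756,0.29022019098262364,0.29993833530311703,0.3091595862891082,0.26181109802289676,0.3375686792488351,2.2222222222222223,15.625,62.22222222222222,45.3125,55.51020408163265
HLM_CLint,all,668,0.3108868051663215,0.5404737356073281,0.3056337259394551,0.31100993005450994,0.3167683317915172,0.28893181716136196,0.3334702405696104,0.7246376811594203,4.25531914893617,75.3623188405797,77.30496453900709,37.125748502994014
LE-MDCK_v2_Papp,glue,252,0.3675864677624188,0.5246313461745485,0.3544326555680093,0.3659225569826396,0.3786902409722128,0.318046277461704,0.4150766190785181,0.0,9.836065573770492,75.78947368421052,40.98360655737705,38.095238095238095
LE-MDCK_v2_Papp,heterobifunctional,216,0.5255869536778224,1.2602617462043209,0.5082533380386226,0.5248946319921101,0.5443636912817703,0.45408780817390104,0.5985292211464919,0.0,0.5076142131979695,0.0,96.95431472081218,8.796296296296296
LE-MDCK_v2_Papp,other,285,0.3915855266632771,0.8268574169793496,0.3811092891108825,0.3901086571850924,0.402305123343535,0.3493155377619037,0.43409887469251385,1.8518518518518519,15.384615384615385,85.64814814814815,23.076923076923077,19.649122807017545
LE-MDCK_v2_Papp,all,753,0.4219926254576005,0.85003718493391,0.4132409155641177,0.42106790635806024,0.43033157705902986,0.38760492332174945,0.45596756930139815,1.2861736334405145,3.321033210332103,82.63665594855306,80.81180811808117,22.709163346613547
LogD,glue,223,0.37048878020460513,0.7750487138575017,0.3579723255660508,0.3715171495060345,0.384442154659822,0.31826758192539395,0.4241468983004788,,,,,
LogD,heterobifunctional,200,0.4904159872467491,0.8159021112753713,0.472530945530631,0.4918793122541357,0.5099136447210051,0.4164568967450699,0.5659876935065662,,,,,
LogD,other,265,0.4140006092162281,0.6155786666885604,0.4039211251490626,0.4152308740348959,0.42838177610483175,0.3672301487154088,0.46507275253848546,,,,,
LogD,all,688,0.42211098383325174,0.7255009187758222,0.41370059518084046,0.42210965258419064,0.4314888177875318,0.38701826127080347,0.4581711516975688,,,,,
RLM_CLint,glue,224,0.2553232748618845,0.4557934499945952,0.24682716855679343,0.25621918645236397,0.26567118783729604,0.21856113963603951,0.29393721675804996,5.825242718446602,0.0,73.7864077669903,65.21739130434783,43.75
RLM_CLint,heterobifunctional,185,0.36802175233000944,0.6187475232974594,0.3545110040422289,0.3679414831659884,0.3794413702190657,0.31711545477697367,0.4168369194843209,0.0,2.4242424242424243,0.0,80.0,10.81081081081081
RLM_CLint,other,238,0.24766281682250862,0.3065773623798549,0.23947545479158883,0.24891087618760666,0.25776595001688063,0.21203971195365112,0.28520169285481833,14.285714285714286,2.7027027027027026,57.142857142857146,64.86486486486487,50.42016806722689
RLM_CLint,all,647,0.28472981167522554,0.44749835680869365,0.2786995882023502,0.28483518522118145,0.290865734949841,0.26045036808111394,0.3091149550710773,6.363636363636363,2.3411371237458196,72.72727272727273,73.24414715719064,36.78516228748068
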