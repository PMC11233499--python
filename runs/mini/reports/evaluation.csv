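task_id,stratum,n,mae,baseline_mae,bootstrap_q1,bootstrap_median,bootstrap_q3,bootstrap_whisker_low,bootstrap_whisker_high,error_low_pct,error_high_pct,precision_low_pct,precision_high_pct,inconclusive_pct
CYP3A4_IC50,glue,31,0.992665869759853,0.5800650758608131,0.9530914675319015,0.9847482982282549,1.0431515318252962,0.8180013710918096,1.178241628265388,0.0,35.483870967741936,0.0,0.0,0.0
CYP3A4_IC50,heterobifunctional,41,0.6469053264298044,0.999706559497513,0.6158574629872747,0.6527462212383788,0.6774806656067998,0.5234226590579871,0.7699154695360872,0.0,0.0,0.0,87.8048780487805,0.0
CYP3A4_IC50,other,49,1.0404301078921336,0.6194938685862345,0.9973273545945214,1.0346011668036077,1.0846830913078476,0.8662937495245321,1.2157166963778367,0.0,32.6530612244898,0.0,6.122448979591836,0.0
CYP3A4_IC50,all,121,0.89484988126357,0.7382246764612291,0.8635403169845186,0.9028911908254813,0.9152249119831907,0.7860134244865105,0.9927518044811987,0.0,22.31404958677686,0.0,32.231404958677686,0.0
CYP3A4_kobs,glue,35,0.407499795932773,0.3909636240001793,0.37293753412236863,0.3996691657871879,0.44457932958150986,0.2654748409336568,0.5520420227702217,0.0,0.0,0.0,0.0,100.0
CYP3A4_kobs,heterobifunctional,37,0.4957409202557721,0.521611828333435,0.4525955974813866,0.4777227130318411,0.5182126687152465,0.35416999063059673,0.6166382755660363,0.0,0.0,0.0,0.0,100.0
CYP3A4_kobs,other,39,0.3097837246985672,0.28750933948272234,0.28482407132277254,0.30599074335479304,0.32668040416258204,0.2220395720630583,0.3894649034222963,0.0,27.272727272727273,0.0,18.181818181818183,71.7948717948718
CYP3A4_kobs,all,111,0.40258083036355624,0.3981642227763021,0.37686320159238706,0.3989375552747708,0.41420741891705953,0.3208468756053784,0.47022374490406826,0.0,27.272727272727273,0.0,18.181818181818183,90.09009009009009
HLM_CLint,glue,49,0.4596542170342148,0.47106536330308274,0.42832303327521937,0.46141254304034907,0.4923795670568799,0.33223823260272856,0.5884643677293707,0.0,0.0,0.0,0.0,100.0
HLM_CLint,heterobifunctional,55,0.8252582698758572,0.8138870369142257,0.7926836777782758,0.8321167274357384,0.8690609854294787,0.6781177163014713,0.9836269469062833,0.0,0.0,0.0,0.0,100.0
HLM_CLint,other,61,0.43283645976830554,0.4308895072543016,0.40639885331187287,0.428450452343739,0.45989484201817366,0.3261548702524217,0.5401388250776249,0.0,0.0,0.0,0.0,100.0
HLM_CLint,all,165,0.5716077910528201,0.570486362270581,0.5493285361376761,0.5687822483413367,0.5931137893118437,0.4836506563764247,0.658791669073095,0.0,0.0,0.0,0.0,100.0
LE-MDCK_v2_Papp,glue,56,0.5788496071381496,0.3620914070985516,0.5473644924213065,0.5816438207668161,0.6073299053850822,0.4574163729756428,0.697278024830746,0.0,42.857142857142854,0.0,10.714285714285714,0.0
LE-MDCK_v2_Papp,heterobifunctional,60,0.9686122210023427,1.2616466557983343,0.9087581125296635,0.9874691024015991,1.036684498287494,0.7168685338929177,1.22857407692424,0.0,0.0,0.0,98.33333333333333,0.0
LE-MDCK_v2_Papp,other,70,1.1923160919015845,0.8996318812820783,1.1680188748125342,1.1977214618606866,1.2298260518251298,1.0753081092936407,1.3225368173440233,0.0,87.14285714285714,0.0,0.0,0.0
LE-MDCK_v2_Papp,all,186,0.9354539660913324,0.8545706980385185,0.901310906813513,0.9272782196980328,0.9554378131590127,0.8201205472952635,1.0366281726772621,0.0,45.69892473118279,0.0,34.946236559139784,0.0
LogD,glue,49,0.6312718028945357,0.8257845456689482,0.5755798813510868,0.6233832394930423,0.6732531557019662,0.4290699698247678,0.8197630672282852,,,,,
LogD,heterobifunctional,57,1.128049832908578,0.898319797804068,1.061061566301511,1.131492878190492,1.2099417138534334,0.8377413449736275,1.433261935181317,,,,,
LogD,other,59,0.9572706506086407,0.6577610179794439,0.888643543625416,0.9443960105447053,0.9991077389256746,0.7229472506750281,1.1648040318760626,,,,,
LogD,all,165,0.9194553163850364,0.7907610380205912,0.8800195886937402,0.9196281845769769,0.9637114765174329,0.7544817569582011,1.0892493082529722,,,,,
RLM_CLint,glue,44,0.5075007171057873,0.47177863909078666,0.467470531003943,0.5115040256430885,0.5456490641479228,0.35020273128797325,0.6629168638638925,0.0,0.0,0.0,0.0,100.0
RLM_CLint,heterobifunctional,52,0.4962900688718565,0.529000244127163,0.4646521769899168,0.48255288024024434,0.5218860123541025,0.37880142394363825,0.607736765400381,0.0,0.0,0.0,0.0,100.0
RLM_CLint,other,57,0.4304860178359138,0.4416841515419727,0.3924396884184479,0.4218811271667149,0.46432633709426885,0.28460971540471647,0.5721563101080003,0.0,0.0,0.0,100.0,94.73684210526316
RLM_CLint,all,153,0.4749988114420802,0.48001483302287284,0.4596802500945473,0.47629839051671896,0.49335112759544364,0.4091739338432029,0.5438574438467881,0.0,0.0,0.0,100.0,98.03921568627452
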