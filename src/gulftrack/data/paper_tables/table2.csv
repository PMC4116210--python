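tag,site,period,first_foraging_date,last_foraging_date,days,filtered_locations,daily_locations,kde50_km2,kde95_km2,region
108170,GS,F1,7/25/2011,3/1/2012,221,487,78,97.6,534.3,NGoM
106360,GS,F1,8/31/2011,12/24/2011,116,196,39,127.2,721.8,WFL
108172,GS,F1,8/10/2011,2/25/2012,200,447,109,206.1,875.9,WFL
106345,GS,F1,7/27/2011,11/10/2011,107,204,35,56.6,276.0,NGoM
108173,GS,F1,7/19/2011,4/2/2012,259,659,123,31.9,190.7,WFL
108174,GS,F1,8/16/2011,11/7/2011,84,141,31,83.2,357.5,WFL
106361,GS,F1,7/1/2011,6/18/2012,354,744,116,851.8,3628.5,NGoM
108964,GS,F1,8/21/2011,9/14/2011,25,149,25,330.5,1432.0,WFL
108965,GS,F1,8/11/2011,7/21/2012,346,1166,170,84.7,685.9,WFL
119941,GS,F1,9/26/2012,8/31/2013,340,359,64,10.4,78.4,SNWA
119943,GS,F1,8/2/2012,11/20/2012,111,273,37,25.9,168.6,WFL
119938,GS,F1,8/7/2012,2/22/2013,200,529,98,31.6,181.0,WFL
119924,GS,F1,7/16/2012,9/10/2012,57,426,57,115.0,584.6,NGoM
119944,GS,F1,6/28/2012,7/15/2013,383,775,125,52.3,292.2,NGoM
119923,GS,F1,7/31/2012,1/7/2013,161,741,112,25.8,120.8,WFL
129502,GS,F1,8/6/2013,10/15/2013,71,941,71,56.9,222.2,SNWA
129504,GS,F1,7/23/2013,10/14/2013,84,507,84,249.3,1452.3,WFL
129505,GS,F1,8/20/2013,10/15/2013,57,815,57,7.8,48.6,WFL
129506,GS,F1,9/10/2013,10/15/2013,36,209,36,170.7,898.4,WFL
129507,GS,F1,9/6/2013,10/15/2013,40,707,40,26.9,106.3,SGoM
129508,GS,F1,8/18/2013,10/15/2013,59,444,59,4.5,22.0,WFL
129510,GS,F1,8/7/2013,10/14/2013,69,419,69,38.2,189.4,NGoM
129511,GS,F1,8/8/2013,9/23/2013,47,270,47,106.8,496.3,NGoM
129512,GS,F1,7/26/2013,10/15/2013,82,670,82,44.0,194.7,WGoM
129515,GS,F1,8/9/2013,9/22/2013,45,298,45,38.1,177.8,NGoM
129513,GS,F1,7/22/2013,8/12/2013,22,201,22,55.2,238.1,NGoM
57656,SJP,F1,8/15/2010,9/12/2010,29,52,15,229.4,911.7,SGoM
52968,SJP,F1,8/21/2010,9/29/2011,405,801,363,75.8,1037.6,WFL
52968,SJP,F2,10/3/2011,3/6/2012,156,266,134,34.6,305.4,WFL
89971,SJP,F1,8/23/2010,9/16/2010,25,133,25,53.8,236.8,WFL
47755,SJP,F1,9/7/2010,1/4/2011,120,325,114,47.9,307.1,SGoM
119942,SJP,F2,9/4/2012,9/29/2012,26,121,26,186.4,893.5,NGoM
129497,SJP,F1,7/21/2013,10/12/2013,84,540,79,5.2,26.8,WFL
129498,SJP,F1,7/3/2013,10/15/2013,105,547,60,34.2,134.8,NGoM
129499,SJP,F1,9/2/2013,10/15/2013,44,296,44,105.8,489.4,SGoM
129500,SJP,F1,8/16/2013,10/15/2013,61,327,61,77.4,418.7,WFL
129514,SJP,F1,7/31/2013,10/15/2013,77,701,77,26.6,105.3,WFL
120439,EAFB,F1,8/31/2012,1/9/2013,132,443,65,77.8,366.3,SGoM
120439,EAFB,F2,1/14/2013,4/6/2013,83,126,32,77.1,309.4,SGoM
120438,EAFB,F1,8/24/2012,10/13/2013,416,1483,255,67.2,453.9,SGoM
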