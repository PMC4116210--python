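tag,site,period,estimator,depth_m,dist_to_land_km,region,trawl_days_fished,trawl_zone_class,jurisdiction,oiled
108170,GS,F1,KDE,-21,4.1,NGoM,9248.8,3,Florida,1
106360,GS,F1,KDE,-64,52.8,SNWA,48.8,1,USA,0
108172,GS,F1,KDE,-66,38.6,SNWA,48.8,1,USA,0
106345,GS,F1,KDE,-32,25.8,NGoM,9248.8,3,USA,1
108171,GS,F1,MCP,-10,8.4,SGoM,,,Mexico,0
108173,GS,F1,KDE,-46,90.2,WFL,9248.8,3,USA,0
108174,GS,F1,KDE,-44,20.9,SNWA,9248.8,3,USA,0
106361,GS,F1,KDE,-28,22.7,NGoM,2502.8,2,USA,1
108961,GS,F1,MCP,-7,1.6,NGoM,2095.7,2,Florida,0
108964,GS,F1,KDE,-58,120.4,WFL,48.8,1,USA,0
108965,GS,F1,KDE,-14,36.4,WFL,1143.3,2,USA,0
119941,GS,F1,KDE,-11,8.9,SNWA,1143.3,2,Florida,0
119943,GS,F1,KDE,-29,80.6,WFL,9248.8,3,USA,0
119938,GS,F1,KDE,-22,42.8,WFL,9248.8,3,USA,0
119924,GS,F1,KDE,-36,34.8,NGoM,2502.8,2,USA,1
119944,GS,F1,KDE,-32,25.0,NGoM,9248.8,3,USA,1
119946,GS,F1,MCP,-8,10.3,NGoM,6815.0,3,USA,1
119923,GS,F1,KDE,-37,111.4,WFL,9248.8,3,USA,0
129502,GS,F1,KDE,-18,21.3,SNWA,1143.3,2,USA,0
129504,GS,F1,KDE,-52,90.1,WFL,9248.8,3,USA,0
129505,GS,F1,KDE,-2,6.3,WFL,1143.3,2,Florida,0
129506,GS,F1,KDE,-63,128.9,WFL,48.8,1,USA,0
129507,GS,F1,KDE,-3,12.5,SGoM,,,Mexico,0
129508,GS,F1,KDE,-2,0.6,WFL,2095.7,2,Florida,0
129510,GS,F1,KDE,-44,42.3,NGoM,9248.8,3,USA,0
129512,GS,F1,KDE,-16,14.2,NGoM,6815.0,3,USA,1
129513,GS,F1,KDE,-12,12.3,WGoM,10108.0,4,Texas,0
129511,GS,F1,KDE,-48,61.3,NGoM,9248.8,3,USA,1
129515,GS,F1,KDE,-27,27.5,NGoM,9248.8,3,USA,0
57656,SJP,F1,KDE,-33,58.9,SGoM,,,Mexico,0
52968,SJP,F1,KDE,-16,26.6,WFL,1143.3,2,USA,0
52968,SJP,F2,KDE,-15,27.0,WFL,1143.3,2,USA,0
89971,SJP,F1,KDE,-31,67.4,WFL,9248.8,3,USA,0
47755,SJP,F1,KDE,-30,54.2,SGoM,,,Mexico,0
119942,SJP,F2,KDE,-28,31.3,NGoM,2502.8,2,USA,1
119948,SJP,F1,MCP,-2,7.2,WFL,1143.3,2,Florida,0
119952,SJP,F1,MCP,-37,41.4,NGoM,2502.8,2,USA,1
129496,SJP,F1,MCP,-20,25.2,SGoM,,,Mexico,0
129496,SJP,F2,MCP,-20,28.6,SGoM,,,Mexico,0
129496,SJP,F3,MCP,-20,34.2,SGoM,,,Mexico,0
129497,SJP,F1,KDE,-6,12.6,WFL,1143.3,2,Florida,0
129498,SJP,F1,KDE,-6,3.8,NGoM,1143.3,2,Florida,0
129499,SJP,F1,KDE,-64,28.9,SGoM,,,Mexico,0
129500,SJP,F1,KDE,-41,78.5,WFL,9248.8,3,USA,0
129514,SJP,F1,KDE,-23,33.1,WFL,9248.8,3,USA,0
120438,EAFB,F1,KDE,-45,74.0,SGoM,,,Mexico,0
120439,EAFB,F1,KDE,-62,138.4,SGoM,,,Mexico,0
120439,EAFB,F2,KDE,-72,137.7,SGoM,,,Mexico,0
120439,EAFB,F3,MCP,-60,136.5,SGoM,,,Mexico,0
120439,EAFB,F4,MCP,-65,136.4,SGoM,,,Mexico,0
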