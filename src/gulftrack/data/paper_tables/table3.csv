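tag,site,period,first_foraging_date,last_foraging_date,days,filtered_locations,site_fidelity_p,mcp_km2,region
108171,GS,F1,9/4/2012,9/20/2012,17,33,96.0396,205.2,SGoM
108961,GS,F1,7/31/2011,8/17/2011,18,233,99.0099,199.1,NGoM
119946,GS,F1,7/17/2012,9/4/2012,50,243,99.0099,796.9,NGoM
119948,SJP,F1,8/12/2012,10/12/2012,62,194,99.0099,148.5,WFL
119952,SJP,F1,8/13/2012,10/3/2012,52,124,98.0198,1987.1,NGoM
129496,SJP,F1,8/22/2013,9/5/2013,15,47,99.0099,809.5,SGoM
129496,SJP,F2,9/13/2013,9/19/2013,7,16,98.0198,238.7,SGoM
129496,SJP,F3,9/28/2013,10/15/2013,18,92,99.0099,911.8,SGoM
120439,EAFB,F3,4/18/2013,4/23/2013,6,18,98.0198,355.4,SGoM
120439,EAFB,F4,5/10/2013,5/24/2013,15,62,99.0099,832.2,SGoM
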