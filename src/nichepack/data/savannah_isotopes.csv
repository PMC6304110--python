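specimen_id,species,site,foraging_group,d13C,d15N
savannah_open_01_i1,savannah_open_01,savannah,open,-19.309547742119168,11.467204915606558
savannah_open_01_i2,savannah_open_01,savannah,open,-20.50654199340878,11.551936226390078
savannah_open_01_i3,savannah_open_01,savannah,open,-19.646885533349536,11.491773910860925
savannah_open_02_i1,savannah_open_02,savannah,open,-20.696857498024357,9.905899114740196
savannah_open_02_i2,savannah_open_02,savannah,open,-20.46693487476384,9.422348304234808
savannah_open_02_i3,savannah_open_02,savannah,open,-19.995661511460266,10.297737141683085
savannah_edge_01_i1,savannah_edge_01,savannah,edge,-18.204050842735086,7.9338466575727455
savannah_edge_01_i2,savannah_edge_01,savannah,edge,-17.338525559809575,8.607570067675478
savannah_edge_01_i3,savannah_edge_01,savannah,edge,-17.26145397660635,7.868733572691198
savannah_edge_02_i1,savannah_edge_02,savannah,edge,-20.620650214345204,7.096388008164579
savannah_edge_02_i2,savannah_edge_02,savannah,edge,-21.450766166888883,7.160082224258069
savannah_edge_02_i3,savannah_edge_02,savannah,edge,-20.599265300404845,6.964348781613175
savannah_edge_03_i1,savannah_edge_03,savannah,edge,-19.727708858641833,10.96597895123395
savannah_edge_03_i2,savannah_edge_03,savannah,edge,-19.53369816907284,11.145856962778327
savannah_edge_03_i3,savannah_edge_03,savannah,edge,-19.558662504657722,10.728358883583143
savannah_edge_04_i1,savannah_edge_04,savannah,edge,-20.43779896673649,10.858995374811748
savannah_edge_04_i2,savannah_edge_04,savannah,edge,-19.899861046519554,10.30891803999716
savannah_edge_04_i3,savannah_edge_04,savannah,edge,-20.143725764770515,10.66354436234253
savannah_edge_05_i1,savannah_edge_05,savannah,edge,-19.57952274152695,10.538714264542875
savannah_edge_05_i2,savannah_edge_05,savannah,edge,-18.986949625196516,8.935318353101989
savannah_edge_05_i3,savannah_edge_05,savannah,edge,-19.72171502678598,9.428150468209402
savannah_edge_06_i1,savannah_edge_06,savannah,edge,-20.403256261982918,11.063518720846924
savannah_edge_06_i2,savannah_edge_06,savannah,edge,-20.38840974482713,10.633258395166218
savannah_edge_06_i3,savannah_edge_06,savannah,edge,-20.559209696859398,10.692267723752453
savannah_edge_07_i1,savannah_edge_07,savannah,edge,-19.507582731264186,10.806996980063328
savannah_edge_07_i2,savannah_edge_07,savannah,edge,-19.34750255778203,10.229197027351034
savannah_edge_07_i3,savannah_edge_07,savannah,edge,-19.885184593309816,9.864315643898875
savannah_edge_08_i1,savannah_edge_08,savannah,edge,-20.58713414538959,11.120032542211849
savannah_edge_08_i2,savannah_edge_08,savannah,edge,-20.25486729780894,10.963467454294747
savannah_edge_08_i3,savannah_edge_08,savannah,edge,-20.680120759725817,11.275568736259833
savannah_clutter_01_i1,savannah_clutter_01,savannah,clutter,-21.840782220158022,8.82266910230805
savannah_clutter_01_i2,savannah_clutter_01,savannah,clutter,-20.490837761773143,9.051602873588797
savannah_clutter_01_i3,savannah_clutter_01,savannah,clutter,-20.83104886295063,8.960403288442162
savannah_clutter_02_i1,savannah_clutter_02,savannah,clutter,-22.216572704064568,9.155194799828507
savannah_clutter_02_i2,savannah_clutter_02,savannah,clutter,-21.61917899686589,9.484223333071169
savannah_clutter_02_i3,savannah_clutter_02,savannah,clutter,-21.2892615085401,8.86895567150223
savannah_clutter_03_i1,savannah_clutter_03,savannah,clutter,-20.582219060360206,12.798680645438274
savannah_clutter_03_i2,savannah_clutter_03,savannah,clutter,-20.580513749497396,13.251000102345053
savannah_clutter_03_i3,savannah_clutter_03,savannah,clutter,-21.152792379762925,12.795385659203466
savannah_clutter_04_i1,savannah_clutter_04,savannah,clutter,-23.425633004395582,10.459372794926834
savannah_clutter_04_i2,savannah_clutter_04,savannah,clutter,-22.834405399431258,10.750915309825352
savannah_clutter_04_i3,savannah_clutter_04,savannah,clutter,-21.55188537942565,11.138158163206487
savannah_clutter_05_i1,savannah_clutter_05,savannah,clutter,-20.53369727521953,7.331356525911615
savannah_clutter_05_i2,savannah_clutter_05,savannah,clutter,-19.919284471795898,7.308087110909389
savannah_clutter_05_i3,savannah_clutter_05,savannah,clutter,-20.45296902090997,8.07521424143007
savannah_clutter_06_i1,savannah_clutter_06,savannah,clutter,-20.59624438491681,9.222876635736744
savannah_clutter_06_i2,savannah_clutter_06,savannah,clutter,-20.24020482700736,8.672936905289264
savannah_clutter_06_i3,savannah_clutter_06,savannah,clutter,-20.084350008550068,9.283532913192623
savannah_fruitbat_01_i1,savannah_fruitbat_01,savannah,fruitbat,-20.8130731127042,7.821877787434364
savannah_fruitbat_01_i2,savannah_fruitbat_01,savannah,fruitbat,-21.176694679160878,7.819082827196387
savannah_fruitbat_01_i3,savannah_fruitbat_01,savannah,fruitbat,-21.143034498698977,7.885482469259123
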