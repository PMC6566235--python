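product_id,process,sucrose,starch,fiber_sol,fiber_ins,fat,protein,gi_obs,gi_pred,gl_obs,gl_pred
P01,Extruded,11.8,61.2,2.4,7.1,2.2,9.1,83,79,18.2,17.2
P02,Extruded,10.9,71.0,0.7,2.0,2.1,6.9,83,82,20.4,20.2
P03,Extruded,6.3,68.0,1.9,5.8,3.3,8.3,83,82,18.5,18.3
P04,Flakes,14.9,56.8,2.8,8.3,2.2,10.3,82,71,17.6,15.3
P05,Extruded,16.8,57.5,2.2,6.7,2.1,8.5,80,77,17.8,17.3
P06,Flakes,11.8,64.2,1.7,5.1,1.4,9.3,79,74,18.0,16.9
P07,Flakes,28.6,53.7,0.8,2.3,2.5,6.3,79,72,19.5,17.8
P08,Extruded,4.1,74.7,0.7,2.0,1.4,12.3,78,82,18.4,19.3
P09,Extruded,28.8,52.0,1.1,3.3,2.7,6.3,78,72,18.9,17.4
P10,Extruded,4.0,62.6,3.2,9.7,2.1,12.3,75,78,15.0,15.6
P11,Extruded,25.2,48.8,2.2,6.5,4.0,7.8,75,70,16.7,15.5
P12,Extruded,30.0,46.9,1.5,4.4,4.8,6.2,73,70,16.8,16.1
P13,Flakes,11.4,69.8,1.0,2.9,2.1,7.1,73,76,17.8,18.5
P14,Bar,27.4,41.0,1.4,4.1,7.1,6.3,72,70,14.8,14.3
P15,Extruded,29.8,44.3,1.9,5.7,3.9,8.4,72,68,16.0,15.2
P16,Extruded,25.0,51.2,1.6,4.8,5.0,7.2,72,70,16.5,16.1
P17,Bar,27.9,40.6,1.5,4.5,7.3,6.2,71,70,14.6,14.3
P18,Flakes,17.2,60.0,1.6,4.7,1.2,8.6,71,73,16.4,17.0
P19,Bar,21.3,48.2,1.3,3.8,6.5,5.8,70,73,14.6,15.2
P20,Extruded,29.7,48.3,1.5,4.6,3.0,7.6,70,70,16.4,16.4
P21,Extruded,20.9,52.6,1.9,5.8,3.7,8.8,70,70,15.4,15.5
P22,Extruded,29.8,49.0,1.3,4.0,5.0,4.9,69,71,16.3,16.7
P23,Bar,22.5,42.7,1.4,4.3,9.8,6.3,68,69,13.3,13.6
P24,Extruded,28.7,47.0,1.4,4.1,7.4,7.6,68,68,15.4,15.4
P25,Extruded,28.8,47.0,1.6,4.7,4.5,8.0,68,69,15.5,15.7
P26,Flakes,28.4,47.7,2.2,6.6,1.7,8.7,68,70,15.5,15.9
P27,Extruded,24.8,48.6,1.3,3.9,10.1,5.7,67,68,14.8,15.0
P28,Bar,30.0,33.4,1.0,3.0,12.9,7.4,66,64,12.6,12.2
P29,Extruded,24.2,54.9,1.3,3.9,3.2,7.0,63,72,14.9,17.1
P30,Flakes,0.7,67.1,3.1,9.3,2.2,11.5,62,62,12.6,12.6
P31,Extruded,26.9,44.7,2.0,5.9,4.9,9.0,61,68,13.1,14.6
P32,Extruded,4.7,62.7,2.1,6.4,7.5,11.1,61,71,12.3,14.3
P33,Muesli,14.9,47.3,2.6,7.8,6.7,11.9,60,61,11.2,11.3
P34,Muesli,11.4,45.5,2.0,6.1,11.1,11.8,59,58,10.1,9.9
P35,Muesli,14.9,44.1,2.2,6.5,9.5,10.6,59,59,10.4,10.5
P36,Granola,22.3,38.9,1.4,4.2,13.7,14.4,59,53,10.8,9.8
P37,Granola,25.5,43.3,1.6,4.7,9.8,10.0,59,58,12.2,12.0
P38,Granola,22.3,41.6,1.9,5.8,10.5,11.6,55,54,10.5,10.4
P39,Granola,18.7,41.8,1.9,5.8,12.4,13.0,54,52,9.8,9.5
P40,Granola,18.5,41.7,1.9,5.7,12.8,13.1,52,52,9.4,9.4
P41,Granola,22.1,41.4,1.9,5.7,10.3,12.0,52,54,9.9,10.3
P42,Granola,22.2,42.3,1.8,5.4,9.8,13.5,50,56,9.7,10.8
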