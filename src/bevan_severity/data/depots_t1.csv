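depot_code,province,aspect,altitude_m,distance_class,forest_type
1a,DU,E,199,gt_3km,none
1b,DU,NE,129,gt_3km,none
1c,DU,NW,289,lt_3km,deciduous
2d,BO,S,1166,lt_3km,coniferous
2e,BO,NE,794,lt_3km,coniferous
2f,BO,NW,690,lt_3km,coniferous
2g,BO,S,1270,gt_3km,none
3h,ZO,SW,39,gt_3km,none
3i,ZO,S,19,lt_3km,deciduous
4j,BR,N,506,lt_3km,deciduous
4k,BR,SW,538,gt_3km,none
4l,BR,SW,785,gt_3km,none
5m,KS,SW,308,lt_3km,coniferous
5n,KS,SW,71,lt_3km,coniferous
5o,KS,NE,35,lt_3km,coniferous
6p,KR,W,431,gt_3km,none
6r,KR,W,657,gt_3km,none
6s,KR,F,603,lt_3km,coniferous
6t,KR,NE,604,lt_3km,coniferous
7u,SI,F,342,gt_3km,none
7v,SI,F,277,lt_3km,coniferous
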