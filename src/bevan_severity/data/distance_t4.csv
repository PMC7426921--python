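species,stratum,frequency,percent,density
Monochamus galloprovincialis,gt_3km,12,24.4,2.2
Monochamus galloprovincialis,lt_3km,37,75.6,6.9
Buprestis dalmatina,gt_3km,8,27.5,1.7
Buprestis dalmatina,lt_3km,21,72.5,7.5
Spondylis buprestoides,gt_3km,2,11.7,0.1
Spondylis buprestoides,lt_3km,15,88.3,3.7
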