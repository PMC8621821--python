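label,country,population,fortified_foods,intake_change_iu,serum_change_nmol_l
Khadgawat 2013 (600),India,children 10-14,milk,600,30
Khadgawat 2013 (1000),India,children 10-14,milk,1000,42
Black 2015,Ireland,adults 18-64,fat spreads + milk,24,2.4
Raulio 2017 (men 25-44),Finland,adults,milk products + fat spreads,264,13
Raulio 2017 (women 25-44),Finland,adults,milk products + fat spreads,200,10
Jaaskelainen 2017 (men),Finland,adults 30+,milk products + fat spreads,280,17
Jaaskelainen 2017 (women),Finland,adults 30+,milk products + fat spreads,200,17
Black 2012,NA,meta-analysis,NA,440,19.4
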