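label,rr,ci_low,ci_high,country,dose,n
Wactawski-Wende 2006,0.89,0.77,1.03,USA,400 IU/day,36282
Avenell 2012,0.85,0.68,1.06,UK,800 IU/day,5292
Trivedi 2003,0.86,0.61,1.20,UK,820 IU/day equivalent,2686
Manson 2018,0.83,0.67,1.02,USA,2000 IU/day,25871
Scragg 2018,0.99,0.60,1.64,New Zealand,bolus + 100000 IU/month,5110
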