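label,food,daily_dose_iu,population,duration,baseline_nmol_l,serum_change_nmol_l
Keane 1998,milk,200,older adults Ireland,12 months,24,15
McKenna 1995,milk,,students + hospital personnel Ireland,4 months,77,16
Khadgawat 2013 (600),milk,600,Indian school children,12 weeks,11.7,12.1
Khadgawat 2013 (1000),milk,1000,Indian school children,12 weeks,11.7,16.9
Jaaskelainen 2017 (men),milk products + fat spreads,,Finnish adults,11 years,47.6,17.6
Jaaskelainen 2017 (women),milk products + fat spreads,,Finnish adults,11 years,47.5,18.1
Kruger 2019,milk powder,600,premenopausal women Malaysia,12 months,48.6,12.2
Gasparri 2019,yoghurt,,meta-analysis n=665,8-16 weeks,,31.0
Nikooyeh 2016,bread,1000,healthy adults Iran,8 weeks,33.9,48.3
Itkonen 2016,bread,1040,young adult women Finland,8 weeks,64.6,7.0
Biancuzzo 2010 (D2),orange juice,1000,US adults,11 weeks,15.8,14.5
Biancuzzo 2010 (D3),orange juice,1000,US adults,11 weeks,17.9,12.3
Madsen 2013,milk + bread,376,Danish families,6 months,73,19
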