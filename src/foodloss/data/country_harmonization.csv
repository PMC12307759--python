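source_name,canonical_name,provenance
"Korea, Rep.",Republic of Korea,world_bank
"Korea, Dem. People's Rep.",Democratic People's Republic of Korea,world_bank
"Egypt, Arab Rep.",Egypt,world_bank
"Iran, Islamic Rep.",Iran,world_bank
"Venezuela, RB",Venezuela,world_bank
"Yemen, Rep.",Yemen,world_bank
"Gambia, The",Gambia,world_bank
"Bahamas, The",Bahamas,world_bank
"Micronesia, Fed. Sts.",Micronesia,world_bank
"Congo, Dem. Rep.",Democratic Republic of the Congo,world_bank
"Congo, Rep.",Congo,world_bank
"Hong Kong SAR, China",Hong Kong,world_bank
"Macao SAR, China",Macao,world_bank
Lao PDR,Lao People's Democratic Republic,world_bank
Slovak Republic,Slovakia,world_bank
Kyrgyz Republic,Kyrgyzstan,world_bank
Viet Nam,Vietnam,fao
Russian Federation,Russia,world_bank
Syrian Arab Republic,Syria,world_bank
Cote d'Ivoire,Côte d'Ivoire,world_bank
Turkiye,Türkiye,world_bank
United States of America,United States,fao
United Republic of Tanzania,Tanzania,fao
Bolivia (Plurinational State of),Bolivia,fao
Venezuela (Bolivarian Republic of),Venezuela,fao
Iran (Islamic Republic of),Iran,fao
Republic of Moldova,Moldova,fao
"China, mainland",China,fao
Czechia,Czech Republic,fao
Cabo Verde,Cape Verde,fao
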