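raw_label,group
wheat,grains
maize,grains
rice,grains
barley,grains
sorghum,grains
millet,grains
oats,grains
potatoes,roots and tubers
sweet potatoes,roots and tubers
cassava,roots and tubers
yams,roots and tubers
tomatoes,vegetables
onions,vegetables
cabbages,vegetables
carrots,vegetables
bananas,fruits
apples,fruits
oranges,fruits
mangoes,fruits
grapes,fruits
beans,pulses
lentils,pulses
chickpeas,pulses
cowpeas,pulses
poultry meat,meat products
bovine meat,meat products
pig meat,meat products
sheep meat,meat products
milk,dairy and eggs
eggs,dairy and eggs
cheese,dairy and eggs
soybeans,oilseeds
sunflower seed,oilseeds
groundnuts,oilseeds
rapeseed,oilseeds
sugar cane,sugar products
sugar beet,sugar products
refined sugar,sugar products
coffee,beverages
tea,beverages
cocoa beans,beverages
spices,others
honey,others
nuts,others
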