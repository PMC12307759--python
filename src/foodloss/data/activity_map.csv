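raw_label,group
harvesting,harvest and on-farm operations
on-farm handling,harvest and on-farm operations
farm drying,harvest and on-farm operations
threshing,harvest and on-farm operations
milling,processing
canning,processing
slaughtering,processing
food processing,processing
transport,transport and distribution
distribution,transport and distribution
trucking,transport and distribution
storage,storage
warehousing,storage
cold storage,storage
retail,marketing and retail
wholesale market,marketing and retail
market sales,marketing and retail
household consumption,consumption
food service,consumption
packaging,packaging
packing,packaging
unspecified,others
whole supply chain,others
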