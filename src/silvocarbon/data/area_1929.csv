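category,area_ha
Agroforestry,1382364
Fruit tree plantations,75054
Managed Forest,69636
Mixed Forest,623929
Grassland,582814
Unproductive area,550436
Non-irrigated arable land,976838
Uncultivated productive area,276183
Water body,162135.1
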