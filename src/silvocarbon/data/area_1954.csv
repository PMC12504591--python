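category,area_ha
Agroforestry,802780.42
Fruit tree plantations,87782.24
Managed Forest,33572.86
Mixed Forest,808314.25
Grassland,279926.59
Unproductive area,275609.51
Non-irrigated arable land,1767352.22
Uncultivated productive area,370223.96
Water body,162135.1
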