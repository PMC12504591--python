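category,area_ha
Agroforestry,47525.03
Fruit tree plantations,163959.79
Managed Forest,45137.78
Mixed Forest,1126240.94
Grassland,296374.59
Unproductive area,725406.93
Non-irrigated arable land,1730580.29
Uncultivated productive area,289524.22
Water body,164629.98
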