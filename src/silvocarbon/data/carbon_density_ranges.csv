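category,lower,upper,source
Agroforestry,50.37,101.57,MC simulation
Fruit tree plantations,38.3,86.59,ISPRA GHG Inventory 2024
Managed Forest,88.32,99.15,ISPRA GHG Inventory 2024
Mixed Forest,126.88,161.17,ISPRA GHG Inventory 2024
Grassland,61.75,89.81,ISPRA GHG Inventory 2024
Unproductive area,1,9,InVEST case study
Non-irrigated arable land,36.64,71.88,ISPRA GHG Inventory 2024
Uncultivated productive area,1,20,InVEST case study
Water body,0,0,fixed zero
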