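type,biofilm,size_nm,hydropathy,charge,t_c,pbcf
Latex carboxylate,Wetland,100,Hydrophilic,(-),< 24 h,~2
Gold,Estuary,65,Hydrophobic,(+),< 12 d,2.18
Gold polystyrene sulfonate,Estuary,50,Hydrophobic,-53 mV,~12 h,3.46
Citrate capped silver,Estuary,"30, 115",Hydrophobic,(-),~12 h,1.4 - 1.5
Citrate capped silver,Marine,100 - 700,Hydrophobic,-18 mV,< 24 h,2.05
PVP capped silver,Benthic,117,Hydrophilic,-17 mV,"> 10 min, < 4 d",4.6
Titanium dioxide,Algal,150,n.d.,-17 mV,< 28 d,4 - 5.6
Copper oxide,Periphyton,100 - 800,Hydrophilic,-35 - +15 mV,~50 min,3.6 - 4.25
Citrate capped silver,Aquabacterium citratiphilum,"30, 70",Hydrophobic,-60 mV,< 20 h,0.8
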