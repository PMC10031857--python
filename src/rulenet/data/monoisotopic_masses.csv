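element,mass
H,1.0078250319
C,12.0
N,14.0030740052
O,15.9949146221
F,18.9984031627
Na,22.9897692820
Mg,23.9850417000
Si,27.9769265327
P,30.9737615120
S,31.9720706912
Cl,34.9688527100
K,38.9637064864
Ca,39.9625909000
Mn,54.9380439000
Fe,55.9349363000
Co,58.9331943000
Ni,57.9353424000
Cu,62.9295977000
Zn,63.9291420000
As,74.9215945000
Se,79.9165218000
Br,78.9183376000
Mo,97.9054045000
I,126.9044719000
B,11.0093053600
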