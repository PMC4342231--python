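gene_id,offset_kb,label
Bradi4g25620,-2000,Up 2 Mb
Bradi4g26150,-1500,Up 1.5 Mb
Bradi4g26877,-1000,Up 1 Mb
Bradi4g27117,-700,Up 700 kb
Bradi4g27270,-500,Up 500 kb
Bradi4g27334,-400,Up 400 kb
Bradi4g27490,-200,Up 200 kb
Bradi4g27607,-100,Up 100 kb
Bradi4g27720,-50,Up 50 kb
Bradi4g27740,-10,Up adjacent
BdPFT1,0,anchor
Bradi4g27760,10,Down adjacent
Bradi4g27777,50,Down 50 kb
Bradi4g27810,100,Down 100 kb
Bradi4g27880,200,Down 200 kb
Bradi4g28040,400,Down 400 kb
Bradi4g28150,500,Down 500 kb
Bradi4g28310,700,Down 700 kb
Bradi4g28580,1000,Down 1 Mb
Bradi4g29060,1500,Down 1.5 Mb
Bradi4g29547,2000,Down 2 Mb
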