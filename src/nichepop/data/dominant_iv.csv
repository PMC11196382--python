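species,ZEFR1,ZEFR2,TNFP3,TNFP4
Salvia daiguii,10.00,14.76,3.42,8.75
Pilea notata,23.87,1.72,14.71,22.21
Strobilanthes pentstemonoides,16.66,1.67,29.51,25.07
Lycianthes lysimachioides,0.00,0.00,25.57,29.51
Pteris multifida,9.65,14.43,0.00,0.00
Selaginella moellendorffii,8.34,12.94,0.00,0.00
Carex thibetica,5.20,14.61,0.00,0.00
Houttuynia cordata,5.67,6.30,1.59,1.01
Isodon amethystoides,3.47,9.33,0.00,0.00
Impatiens piufanensis,0.00,0.00,3.65,7.29
Boehmeria nivea,5.71,1.31,0.92,0.00
Youngia japonica,0.00,0.00,3.38,4.21
Ficus tikoua,0.83,2.04,1.14,0.00
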