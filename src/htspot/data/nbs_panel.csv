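marker,cutoff,direction,alert_fraction
Val,290.000,up,0.10
Leu,245.000,up,0.10
Met,63.000,up,0.10
Phe,153.000,up,0.10
Tyr,190.000,up,0.10
Glu,560.000,up,0.10
Orn,250.000,up,0.10
Cit,65.000,up,0.10
Arg,100.000,up,0.10
Ala,900.000,up,0.10
Gly,1000.000,up,0.10
C0,6.250,down,0.10
C3,7.000,up,0.10
C4,1.690,up,0.10
C4-OH,0.550,up,0.10
C5,1.000,up,0.10
C5:1,0.450,up,0.10
C5-OH,1.040,up,0.10
C6DC,0.270,up,0.10
C6,0.470,up,0.10
C8,0.350,up,0.10
C10:2,0.500,up,0.10
C10:1,0.300,up,0.10
C10,0.420,up,0.10
C3DC,0.250,up,0.10
C5DC,0.300,up,0.10
C14:1,0.640,up,0.10
C14,0.810,up,0.10
C16:1,0.340,up,0.10
C16,9.280,up,0.10
C18:1,3.000,up,0.10
C16-OH,0.230,up,0.10
C18:1-OH,0.750,up,0.10
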