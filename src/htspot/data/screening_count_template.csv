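marker,n_definite_positive,n_alert_zone
Val,5,9
Leu,39,80
Met,63,54
Phe,1,1
Tyr,92,57
Glu,95,48
Orn,43,26
Cit,6,2
Arg,13,8
Ala,1,1
Gly,6,12
C0,38,38
C3,29,31
C4,1,1
C4-OH,27,40
C5,1,1
C5:1,3,3
C5-OH,6,1
C6DC,145,95
C6,9,10
C8,126,103
C10:2,5,5
C10:1,187,133
C10,41,36
C3DC,284,142
C5DC,156,155
C14:1,6,3
C14,12,20
C16:1,289,311
C16,1,4
C18:1,8,9
C16-OH,65,21
C18:1-OH,1,1
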