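# units: per_s
from,to,k0,k1
C1,C2,24000,0.06
C2,C1,400,-0.045
C2,C3,18000,0.06
C3,C2,800,-0.045
C3,C4,12000,0.06
C4,C3,1200,-0.045
C4,C5,6000,0.06
C5,C4,1600,-0.045
C5,O6,15000,0.03
O6,C5,1044.52,-0.03
O6,I12,1601.36,0.0
I12,O6,1.65195,0.0
O6,S13,400.8,-0.011
S13,O6,0.207,-0.031
I7,I8,8000,0.06
I8,I7,33.8186,-0.045
I8,I9,6000,0.06
I9,I8,67.6373,-0.045
I9,I10,4000,0.06
I10,I9,101.456,-0.045
I10,I11,2000,0.06
I11,I10,135.275,-0.045
I11,I12,4000,0.03
I12,I11,53.0338,-0.03
C1,I7,5,0.01
I7,C1,21.8904,-0.045
C2,I8,5,0.01
I8,C2,21.8904,-0.045
C3,I9,5,0.01
I9,C3,21.8904,-0.045
C4,I10,5,0.01
I10,C4,21.8904,-0.045
C5,I11,5,0.01
I11,C5,21.8904,-0.045
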