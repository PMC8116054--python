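specimen_id,taxon,G,H,B,U,R,F,Sub,A,T,Sac,estimated
A.L. 288-1,A. afarensis,21.6,28.9,41.1,16.1,15.1,28.6,20.8,37.0,18.0,25.3,
KSD-VP-1/1,A. afarensis,30.1,,58.8,,,,,49.0,,32.4,
DIK-1-1,A. afarensis,13.5,,,,,,,,13.1,,
StW 573,A. africanus,25.9,31.3,54.0,24.3,21.9,35.2,24.5,43.0,18.0,,
StW 431,A. africanus,,,59.0,25.7,21.9,,,45.0,,27.5,
MH1,A. sediba,,,57.0,18.9,,33.0,23.2,,,22.0,
MH2,A. sediba,24.6,30.1,52.4,17.4,18.8,32.7,,,18.1,23.6,
BOU-VP-12/1,A. garhi,,,,,21.4,,23.7,,,,
TM 1517,P. robustus,,,54.0,22.0,,,,,18.9,,
OH 80,P. boisei,,,,,26.3,,26.5,,,,
KNM-ER 1500,P. boisei,,,,21.4,20.2,,24.2,,19.2,,T
KNM-ER 1503/1504,P. boisei,,,57.0,,,30.6,22.2,,,,
KNM-ER 3735,H. habilis,,,55.0,,20.0,,,,,25.3,
KNM-WT 15000,H. erectus,27.6,31.6,55.0,19.0,,46.0,28.8,,25.0,33.6,T
LES 1,H. naledi,,33.2,,16.1,,36.0,24.2,,,24.5,
LB 1,H. floresiensis,,,,19.5,,31.0,22.1,36.0,19.5,,
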