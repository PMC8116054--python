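taxon,element,mean,sd,n
Homo sapiens,G,29.5,2.7,67
Homo sapiens,H,42.3,3.5,67
Homo sapiens,B,59.1,4.7,52
Homo sapiens,U,21.8,1.9,51
Homo sapiens,R,21.7,2.1,51
Homo sapiens,F,44.5,3.5,67
Homo sapiens,Sub,28.6,2.1,52
Homo sapiens,A,51.2,3.5,67
Homo sapiens,T,28.2,2.0,66
Homo sapiens,Sac,38.6,3.1,67
Pan,G,26.6,2.4,113
Pan,H,38.2,3.1,113
Pan,B,62.5,5.5,95
Pan,U,22.5,2.8,95
Pan,R,24.5,1.8,94
Pan,F,32.8,2.5,120
Pan,Sub,25.0,2.0,98
Pan,A,38.6,3.3,116
Pan,T,18.1,34.1,116
Pan,Sac,28.4,3.9,109
Gorilla,G,39.2,5.5,119
Gorilla,H,54.9,7.3,122
Gorilla,B,93.0,13.0,94
Gorilla,U,33.4,5.7,89
Gorilla,R,31.7,4.4,91
Gorilla,F,46.6,5.9,125
Gorilla,Sub,35.7,4.9,93
Gorilla,A,53.1,6.9,114
Gorilla,T,24.9,5.6,108
Gorilla,Sac,37.7,5.8,102
Pongo,G,29.2,3.6,47
Pongo,H,40.0,4.8,49
Pongo,B,63.9,7.1,45
Pongo,U,22.1,3.2,46
Pongo,R,22.8,2.8,46
Pongo,F,32.9,4.0,49
Pongo,Sub,20.8,2.6,45
Pongo,A,39.0,4.7,49
Pongo,T,18.0,2.7,46
Pongo,Sac,28.0,4.1,43
Hylobatidae,G,13.2,1.7,62
Hylobatidae,H,18.5,2.3,66
Hylobatidae,B,28.0,3.1,66
Hylobatidae,U,11.0,1.5,66
Hylobatidae,R,12.6,1.5,69
Hylobatidae,F,16.4,2.1,65
Hylobatidae,Sub,11.0,1.5,65
Hylobatidae,A,20.6,3.0,66
Hylobatidae,T,7.5,1.0,59
Hylobatidae,Sac,14.7,2.3,58
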