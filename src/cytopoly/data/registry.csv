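name,arm,segments,centromere_index,seq_class,parent,n_steps,kind,mapping_version,notes
p'borA1,A,,,main,,,,,main banding sequence of arm A
h'borA2,A,,,alternative,p'borA1,1,simple paracentric,,found hetero- and homozygous; Holarctic distribution
p'borA3,A,,,unique,p'borA1,1,simple paracentric,,
p'borA4,A,,,alternative,p'borA1,1,simple paracentric,,found hetero- and homozygous
p'borA5,A,,,rare,p'borA1,3,complex,,three inversion steps from p'borA1; predates the species (shared with sibling species); intermediates hypothetical
p'borA6,A,,,unique,p'borA1,1,simple paracentric,,
p'borA7,A,,,unique,p'borA1,1,simple pericentric,,pericentric inversion spanning arms A and B; inverted homologue of chromosome AB becomes submetacentric
p'borA8,A,,,rare,p'borA5,1,simple paracentric,,complex relative to p'borA1 but a simple inversion of p'borA5
p'borA9,A,,,rare,p'borA5,1,simple paracentric,,complex relative to p'borA1 but a simple inversion of p'borA5
p'borB1,B,,,main,,,,,main banding sequence of arm B
h'borB2,B,,,alternative,p'borB1,1,simple paracentric,,only arm-B inversion found hetero- and homozygous
p'borB3,B,,,unique,p'borB1,1,simple paracentric,,
p'borB4,B,,,unique,p'borB1,1,simple paracentric,,
p'borB5,B,,,unique,p'borB1,1,simple paracentric,,
p'borB6,B,,,unique,p'borB1,1,simple pericentric,,arm-B product of the pericentric inversion that also yields p'borA7
p'borB7,B,,,unique,p'borB1,1,simple paracentric,,
p'borC1,C,,,main,,,,,main banding sequence of arm C; arm largely monomorphic
p'borC2,C,,,unique,p'borC1,1,simple paracentric,,large simple inversion
p'borC3,C,,,unique,p'borC1,1,simple pericentric,,short pericentric inversion
p'borD1,D,,,main,,,,,main banding sequence of arm D
h'borD2,D,,,alternative,p'borD1,1,simple paracentric,,found hetero- and homozygous
p'borD3,D,,,unique,p'borD1,1,simple paracentric,,
p'borD4,D,,,unique,p'borD1,,translocation,,product of a reciprocal translocation between chromosomes CD and EF
p'borD5,D,,,unique,p'borD1,1,simple pericentric,,
h'borE1,E,,,main,,,,,main banding sequence of arm E; Holarctic; two mapping versions (KV/GV) in circulation
p'borE2,E,,,unique,h'borE1,1,simple paracentric,,
p'borE3,E,,,unique,h'borE1,1,simple paracentric,,
p'borE4,E,,,unique,h'borE1,1,simple paracentric,,
p'borE5,E,,,unique,h'borE1,1,simple paracentric,,
p'borE6,E,,,unique,h'borE1,1,simple paracentric,,
p'borE7,E,,,unique,h'borE1,,translocation,,arm-E product of the CD/EF reciprocal translocation
p'borF1,F,,,main,,,,,main banding sequence of arm F
p'borF2,F,,,alternative,p'borF1,1,simple paracentric,,found hetero- and homozygous
p'borF3,F,,,unique,p'borF1,1,simple paracentric,,
h'borF4,F,,,rare,p'borF1,1,simple paracentric,,low frequency in several populations
p'borF5,F,,,unique,p'borF1,2,complex,,combination of the two inversions separating p'borF2 and p'borF4 from p'borF1
p'borF6,F,,,unique,p'borF1,1,simple paracentric,,
p'borF7,F,,,unique,p'borF1,1,simple paracentric,,
p'borG1,G,,,main,,,,,main banding sequence of arm G
p'borG2,G,,,alternative,p'borG1,1,simple paracentric,,simple inversion spanning most of the arm; reaches fixation in some Western-Siberian populations
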