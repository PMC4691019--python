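genes	group	chromosome
Pbr029794,Pbr029797	1	scaffold503.0
Pbr029330,Pbr029332	1	scaffold491.0
Pbr019026,Pbr019030	2a	Chr8
Pbr020001,Pbr020000	2a	Chr15
Pbr029304,Pbr029307	2c	scaffold490.0
Pbr021938,Pbr021935,Pbr021930	2c	Chr8
Pbr006376,Pbr006380	2c	scaffold1326.0
Pbr032698,Pbr032702	2c	scaffold591.0
Pbr015073,Pbr032444	2d	Chr6
Pbr018132,Pbr018122	2d	Chr9
Pbr009294,Pbr009274	2d	Chr15
Pbr007956,Pbr007949	2e	Chr7
Pbr002913,Pbr002914	3	Chr7
Pbr001238,Pbr001243,Pbr001239,Pbr001240	3	Chr12
Pbr001424,Pbr001425	3	Chr12
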