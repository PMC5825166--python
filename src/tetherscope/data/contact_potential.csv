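,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
A,-0.5600,-0.7389,0.7944,0.7944,-0.8156,0.0022,0.7178,-1.2500,0.8967,-1.0711,-0.5856,0.7944,0.3089,0.7944,1.0500,0.1044,0.0789,-1.1733,0.1300,0.2322
C,-0.7389,-0.9722,1.0278,1.0278,-1.0722,-0.0056,0.9278,-1.6389,1.1611,-1.4056,-0.7722,1.0278,0.3944,1.0278,1.3611,0.1278,0.0944,-1.5389,0.1611,0.2944
D,0.7944,1.0278,-0.9722,-0.9722,1.1278,0.0611,-0.8722,1.6944,-1.1056,1.4611,0.8278,-0.9722,-0.3389,-0.9722,-1.3056,-0.0722,-0.0389,1.5944,-0.1056,-0.2389
E,0.7944,1.0278,-0.9722,-0.9722,1.1278,0.0611,-0.8722,1.6944,-1.1056,1.4611,0.8278,-0.9722,-0.3389,-0.9722,-1.3056,-0.0722,-0.0389,1.5944,-0.1056,-0.2389
F,-0.8156,-1.0722,1.1278,1.1278,-1.1822,-0.0089,1.0178,-1.8056,1.2744,-1.5489,-0.8522,1.1278,0.4311,1.1278,1.4944,0.1378,0.1011,-1.6956,0.1744,0.3211
G,0.0022,-0.0056,0.0611,0.0611,-0.0089,0.0267,0.0578,-0.0278,0.0656,-0.0200,0.0011,0.0611,0.0400,0.0611,0.0722,0.0311,0.0300,-0.0244,0.0322,0.0367
H,0.7178,0.9278,-0.8722,-0.8722,1.0178,0.0578,-0.7822,1.5278,-0.9922,1.3178,0.7478,-0.8722,-0.3022,-0.8722,-1.1722,-0.0622,-0.0322,1.4378,-0.0922,-0.2122
I,-1.2500,-1.6389,1.6944,1.6944,-1.8056,-0.0278,1.5278,-2.7500,1.9167,-2.3611,-1.3056,1.6944,0.6389,1.6944,2.2500,0.1944,0.1389,-2.5833,0.2500,0.4722
K,0.8967,1.1611,-1.1056,-1.1056,1.2744,0.0656,-0.9922,1.9167,-1.2567,1.6522,0.9344,-1.1056,-0.3878,-1.1056,-1.4833,-0.0856,-0.0478,1.8033,-0.1233,-0.2744
L,-1.0711,-1.4056,1.4611,1.4611,-1.5489,-0.0200,1.3178,-2.3611,1.6522,-2.0267,-1.1189,1.4611,0.5533,1.4611,1.9389,0.1711,0.1233,-2.2178,0.2189,0.4100
M,-0.5856,-0.7722,0.8278,0.8278,-0.8522,0.0011,0.7478,-1.3056,0.9344,-1.1189,-0.6122,0.8278,0.3211,0.8278,1.0944,0.1078,0.0811,-1.2256,0.1344,0.2411
N,0.7944,1.0278,-0.9722,-0.9722,1.1278,0.0611,-0.8722,1.6944,-1.1056,1.4611,0.8278,-0.9722,-0.3389,-0.9722,-1.3056,-0.0722,-0.0389,1.5944,-0.1056,-0.2389
P,0.3089,0.3944,-0.3389,-0.3389,0.4311,0.0400,-0.3022,0.6389,-0.3878,0.5533,0.3211,-0.3389,-0.1067,-0.3389,-0.4611,-0.0089,0.0033,0.6022,-0.0211,-0.0700
Q,0.7944,1.0278,-0.9722,-0.9722,1.1278,0.0611,-0.8722,1.6944,-1.1056,1.4611,0.8278,-0.9722,-0.3389,-0.9722,-1.3056,-0.0722,-0.0389,1.5944,-0.1056,-0.2389
R,1.0500,1.3611,-1.3056,-1.3056,1.4944,0.0722,-1.1722,2.2500,-1.4833,1.9389,1.0944,-1.3056,-0.4611,-1.3056,-1.7500,-0.1056,-0.0611,2.1167,-0.1500,-0.3278
S,0.1044,0.1278,-0.0722,-0.0722,0.1378,0.0311,-0.0622,0.1944,-0.0856,0.1711,0.1078,-0.0722,-0.0089,-0.0722,-0.1056,0.0178,0.0211,0.1844,0.0144,0.0011
T,0.0789,0.0944,-0.0389,-0.0389,0.1011,0.0300,-0.0322,0.1389,-0.0478,0.1233,0.0811,-0.0389,0.0033,-0.0389,-0.0611,0.0211,0.0233,0.1322,0.0189,0.0100
V,-1.1733,-1.5389,1.5944,1.5944,-1.6956,-0.0244,1.4378,-2.5833,1.8033,-2.2178,-1.2256,1.5944,0.6022,1.5944,2.1167,0.1844,0.1322,-2.4267,0.2367,0.4456
W,0.1300,0.1611,-0.1056,-0.1056,0.1744,0.0322,-0.0922,0.2500,-0.1233,0.2189,0.1344,-0.1056,-0.0211,-0.1056,-0.1500,0.0144,0.0189,0.2367,0.0100,-0.0078
Y,0.2322,0.2944,-0.2389,-0.2389,0.3211,0.0367,-0.2122,0.4722,-0.2744,0.4100,0.2411,-0.2389,-0.0700,-0.2389,-0.3278,0.0011,0.0100,0.4456,-0.0078,-0.0433
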