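level_ug_per_ml,replicate,signal,matrix
0.1,1,0.218092,solvent
0.1,2,0.218092,solvent
0.1,3,0.218092,solvent
1.0,1,1.1794,solvent
1.0,2,1.1794,solvent
1.0,3,1.1794,solvent
3.0,1,3.253,solvent
3.0,2,3.253,solvent
3.0,3,3.253,solvent
6.0,1,6.2014,solvent
6.0,2,6.2014,solvent
6.0,3,6.2014,solvent
10.0,1,9.8302,solvent
10.0,2,9.8302,solvent
10.0,3,9.8302,solvent
15.0,1,13.8802,solvent
15.0,2,13.8802,solvent
15.0,3,13.8802,solvent
0.1,1,0.224572,sample
0.1,2,0.224572,sample
0.1,3,0.224572,sample
1.0,1,1.2442,sample
1.0,2,1.2442,sample
1.0,3,1.2442,sample
3.0,1,3.4474,sample
3.0,2,3.4474,sample
3.0,3,3.4474,sample
6.0,1,6.5902,sample
6.0,2,6.5902,sample
6.0,3,6.5902,sample
10.0,1,10.4782,sample
10.0,2,10.4782,sample
10.0,3,10.4782,sample
15.0,1,14.8522,sample
15.0,2,14.8522,sample
15.0,3,14.8522,sample
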