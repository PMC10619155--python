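roi_index,roi_label,roi_abbrev,network,braak_stage,cortical
1,Hippocampus,HIPP,Subcortical,2,0
2,Entorhinal,ENT,Limbic,1,1
3,Amygdala,AMYG,Subcortical,3,0
4,Thalamus Proper,THALP,Subcortical,,0
5,Caudate,CAUD,Subcortical,,0
6,Putamen,PUT,Subcortical,,0
7,Pallidum,PAL,Subcortical,,0
8,Accumbens Area,ACUM,Subcortical,,0
9,Caudal Anterior Cingulate,CAC,Salience/VentralAttention,4,1
10,Caudal Middle Frontal,CMF,Control,5,1
11,Cuneus,CUN,Visual,6,1
12,Fusiform,FUS,Visual,3,1
13,Inferior Parietal,INFP,DefaultMode,5,1
14,Inferior Temporal,IT,Limbic,4,1
15,Isthmus Cingulate,ISTC,DefaultMode,4,1
16,Lateral Occipital,LOCC,Visual,5,1
17,Lateral Orbitofrontal,LORB,Limbic,5,1
18,Lingual,LIN,Visual,3,1
19,Medial Orbitofrontal,MORB,Limbic,5,1
20,Middle Temporal,MT,DefaultMode,4,1
21,Parahippocampal,PARH,DefaultMode,3,1
22,Paracentral,PARC,Somatomotor,6,1
23,Pars Opercularis,POPE,Salience/VentralAttention,5,1
24,Pars Orbitalis,PORB,DefaultMode,5,1
25,Pars Triangularis,PTRI,DefaultMode,5,1
26,Pericalcarine,PCAL,Visual,6,1
27,Postcentral,PSTS,Somatomotor,6,1
28,Posterior Cingulate,PC,DefaultMode,4,1
29,Precentral,PREC,Somatomotor,6,1
30,Precuneus,PCUN,DefaultMode,5,1
31,Rostral Anterior Cingulate,RAC,DefaultMode,4,1
32,Rostral Middle Frontal,RMF,Control,5,1
33,Superior Frontal,SF,DefaultMode,5,1
34,Superior Parietal,SP,DorsalAttention,5,1
35,Superior Temporal,ST,Somatomotor,5,1
36,Supramarginal,SMAR,Salience/VentralAttention,5,1
37,Transverse Temporal,TT,Somatomotor,3,1
38,Insula,INS,Salience/VentralAttention,4,1
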