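ligand	receptor	ppi_prob
G00000	G00050	0.799
G00001	G00051	0.526
G00002	G00052	0.583
G00003	G00053	0.872
G00004	G00054	0.988
G00005	G00055	0.484
G00006	G00056	0.446
G00007	G00057	0.507
G00008	G00058	0.612
G00009	G00059	0.5
G00010	G00060	0.747
G00011	G00061	0.764
G00012	G00062	0.462
G00013	G00063	0.734
G00014	G00064	0.403
G00015	G00065	0.674
G00016	G00066	0.976
G00017	G00067	0.872
G00018	G00068	0.752
G00019	G00069	0.592
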