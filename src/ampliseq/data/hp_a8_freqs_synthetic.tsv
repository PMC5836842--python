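sample	freq_a8
HP001	0.16
HP002	0.18
HP003	0.21
HP004	0.42
HP005	0.00
HP006	0.00
HP007	0.00
HP008	0.00
HP009	0.00
HP010	0.00
HP011	0.00
HP012	0.00
HP013	0.00
HP014	0.00
HP015	0.00
HP016	0.00
HP017	0.00
HP018	0.00
HP019	0.00
HP020	0.00
HP021	0.00
HP022	0.00
HP023	0.00
HP024	0.00
HP025	0.00
HP026	0.00
HP027	0.00
HP028	0.00
HP029	0.00
HP030	0.01
HP031	0.01
HP032	0.01
HP033	0.01
HP034	0.01
HP035	0.01
HP036	0.01
HP037	0.01
HP038	0.02
HP039	0.02
HP040	0.02
HP041	0.02
HP042	0.02
HP043	0.03
HP044	0.03
HP045	0.03
HP046	0.03
HP047	0.03
HP048	0.03
HP049	0.03
HP050	0.03
HP051	0.04
HP052	0.04
HP053	0.04
HP054	0.04
HP055	0.04
HP056	0.04
HP057	0.04
HP058	0.04
HP059	0.04
HP060	0.04
HP061	0.04
HP062	0.04
HP063	0.04
HP064	0.04
HP065	0.04
HP066	0.04
HP067	0.04
HP068	0.04
HP069	0.05
HP070	0.05
HP071	0.05
HP072	0.05
HP073	0.05
HP074	0.05
HP075	0.05
HP076	0.05
HP077	0.05
HP078	0.06
HP079	0.06
HP080	0.06
HP081	0.06
HP082	0.07
HP083	0.07
HP084	0.08
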