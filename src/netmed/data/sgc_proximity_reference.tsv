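# Published interactome-proximity z-scores and one-sided p-values from the
# sGC subunits (GUCY1A3/GUCY1B3/GUCY1A2, jointly and per subunit) to disease
# gene sets.  z is printed to 3 decimals and p to 5 decimals; stable_5dp
# marks rows where Phi(printed z) rounds exactly to the printed p.
query	disease	z	p	stable_5dp
All	Vision disorders	-3.405	0.00033	1
All	Varicose veins	-3.135	0.00086	1
All	Esophageal disease	-3.001	0.00134	0
All	Spinocerebellar ataxias	-2.995	0.00137	1
All	Asthma	-2.787	0.00266	1
All	Head and neck neoplasms	-2.725	0.00321	0
All	Stroke	-2.698	0.00348	0
All	Retinitis pigmentosa	-2.279	0.01132	0
All	Diabetes mellitus type 2	-2.122	0.01691	0
alpha-1	Vision disorders	-3.711	0.00010	1
alpha-1	Varicose veins	-3.239	0.00060	1
alpha-1	Esophageal disease	-2.959	0.00154	1
alpha-1	Spinocerebellar ataxias	-2.741	0.00307	0
alpha-1	Head and neck neoplasms	-2.529	0.00572	1
alpha-1	Asthma	-2.494	0.00631	0
alpha-1	Stroke	-2.288	0.01106	0
alpha-1	Retinitis pigmentosa	-1.923	0.02727	0
alpha-2	Vision disorders	-2.383	0.00859	1
alpha-2	Spinocerebellar ataxias	-2.356	0.00923	0
alpha-2	Stroke	-2.289	0.01105	0
alpha-2	Varicose veins	-2.240	0.01255	1
alpha-2	Esophageal disease	-2.238	0.01263	0
alpha-2	Asthma	-2.217	0.01330	0
alpha-2	Head and neck neoplasms	-2.127	0.01672	0
alpha-2	Retinitis pigmentosa	-2.108	0.01751	0
alpha-2	X-linked mental retardation	-2.080	0.01874	0
beta-1	Vision disorders	-2.387	0.00848	0
beta-1	Stroke	-2.339	0.00966	0
beta-1	Asthma	-2.291	0.01097	0
beta-1	Varicose veins	-2.270	0.01162	0
beta-1	Spinocerebellar ataxias	-2.266	0.01172	0
beta-1	Head and neck neoplasms	-2.225	0.01302	0
beta-1	Esophageal disease	-2.199	0.01394	1
beta-1	Retinitis pigmentosa	-2.041	0.02062	0
beta-1	Diabetes mellitus type 2	-1.931	0.02671	0
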