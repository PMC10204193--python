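gene	direction
G0UP001	up
G0UP002	up
G0UP003	up
G0UP004	up
G0UP005	up
G0UP006	up
G0UP007	up
G0UP008	up
G0UP009	up
G0UP010	up
G0UP011	up
G0UP012	up
G0UP013	up
G0UP014	up
G0UP015	up
G0UP016	up
G0UP017	up
G0UP018	up
G0UP019	up
G0UP020	up
G0UP021	up
G0UP022	up
G0UP023	up
G0UP024	up
G0UP025	up
G0UP026	up
G0UP027	up
G0UP028	up
G0UP029	up
G0UP030	up
G0UP031	up
G0UP032	up
G0UP033	up
G0UP034	up
G0UP035	up
G0UP036	up
G0UP037	up
G0UP038	up
G0UP039	up
G0UP040	up
G0UP041	up
G0UP042	up
G0UP043	up
G0UP044	up
G0UP045	up
G0UP046	up
G0UP047	up
G0UP048	up
G0UP049	up
G0UP050	up
G0UP051	up
G0UP052	up
G0UP053	up
G0UP054	up
G0UP055	up
G0UP056	up
G0UP057	up
G0UP058	up
G0UP059	up
G0UP060	up
G0UP061	up
G0UP062	up
G0UP063	up
G0UP064	up
G0UP065	up
G0UP066	up
G0UP067	up
G0UP068	up
G0UP069	up
G0UP070	up
G0DN001	down
G0DN002	down
G0DN003	down
G0DN004	down
G0DN005	down
G0DN006	down
G0DN007	down
G0DN008	down
G0DN009	down
G0DN010	down
G0DN011	down
G0DN012	down
G0DN013	down
G0DN014	down
G0DN015	down
G0DN016	down
G0DN017	down
G0DN018	down
G0DN019	down
G0DN020	down
G0DN021	down
G0DN022	down
G0DN023	down
G0DN024	down
G0DN025	down
G0DN026	down
G0DN027	down
G0DN028	down
G0DN029	down
G0DN030	down
G0DN031	down
G0DN032	down
G0DN033	down
G0DN034	down
G0DN035	down
G0DN036	down
G0DN037	down
G0DN038	down
G0DN039	down
G0DN040	down
G0DN041	down
G0DN042	down
G0DN043	down
G0DN044	down
G0DN045	down
G0DN046	down
G0DN047	down
G0DN048	down
G0DN049	down
G0DN050	down
G0DN051	down
G0DN052	down
G0DN053	down
G0DN054	down
G0DN055	down
G0DN056	down
G0DN057	down
G0DN058	down
G0DN059	down
G0DN060	down
G0DN061	down
G0DN062	down
G0DN063	down
G0DN064	down
G0DN065	down
G0DN066	down
G0DN067	down
G0DN068	down
G0DN069	down
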