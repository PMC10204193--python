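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
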