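gene
HK001
HK002
HK003
HK004
HK005
HK006
HK007
HK008
HK009
HK010
HK011
HK012
HK013
HK014
HK015
HK016
HK017
HK018
HK019
HK020
HK021
HK022
HK023
HK024
HK025
HK026
HK027
HK028
HK029
HK030
HK031
HK032
HK033
HK034
HK035
HK036
HK037
HK038
HK039
HK040
HK041
HK042
HK043
HK044
HK045
HK046
HK047
HK048
HK049
HK050
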