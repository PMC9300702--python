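CD63
CDH5
ENDOONLY000
ENDOONLY001
ENDOONLY002
ENDOONLY003
ENDOONLY004
ENDOONLY005
ENDOONLY006
ENDOONLY007
ENDOONLY008
ENDOONLY009
ENDOONLY010
ENDOONLY011
ENDOONLY012
ENDOONLY013
ENDOONLY014
ENDOONLY015
ENDOONLY016
ENDOONLY017
ENDOONLY018
ENDOONLY019
ENDOONLY020
ENDOONLY021
ENDOONLY022
ENDOONLY023
ENDOONLY024
ENDOONLY025
ENDOONLY026
ENDOONLY027
ENDOONLY028
ENDOONLY029
ENDOONLY030
ENDOONLY031
ENDOONLY032
ENDOONLY033
ENDOONLY034
ENDOONLY035
ENDOONLY036
ENDOONLY037
ENDOONLY038
ENDOONLY039
ENDOONLY040
ENDOONLY041
ENDOONLY042
ENDOONLY043
ENDOONLY044
ENDOONLY045
ENDOONLY046
ENDOONLY047
ENDOONLY048
ENDOONLY049
GARS1
HARS1
ITGA2
ITGA5
ITGAV
MCAM
PECAM1
RTN4
SHARED000
SHARED001
SHARED002
SHARED003
SHARED004
SHARED005
SHARED006
SHARED007
SHARED008
SHARED009
SHARED010
SHARED011
SHARED012
SHARED013
SHARED014
SHARED015
SHARED016
SHARED017
SHARED018
SHARED019
SHARED020
SHARED021
SHARED022
SHARED023
SHARED024
WARS1
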