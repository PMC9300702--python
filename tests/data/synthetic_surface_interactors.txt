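CD63
CDH5
ECE1
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
SURFONLY000
SURFONLY001
SURFONLY002
SURFONLY003
SURFONLY004
SURFONLY005
SURFONLY006
SURFONLY007
SURFONLY008
SURFONLY009
SURFONLY010
SURFONLY011
SURFONLY012
SURFONLY013
SURFONLY014
SURFONLY015
SURFONLY016
SURFONLY017
SURFONLY018
SURFONLY019
SURFONLY020
SURFONLY021
SURFONLY022
SURFONLY023
SURFONLY024
SURFONLY025
SURFONLY026
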