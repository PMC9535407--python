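synonym,canonicalLabel,traitIRI,kind
body mass,body mass,OBA:VT0001259,mass
weight,body mass,OBA:VT0001259,mass
body weight,body mass,OBA:VT0001259,mass
body length with tail,body length with tail,FOVT:0000001,length
total length,body length with tail,FOVT:0000001,length
ear length to notch,ear length to notch,FOVT:0000005,length
ear length,ear length to notch,FOVT:0000005,length
external ear length,ear length to notch,FOVT:0000005,length
tail length,tail length,OBA:VT0002758,length
pes length,pes length,OBA:1000048,length
hindfoot length,pes length,OBA:1000048,length
forearm length,forearm length,OBA:VT0010023,length
astragalus lateral length,astragalus lateral length,FOVT:0000013,length
astragalus GLl,astragalus lateral length,FOVT:0000013,length
talus lateral length,astragalus lateral length,FOVT:0000013,length
GLl,astragalus lateral length,FOVT:0000013,length
astragalus breadth,astragalus breadth,FOVT:0000021,length
astragalus width,astragalus breadth,FOVT:0000021,length
talus breadth,astragalus breadth,FOVT:0000021,length
calcaneus length,calcaneus length,FOVT:0000022,length
calcaneus greatest length,calcaneus length,FOVT:0000022,length
calcaneus maximal length,calcaneus length,FOVT:0000022,length
calcaneus width,calcaneus width,FOVT:0001079,length
humerus length,humerus length,OBA:VT0004350,length
tooth row length,tooth row length,FOVT:0000030,length
toothrow length,tooth row length,FOVT:0000030,length
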