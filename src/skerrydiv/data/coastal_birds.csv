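species,occurrences,classification,redlist
Arctic Jaeger,293,specialist,none
Arctic Tern,1156,specialist,none
Barnacle Goose,121,specialist,none
Black Guillemot,218,specialist,NT
Black-headed Gull,272,generalist,none
Black-throated Diver,14,generalist,none
Canada Goose,631,generalist,none
Caspian Tern,57,specialist,VU
Common Eider,3163,specialist,NT
Common Goldeneye,1596,generalist,none
Common Gull,2453,generalist,none
Common Murre,14,specialist,none
Common Pochard,56,generalist,NT
Common Redshank,491,generalist,none
Common Ringed Plover,132,specialist,none
Common Sandpiper,1091,generalist,NT
Common Shelduck,92,specialist,none
Common Teal,88,generalist,none
Common Tern,464,generalist,none
Eurasian Coot,405,generalist,none
Eurasian Curlew,22,generalist,VU
Eurasian Oystercatcher,1322,specialist,none
Eurasian Wigeon,13,generalist,none
Gadwall,100,generalist,none
Garganey,9,generalist,VU
Goosander,2642,generalist,none
Great Black-backed Gull,1290,specialist,none
Great Cormorant,38,specialist,none
Great Crested Grebe,938,generalist,none
Greater Scaup,2,specialist,VU
Grey Heron,35,generalist,none
Greylag Goose,933,generalist,none
Herring Gull,721,generalist,NT
Horned Grebe,25,generalist,NT
Lesser Black-backed Gull,342,specialist,NT
Little Ringed Plover,2,generalist,none
Mallard,2085,generalist,none
Mute Swan,1964,generalist,none
Northern Lapwing,79,generalist,none
Northern Pintail,9,generalist,NT
Northern Shoveler,90,generalist,none
Razorbill,96,specialist,none
Red-breasted Merganser,741,specialist,none
Red-necked Grebe,2,generalist,none
Rock Pipit,128,specialist,none
Ruddy Turnstone,313,specialist,VU
Tufted Duck,978,generalist,none
Velvet Scoter,336,specialist,NT
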