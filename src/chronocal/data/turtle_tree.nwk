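((((Pelusios:60.375000,Pelomedusa:60.375000)Pelomedusidae:55.075000,Podocnemis:115.450000)Pelomedusoides:22.650000,((Chelodina:56.625000,Elseya:56.625000)Chelodininae:45.025000,(Chelus:57.525000,Phrynops:57.525000)Chelus_Phrynops:44.125000)Chelidae:36.450000)Pleurodira:65.400000,(((Apalone:80.175000,Pelodiscus:80.175000)Trionychidae:62.875000,Carettochelys:143.050000)Trionychia:19.050000,(((Chelonia:71.462500,Dermochelys:71.462500)Chelonioidea:23.062500,(((Kinosternon:64.465625,Sternotherus:64.465625)Kinosternidae:11.665625,Dermatemys:76.131250)Kinosternoidea:6.131250,Chelydra:82.262500)Chelydroidea:12.262500)Americhelydia:24.525000,(((Heosemys:35.550000,Mauremys:35.550000)Heosemys_Mauremys:31.937500,Testudo:67.487500)Testuguria:17.187500,(((Graptemys:18.500000,Trachemys:18.500000)Graptemys_Trachemys:26.668750,Chrysemys:45.168750)Emydidae:13.168750,Platysternon:58.337500)Emydidae_Platysternon:26.337500)Testudinoidea:34.375000)Durocryptodira:43.050000)Cryptodira:41.400000)Testudines;
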