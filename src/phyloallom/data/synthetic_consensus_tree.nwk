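[SYNTHETIC stand-in chronogram for the 34-species primate sample. Hand-built once from widely accepted approximate divergence dates (branch lengths in millions of years; root age 73 my). It is NOT the 10kTrees consensus tree, which users must download themselves; tree-dependent results computed on this stand-in are approximate reproductions only.]
(((Galagoides_demidoff:40.0,Loris_tardigradus:40.0):23,(Daubentonia_madagascariensis:58.0,((Varecia_variegata:28.0,(Lemur_catta:18.0,Eulemur_mongoz:18.0):10):10,(Lepilemur_ruficaudatus:34.0,(Microcebus_murinus:27.0,Mirza_coquereli:27.0):7):4):20):5):10,(((Lagothrix_lagotricha:12.0,Ateles_paniscus:12.0):13,(Aotus_trivirgatus:23.0,((Saguinus_oedipus:15.0,Callithrix_penicillata:15.0):6,(Saimiri_sciureus:17.0,(Cebus_apella:6.0,Cebus_capucinus:6.0):11):4):2):2):18,((Hylobates_lar:20.0,(Pongo_pygmaeus:16.0,((Gorilla_gorilla_gorilla:1.5,Gorilla_beringei:1.5):7.5,(Homo_sapiens:6.6,(Pan_troglodytes:2.2,Pan_paniscus:2.2):4.4):2.4):7):4):10,((Colobus_polykomos:13.0,(Trachypithecus_germaini:9.0,Semnopithecus_entellus:9.0):4):5,((Chlorocebus_sabaeus:9.0,Cercopithecus_cephus:9.0):5,((Macaca_mulatta:3.5,Macaca_fascicularis:3.5):6.5,(Cercocebus_atys:9.0,(Papio_hamadryas:8.0,Lophocebus_albigena:8.0):1):1):4):4):12):13):30);
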