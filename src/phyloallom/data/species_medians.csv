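# Species-median neuroanatomical volumes for the 34-primate comparative sample.
# Literal constants transcribed from the published species table; never regenerated at runtime.
# Volumes in mm^3; *_mad columns are raw median absolute deviations (printed only for species with
# n >= 4 specimens, plus the two n = 2 species); ratio_* columns are the printed percentages.
# For multi-specimen species the printed ratio is the median of per-specimen ratios (with its MAD),
# not the ratio of medians, so those cells are not recomputable from this table (verified = 0).
# ratio cells marked verified = 1 recompute exactly from the printed medians at 2 decimals
# (half-away-from-zero); cells marked 0 were evidently computed from unrounded volumes.
# The white-faced sapajou cerebral volume is RECONSTRUCTED from its printed ratio (source-table
# extraction defect); its ratio cell is excluded from the verified list.
# Rhesus and crab-eating macaque medians follow exclusion of one outlier specimen each
# (cerebellar and cerebral volumes), as noted in the source table.
species,taxon,n_specimens,cerebellum,cerebrum,ansiform,cerebellum_mad,cerebrum_mad,ansiform_mad,ratio_cbl_cbr,ratio_cbl_cbr_mad,ratio_ans_cbl,ratio_ans_cbl_mad,cbl_cbr_verified,ans_cbl_verified,note
Demidoff's galago,Galagoides_demidoff,1,320,1925,,,,,16.65,,,,0,,
Red slender loris,Loris_tardigradus,1,447,3071,,,,,14.54,,,,0,,
Aye-aye,Daubentonia_madagascariensis,1,3032,17151,374,,,,17.68,,12.33,,1,0,
Black-and-white ruffed lemur,Varecia_variegata,1,3377,16032,,,,,21.06,,,,1,,
Ring-tailed lemur,Lemur_catta,1,2035,12658,,,,,16.08,,,,1,,
Mongoose lemur,Eulemur_mongoz,1,3224,14495,,,,,22.24,,,,1,,
Red-tailed sportive lemur,Lepilemur_ruficaudatus,1,882,4087,,,,,21.59,,,,0,,
Coquerel's mouse lemur,Mirza_coquereli,1,884,3885,,,,,22.75,,,,1,,
Gray mouse lemur,Microcebus_murinus,1,170,809,,,,,20.99,,,,0,,
Squirrel monkey,Saimiri_sciureus,2,920,8540,103,55,1263,,10.93,2.26,11.20,,0,1,ratio_cbl_cbr is specimen-level median
Tufted capuchin,Cebus_apella,1,5191,36285,1012,,,,14.31,,19.50,,1,1,
White-faced sapajou,Cebus_capucinus,1,4274,40058,,,,,10.67,,,,0,,cerebrum reconstructed from printed ratio
Cotton-top tamarin,Saguinus_oedipus,1,750,6254,,,,,11.99,,,,1,,
Black-pencilled marmoset,Callithrix_penicillata,1,485,3938,,,,,12.31,,,,0,,
Douroucouli,Aotus_trivirgatus,1,1627,11746,217,,,,13.85,,13.31,,1,0,
Wooly monkey,Lagothrix_lagotricha,1,5595,49385,874,,,,11.33,,15.62,,1,1,
Black spider monkey,Ateles_paniscus,2,8903,77381,,1411,10948,,11.49,0.20,,,0,,ratio is specimen-level median
Orangutan,Pongo_pygmaeus,1,25757,184458,6081,,,,13.96,,23.61,,1,1,
Chimpanzee,Pan_troglodytes,9,57047,284482,15544,6915,26063,1932,18.36,3.56,27.25,3.69,0,0,ratios are specimen-level medians
Bonobo,Pan_paniscus,1,48408,243036,6627,,,,19.92,,13.69,,1,1,
Human,Homo_sapiens,10,142171,1005711,43726,18710,179368,5003,14.26,1.75,30.76,1.91,0,0,ratios are specimen-level medians
Western lowland gorilla,Gorilla_gorilla_gorilla,1,58402,237690,13107,,,,24.57,,22.44,,1,1,
Eastern gorilla,Gorilla_beringei,1,46163,272908,,,,,16.92,,,,1,,
Gibbon,Hylobates_lar,1,8681,60685,,,,,14.31,,,,0,,
Indochinese lutung,Trachypithecus_germaini,1,3756,37988,,,,,9.89,,,,1,,
Hanuman langur,Semnopithecus_entellus,1,6749,49916,,,,,13.52,,,,1,,
King colobus,Colobus_polykomos,1,5787,40468,842,,,,14.30,,14.55,,1,1,
Rhesus macaque,Macaca_mulatta,6,10456,75928,,500,4689,,13.54,0.64,,,0,,medians after excluding one outlier specimen
Crab-eating macaque,Macaca_fascicularis,8,6184,46286,,955,9597,,12.89,0.98,,,0,,medians after excluding one outlier specimen
Hamadryas baboon,Papio_hamadryas,1,9478,89861,1841,,,,10.55,,19.42,,1,1,
Gray-cheeked mangabey,Lophocebus_albigena,1,6320,49185,,,,,12.85,,,,1,,
Sooty mangabey,Cercocebus_atys,1,5362,51689,,,,,10.37,,,,1,,
Green monkey,Chlorocebus_sabaeus,1,4169,53627,505,,,,7.77,,12.11,,1,1,
Moustached guenon,Cercopithecus_cephus,1,3697,41538,,,,,8.90,,,,1,,
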