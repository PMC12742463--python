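species,common_name,overlapping_mesohabitat,diet_similarities,diel_activity,fecundity_egg_size,age_at_maturity,larval_dispersal,adult_size
weight,,1,1,1,2,1,2,2
galaxias_macronasus,Bignose galaxiid,2,2,2,3,2,3,3
galaxias_pullus,Dusky galaxiid,2,2,2,3,3,3,2
galaxias_cobinitis,Lowland longjaw galaxiid,2,2,2,3,1,3,3
galaxias_prognathus,Upland longjaw galaxiid,2,2,2,3,1,3,3
galaxias_eldoni,Eldon's galaxiid,2,2,2,3,2,3,2
neochanna_burrowsius,Canterbury mudfish,2,2,1,3,2,3,2
neochanna_apoda,Brown mudfish,2,2,1,3,2,3,2
neochanna_diversus,Black mudfish,2,2,1,3,2,3,2
neochanna_heleosis,Northland mudfish,2,2,1,3,2,3,2
neochanna_rekohua,Chatham Island mudfish,2,2,1,3,2,3,2
galaxias_depressiceps,Taieri Flathead galaxiid,2,2,2,2,2,3,2
galaxias_divergens,Dwarf galaxiid,2,2,2,1,2,3,3
galaxias_gollumoides,Gollum galaxiid,2,2,2,1,1,3,3
gobiomorphus_alpinus,Tarndale bully,2,2,2,1,1,3,3
gobiomorphus_breviceps,Upland bully,2,2,2,3,1,2,2
galaxias_vulgaris,Canterbury galaxiid,2,2,2,1,2,2,3
galaxias_paucispondylus,Alpine galaxiid,2,2,2,1,2,3,2
galaxias_anomalus,Roundhead galaxiid,2,2,1,1,2,3,2
galaxias_brevipinnis,Koaro,3,3,2,1,2,1,2
galaxias_argenteus,Giant kokopu,3,3,3,1,3,1,1
galaxias_postvectis,Shortjaw kokopu,3,3,2,1,3,1,1
gobiomorphus_hubbsi,Bluegill bully,2,2,2,1,1,1,3
galaxias_fasciatus,Banded kokopu,3,3,2,1,3,1,1
gobiomorphus_basalis,Cran's bully,2,2,2,1,1,2,2
retropinna_retropinna,Common smelt,3,2,3,1,1,1,2
galaxias_maculatus,Inanga,3,2,2,1,1,1,2
cheimarrichthys_fosteri,Torrentfish,2,2,2,1,2,1,2
stokellia_anisodon,Stokell's smelt,3,1,3,1,1,1,2
gobiomorphus_huttoni,Redfin bully,2,2,2,1,2,1,2
anguilla_dieffenbachii,Longfin eel,2,3,1,1,3,1,1
anguilla_australis,Shortfin eel,2,3,1,1,3,1,1
gobiomorphus_cotidianus,Common bully,2,2,2,1,1,1,2
gobiomorphus_gobiodes,Giant bully,2,2,2,1,2,1,1
rhombosolea_retiarii,Black flounder,1,3,2,1,2,1,1
geotria_australis,Pouched lamprey,1,1,1,1,3,1,1
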