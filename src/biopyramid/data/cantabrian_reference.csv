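species,common_name,order,trophic_group,abundance,density_ind_km2,biomass_tonnes,biomass_kg_km2
Vulpes_vulpes,red fox,Carnivora,secondary_consumer,8240,7.32,49.44,43.95
Canis_lupus,wolf,Carnivora,secondary_consumer,115,0.10,3.44,3.06
Felis_silvestris,European wildcat,Carnivora,secondary_consumer,313,0.28,1.33,1.18
Martes_martes,pine marten,Carnivora,secondary_consumer,636,0.57,0.83,0.73
Meles_meles,Eurasian badger,Carnivora,omnivore,1780,1.58,21.36,18.98
Ursus_arctos,brown bear,Carnivora,omnivore,13,0.01,1.24,1.10
Cervus_elaphus,red deer,Artiodactyla,primary_consumer,9113,8.10,656.11,583.21
Capreolus_capreolus,roe deer,Artiodactyla,primary_consumer,19140,17.01,468.92,416.82
Sus_scrofa,wild boar,Artiodactyla,primary_consumer,4598,4.09,344.86,306.54
Sciurus_vulgaris,red squirrel,Rodentia,primary_consumer,1412,1.26,0.42,0.38
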